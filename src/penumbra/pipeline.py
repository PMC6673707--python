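"""End-to-end orchestration: generate -> geometry -> sample -> fit.

Stages communicate through files only (cohort directory, long-table CSV,
report CSVs), so any stage can be rerun from its inputs. Reruns with an
identical config produce byte-identical tables and manifests.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import os
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import geometry as geo
from .models import (
    FitResult,
    fit_gradient_model,
    fit_type_comparison_model,
    report_tables,
)
from .sampling import (
    CSF_MD_THRESHOLD,
    ParticipantData,
    apply_csf_exclusion,
    assemble_table,
)
from .synthetic import PhantomConfig, generate_cohort
from .volume_io import (
    MaskVolume,
    ScalarVolume,
    ShellRecord,
    assert_common_grid,
    read_volume,
    write_records,
    write_volume,
)

log = logging.getLogger("penumbra")

__all__ = [
    "GeometryOptions",
    "SamplingOptions",
    "ModelOptions",
    "RunConfig",
    "PipelineError",
    "load_participant_volumes",
    "participant_geometry",
    "cohort_table",
    "run_pipeline",
    "validate_real_cohort",
]

VOLUME_KINDS = ("wmh_mask", "nawm_mask", "fa", "md")


class PipelineError(RuntimeError):
    """A stage failed; the message names the stage and cause."""


@dataclass(frozen=True)
class GeometryOptions:
    tract_threshold: float = geo.TRACT_PROBABILITY_THRESHOLD
    dilation_connectivity: int = 26
    component_connectivity: int = 26
    n_shells: int = geo.DEFAULT_N_SHELLS
    allow_anisotropic: bool = False
    #: treat all nearby components of a tract as one pooled seed mask
    pooled_nearby: bool = False


@dataclass(frozen=True)
class SamplingOptions:
    md_threshold: float = CSF_MD_THRESHOLD
    #: 'contour' drops flagged records from both analyses; 'md_only'
    #: keeps them for FA fits
    csf_scope: str = "contour"

    def __post_init__(self) -> None:
        if self.csf_scope not in ("contour", "md_only"):
            raise ValueError("csf_scope must be 'contour' or 'md_only'")


@dataclass(frozen=True)
class ModelOptions:
    df_method: str = "satterthwaite"
    outcomes: tuple[str, ...] = ("fa", "md")
    families: tuple[str, ...] = ("gradient", "comparison")
    scopes: tuple[str, ...] = ("all",)  # 'all', 'per_tract', or tract names


@dataclass(frozen=True)
class RunConfig:
    """Full pipeline configuration (one JSON file)."""

    mode: str  # {'synthetic', 'real'}
    phantom: PhantomConfig | None = None
    cohort_dir: str | None = None
    geometry: GeometryOptions = field(default_factory=GeometryOptions)
    sampling: SamplingOptions = field(default_factory=SamplingOptions)
    models: ModelOptions = field(default_factory=ModelOptions)
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.mode not in ("synthetic", "real"):
            raise ValueError("mode must be 'synthetic' or 'real'")
        if self.mode == "synthetic" and self.phantom is None:
            raise ValueError("synthetic mode requires a phantom config")
        if self.mode == "real" and not self.cohort_dir:
            raise ValueError("real mode requires cohort_dir")

    @classmethod
    def from_json(cls, text: str) -> "RunConfig":
        raw = json.loads(text)
        phantom = raw.get("phantom")
        if phantom is not None:
            phantom = PhantomConfig.from_json(json.dumps(phantom))
        geometry = GeometryOptions(**raw.get("geometry", {}))
        sampling = SamplingOptions(**raw.get("sampling", {}))
        mraw = raw.get("models", {})
        for key in ("outcomes", "families", "scopes"):
            if key in mraw:
                mraw[key] = tuple(mraw[key])
        models = ModelOptions(**mraw)
        return cls(
            mode=raw["mode"],
            phantom=phantom,
            cohort_dir=raw.get("cohort_dir"),
            geometry=geometry,
            sampling=sampling,
            models=models,
            seed=raw.get("seed"),
        )

    def effective(self) -> dict:
        d = dataclasses.asdict(self)
        return d


# ---------------------------------------------------------------------------
# cohort loading and geometry


def _tract_files(pdir: Path) -> dict[str, Path]:
    out = {}
    for f in sorted(pdir.glob("tract_*.nii")) + sorted(pdir.glob("tract_*.nii.gz")):
        name = f.name[len("tract_"):].split(".nii")[0]
        out[name] = f
    return out


def load_participant_volumes(pdir: Path) -> dict:
    """Read one participant's bundle; raises with the missing kind named."""
    tracts = _tract_files(pdir)
    if not tracts:
        raise PipelineError(f"{pdir.name}: no tract_*.nii volumes found")
    volumes: dict = {"tract_probs": {}}
    for name, path in tracts.items():
        volumes["tract_probs"][name] = read_volume(path, kind="probability")
    for kind in VOLUME_KINDS:
        candidates = [pdir / f"{kind}.nii", pdir / f"{kind}.nii.gz"]
        path = next((c for c in candidates if c.exists()), None)
        if path is None:
            raise PipelineError(f"{pdir.name}: missing volume {kind}")
        volumes[kind] = read_volume(path, kind="mask" if kind.endswith("_mask") else "scalar")
    assert_common_grid(
        list(volumes["tract_probs"].values())
        + [volumes[k] for k in VOLUME_KINDS]
    )
    return volumes


def participant_geometry(
    participant: str,
    volumes: dict,
    options: GeometryOptions,
    save_shells_dir: Path | None = None,
) -> ParticipantData:
    """Partition every tract and build its shell sets for one participant."""
    partitions: dict[str, geo.TractPartition] = {}
    tract_shells: dict[str, geo.ShellSet] = {}
    nearby_shells: dict[str, list[geo.ShellSet]] = {}
    wmh: MaskVolume = volumes["wmh_mask"]
    nawm: MaskVolume = volumes["nawm_mask"]
    for name, prob in sorted(volumes["tract_probs"].items()):
        tract_mask = geo.binarize_tract(prob, threshold=options.tract_threshold)
        part = geo.partition_tract(tract_mask, wmh, nawm, tract_name=name)
        partitions[name] = part
        shells = geo.build_tract_wmh_shells(
            part,
            n_shells=options.n_shells,
            connectivity=options.dilation_connectivity,
            allow_anisotropic=options.allow_anisotropic,
        )
        tract_shells[name] = shells
        union = shells.union_mask() if part.has_lesion else None
        components = geo.find_nearby_wmh(
            wmh,
            part,
            component_connectivity=options.component_connectivity,
            max_steps=options.n_shells,
            allow_anisotropic=options.allow_anisotropic,
        )
        if options.pooled_nearby and components:
            pooled = np.zeros(wmh.grid.shape, dtype=bool)
            for comp in components:
                pooled |= comp.data
            components = [MaskVolume(wmh.grid, pooled)]
        nearby_shells[name] = [
            geo.build_nearby_shells(
                comp,
                part,
                union,
                wmh_mask=wmh,
                n_shells=options.n_shells,
                connectivity=options.dilation_connectivity,
                allow_anisotropic=options.allow_anisotropic,
            )
            for comp in components
        ]
        log.info(
            "%s/%s: %%WMHvol=%s, nearby components=%d",
            participant,
            name,
            "NA" if part.pct_wmh_vol is None else f"{part.pct_wmh_vol:.2f}",
            len(components),
        )
        if save_shells_dir is not None:
            _save_shells(save_shells_dir, participant, name, tract_shells[name], nearby_shells[name])
    return ParticipantData(
        participant=participant,
        partitions=partitions,
        tract_wmh_shells=tract_shells,
        nearby_shells=nearby_shells,
        fa=volumes["fa"],
        md=volumes["md"],
    )


def _save_shells(out_dir, participant, tract, tract_set, nearby_sets) -> None:
    out = Path(out_dir) / participant
    out.mkdir(parents=True, exist_ok=True)
    grid = tract_set.seed_mask.grid
    label = np.zeros(grid.shape, dtype=float)
    for k, (_, mask) in enumerate(tract_set.shells, start=1):
        label[mask.data] = k
    write_volume(ScalarVolume(grid, label), out / f"shells_{tract}_tract_wmh.nii")
    for i, ns in enumerate(nearby_sets):
        label = np.zeros(grid.shape, dtype=float)
        for k, (_, mask) in enumerate(ns.shells, start=1):
            label[mask.data] = k
        write_volume(ScalarVolume(grid, label), out / f"shells_{tract}_nearby{i}.nii")


def cohort_table(
    cohort_dir: str | os.PathLike,
    geometry_options: GeometryOptions | None = None,
    sampling_options: SamplingOptions | None = None,
    save_shells_dir: Path | None = None,
) -> list[ShellRecord]:
    """Run geometry + sampling over a cohort directory, returning records."""
    geometry_options = geometry_options or GeometryOptions()
    sampling_options = sampling_options or SamplingOptions()
    cohort = Path(cohort_dir)
    if not cohort.is_dir():
        raise PipelineError(f"sample stage: cohort directory {cohort} does not exist")
    pdirs = sorted(d for d in cohort.iterdir() if d.is_dir())
    if not pdirs:
        raise PipelineError(f"sample stage: no participant directories in {cohort}")
    pdata = []
    for pdir in pdirs:
        volumes = load_participant_volumes(pdir)
        pdata.append(
            participant_geometry(pdir.name, volumes, geometry_options, save_shells_dir)
        )
    records = assemble_table(pdata)
    records = apply_csf_exclusion(records, md_threshold=sampling_options.md_threshold)
    return records


# ---------------------------------------------------------------------------
# fits


def _clear_csf_flags(records: list[ShellRecord]) -> list[ShellRecord]:
    return [
        dataclasses.replace(r, excluded_csf=False) if r.excluded_csf else r
        for r in records
    ]


def fit_stage(
    records: list[ShellRecord],
    options: ModelOptions,
    sampling_options: SamplingOptions | None = None,
) -> list[FitResult]:
    """All requested fits; 'per_tract' expands to every tract in the table."""
    sampling_options = sampling_options or SamplingOptions()
    tracts = sorted({r.tract for r in records})
    fits: list[FitResult] = []
    for outcome in options.outcomes:
        recs = records
        if outcome == "fa" and sampling_options.csf_scope == "md_only":
            recs = _clear_csf_flags(records)
        for family in options.families:
            fitter = fit_gradient_model if family == "gradient" else fit_type_comparison_model
            scopes: list[str] = []
            for scope in options.scopes:
                if scope == "per_tract":
                    scopes.extend(tracts)
                else:
                    scopes.append(scope)
            for scope in scopes:
                try:
                    fits.append(fitter(recs, outcome, scope=scope, df_method=options.df_method))
                except (ValueError, RuntimeError) as exc:
                    log.warning("fit skipped (%s/%s/%s): %s", outcome, family, scope, exc)
    return fits


# ---------------------------------------------------------------------------
# full pipeline


def run_pipeline(config: RunConfig, out_dir: str | os.PathLike) -> dict[str, Path]:
    """Run all stages; returns paths of the artifacts written.

    Any stage failure raises :class:`PipelineError` naming the stage; a
    ``.incomplete`` marker is left in ``out_dir`` until the run finishes.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    marker = out / ".incomplete"
    marker.write_text("run in progress")
    artifacts: dict[str, Path] = {}
    try:
        if config.mode == "synthetic":
            phantom = config.phantom
            if config.seed is not None:
                phantom = dataclasses.replace(phantom, seed=config.seed)
            cohort_dir = out / "cohort"
            try:
                generate_cohort(phantom, cohort_dir)
            except Exception as exc:
                raise PipelineError(f"generate stage: {exc}") from exc
            artifacts["cohort"] = cohort_dir
        else:
            cohort_dir = Path(config.cohort_dir)
            if not cohort_dir.is_dir():
                raise PipelineError(f"input stage: cohort directory {cohort_dir} not found")

        try:
            records = cohort_table(cohort_dir, config.geometry, config.sampling)
        except PipelineError:
            raise
        except Exception as exc:
            raise PipelineError(f"sample stage: {exc}") from exc
        table_path = out / "table.csv"
        write_records(records, table_path)
        artifacts["table"] = table_path
        n_excluded = sum(r.excluded_csf for r in records)
        log.info("table: %d records, %d CSF-excluded", len(records), n_excluded)

        try:
            fits = fit_stage(records, config.models, config.sampling)
        except Exception as exc:
            raise PipelineError(f"fit stage: {exc}") from exc
        manifest_extra = {
            "effective_config": config.effective(),
            "n_records": len(records),
            "n_csf_excluded": n_excluded,
            "n_participants": len({r.participant for r in records}),
        }
        paths = report_tables(fits, out / "fits", manifest_extra=manifest_extra)
        artifacts.update(paths)
    finally:
        if marker.exists() and "manifest" in artifacts:
            marker.unlink()
    return artifacts


# ---------------------------------------------------------------------------
# validation


def validate_real_cohort(cohort_dir: str | os.PathLike) -> dict:
    """Inventory a cohort directory; lists every violation, not just the first.

    Tracts without a WMH intersection are legal and only noted; a
    participant with no eligible lesion at all is flagged 'no-lesion'
    (kept in the inventory, excluded from fitting).
    """
    cohort = Path(cohort_dir)
    if not cohort.is_dir():
        raise FileNotFoundError(f"cohort directory {cohort} does not exist")
    report: dict = {"participants": {}, "errors": [], "n_participants": 0}
    pdirs = sorted(d for d in cohort.iterdir() if d.is_dir())
    report["n_participants"] = len(pdirs)
    for pdir in pdirs:
        entry: dict = {"missing": [], "grid_ok": True, "no_lesion": False, "tracts": {}}
        tracts = _tract_files(pdir)
        if not tracts:
            entry["missing"].append("tract probability maps")
        for kind in VOLUME_KINDS:
            if not (pdir / f"{kind}.nii").exists() and not (pdir / f"{kind}.nii.gz").exists():
                entry["missing"].append(kind)
        if not entry["missing"]:
            try:
                volumes = load_participant_volumes(pdir)
                wmh = volumes["wmh_mask"]
                if wmh.n_foreground == 0:
                    entry["no_lesion"] = True
                for name, prob in sorted(volumes["tract_probs"].items()):
                    tract_mask = geo.binarize_tract(prob)
                    part = geo.partition_tract(tract_mask, wmh, volumes["nawm_mask"], name)
                    entry["tracts"][name] = {
                        "pct_wmh_vol": part.pct_wmh_vol,
                        "has_lesion": part.has_lesion,
                    }
                if entry["tracts"] and not any(
                    t["has_lesion"] for t in entry["tracts"].values()
                ):
                    entry["no_lesion"] = True
            except Exception as exc:  # noqa: BLE001 - collect, don't abort
                entry["grid_ok"] = False
                report["errors"].append(f"{pdir.name}: {exc}")
        else:
            report["errors"].append(
                f"{pdir.name}: missing {', '.join(entry['missing'])}"
            )
        report["participants"][pdir.name] = entry
    return report
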