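"""Synthetic phantom cohorts with planted penumbra structure.

Generates per-participant bundles (tract probability maps, WMH and NAWM
masks, FA and MD maps) in which the diffusion values in normal-appearing
white matter follow a known log-distance gradient away from each lesion:

    value(voxel) = (b0 + u0_participant + u0_tract [+ type offset])
                 + (b1 + u1_participant + u1_tract [+ type slope delta])
                   * log(d_mm + 1) + noise

where ``d_mm`` is the Chebyshev voxel distance to the nearest lesion
times the voxel size, capped at ``cap_distance_mm`` (the curve is frozen
beyond the modelled range). Lesions are axis-aligned ellipsoids, either
intersecting a tract or placed nearby with a controlled Chebyshev gap.
Everything is a pure function of the config, including its seed.
"""

from __future__ import annotations

import dataclasses
import json
import math
import os
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy import ndimage

from .geometry import PlacementError
from .volume_io import MaskVolume, ScalarVolume, VolumeGrid, write_volume

__all__ = [
    "TractSpec",
    "LesionPlan",
    "GradientParams",
    "EffectSDs",
    "PhantomConfig",
    "LesionTruth",
    "ParticipantTruth",
    "CohortTruth",
    "make_tract_probability_map",
    "place_lesions",
    "synthesize_maps",
    "generate_cohort",
    "load_truth",
    "default_config",
]


@dataclass(frozen=True)
class TractSpec:
    """A synthetic tract: a polyline centerline with a tubular radius."""

    name: str
    control_points: tuple[tuple[float, float, float], ...]
    radius_mm: float

    def __post_init__(self) -> None:
        if len(self.control_points) < 2:
            raise ValueError("centerline needs at least two control points")
        if self.radius_mm <= 0:
            raise ValueError("radius_mm must be positive")


@dataclass(frozen=True)
class LesionPlan:
    n_intersecting_per_tract: int = 1
    n_nearby_per_tract: int = 0
    semi_axes_range_mm: tuple[float, float] = (2.0, 4.0)
    nearby_gap_range_mm: tuple[float, float] = (2.0, 10.0)
    #: minimum Chebyshev separation (voxels) between distinct lesions, so
    #: each voxel's nearest lesion within the shell range is unambiguous
    min_separation_vox: int = 12
    #: require intersecting lesions to lie fully inside the tract mask
    contain_in_tract: bool = True
    max_attempts: int = 500

    def __post_init__(self) -> None:
        if self.n_intersecting_per_tract < 0 or self.n_nearby_per_tract < 0:
            raise ValueError("lesion counts must be >= 0")
        lo, hi = self.semi_axes_range_mm
        if lo <= 0 or hi < lo:
            raise ValueError("bad semi_axes_range_mm")
        lo, hi = self.nearby_gap_range_mm
        if lo < 2.0 or hi > 10.0 or hi < lo:
            raise ValueError("nearby gap range must lie within [2, 10] mm")


@dataclass(frozen=True)
class GradientParams:
    """Planted fixed-effect structure, per outcome.

    Slopes are per unit log(distance_mm + 1); the distance-0 value (the
    lesion interior) is the intercept. ``*_nearby_offset`` shifts the
    curve for voxels whose nearest lesion does not touch their tract;
    ``*_nearby_slope_delta`` plants a type-by-distance interaction.
    """

    fa_at_wmh: float = 0.30
    fa_slope: float = 0.024
    md_at_wmh: float = 9.2e-4
    md_slope: float = -8.5e-6
    fa_asymptote: float | None = None
    md_asymptote: float | None = None
    fa_nearby_offset: float = 0.0
    md_nearby_offset: float = 0.0
    fa_nearby_slope_delta: float = 0.0
    md_nearby_slope_delta: float = 0.0
    cap_distance_mm: float = 10.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.fa_at_wmh <= 1.0:
            raise ValueError("fa_at_wmh must be in [0, 1]")
        if self.fa_asymptote is not None and not 0.0 <= self.fa_asymptote <= 1.0:
            raise ValueError("fa_asymptote must be in [0, 1]")
        if self.md_at_wmh <= 0:
            raise ValueError("md_at_wmh must be positive")


@dataclass(frozen=True)
class EffectSDs:
    """Random-effect standard deviations for one outcome."""

    sd_participant_intercept: float = 0.0
    sd_participant_slope: float = 0.0
    sd_tract_intercept: float = 0.0
    sd_tract_slope: float = 0.0

    def __post_init__(self) -> None:
        for f in dataclasses.fields(self):
            if getattr(self, f.name) < 0:
                raise ValueError(f"{f.name} must be >= 0")


@dataclass(frozen=True)
class PhantomConfig:
    n_participants: int = 2
    grid_shape: tuple[int, int, int] = (64, 64, 40)
    voxel_size_mm: tuple[float, float, float] = (2.0, 2.0, 2.0)
    tract_specs: tuple[TractSpec, ...] = ()
    lesion_plan: LesionPlan = field(default_factory=LesionPlan)
    gradient_params: GradientParams = field(default_factory=GradientParams)
    fa_effects: EffectSDs = field(default_factory=EffectSDs)
    md_effects: EffectSDs = field(default_factory=EffectSDs)
    fa_noise_sd: float = 0.0
    md_noise_sd: float = 0.0
    csf_fraction: float = 0.0
    csf_md_range: tuple[float, float] = (1.2e-3, 2.5e-3)
    fa_background: float = 0.15
    md_background: float = 7.0e-4
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_participants < 1:
            raise ValueError("n_participants must be >= 1")
        if self.fa_noise_sd < 0 or self.md_noise_sd < 0:
            raise ValueError("noise SDs must be >= 0")
        if not 0.0 <= self.csf_fraction <= 1.0:
            raise ValueError("csf_fraction must be in [0, 1]")
        if not self.tract_specs:
            raise ValueError("at least one tract spec is required")

    @property
    def grid(self) -> VolumeGrid:
        return VolumeGrid(shape=self.grid_shape, voxel_size_mm=self.voxel_size_mm)

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self), indent=2, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "PhantomConfig":
        raw = json.loads(text)
        raw["tract_specs"] = tuple(
            TractSpec(
                name=t["name"],
                control_points=tuple(tuple(p) for p in t["control_points"]),
                radius_mm=t["radius_mm"],
            )
            for t in raw.get("tract_specs", ())
        )
        for key, typ in (
            ("lesion_plan", LesionPlan),
            ("gradient_params", GradientParams),
            ("fa_effects", EffectSDs),
            ("md_effects", EffectSDs),
        ):
            if key in raw and isinstance(raw[key], dict):
                sub = {
                    k: tuple(v) if isinstance(v, list) else v for k, v in raw[key].items()
                }
                raw[key] = typ(**sub)
        for key in ("grid_shape", "voxel_size_mm", "csf_md_range"):
            if key in raw:
                raw[key] = tuple(raw[key])
        return cls(**raw)


# ---------------------------------------------------------------------------
# ground truth


@dataclass(frozen=True)
class LesionTruth:
    lesion_id: str
    tract: str
    kind: str  # {'intersecting', 'nearby'}
    voxels: np.ndarray = field(repr=False)  # (N, 3) int indices

    def __post_init__(self) -> None:
        vox = np.asarray(self.voxels, dtype=int)
        if vox.ndim != 2 or vox.shape[1] != 3 or vox.shape[0] == 0:
            raise ValueError("lesion voxel set must be a nonempty (N, 3) array")
        if self.kind not in ("intersecting", "nearby"):
            raise ValueError(f"bad lesion kind {self.kind!r}")
        object.__setattr__(self, "voxels", vox)


@dataclass(frozen=True)
class ParticipantTruth:
    participant: str
    lesions: tuple[LesionTruth, ...]
    # (intercept, slope) random-effect draws per outcome
    fa_effects: tuple[float, float]
    md_effects: tuple[float, float]


@dataclass(frozen=True)
class CohortTruth:
    participants: tuple[ParticipantTruth, ...]
    tract_fa_effects: dict[str, tuple[float, float]]
    tract_md_effects: dict[str, tuple[float, float]]
    gradient_params: GradientParams
    seed: int

    def to_json(self) -> str:
        payload = {
            "seed": self.seed,
            "gradient_params": dataclasses.asdict(self.gradient_params),
            "tract_fa_effects": {k: list(v) for k, v in sorted(self.tract_fa_effects.items())},
            "tract_md_effects": {k: list(v) for k, v in sorted(self.tract_md_effects.items())},
            "participants": [
                {
                    "participant": p.participant,
                    "fa_effects": list(p.fa_effects),
                    "md_effects": list(p.md_effects),
                    "lesions": [
                        {
                            "lesion_id": les.lesion_id,
                            "tract": les.tract,
                            "kind": les.kind,
                            "voxels": les.voxels.tolist(),
                        }
                        for les in p.lesions
                    ],
                }
                for p in self.participants
            ],
        }
        return json.dumps(payload, indent=1, sort_keys=True)


def load_truth(path: str | os.PathLike) -> CohortTruth:
    raw = json.loads(Path(path).read_text())
    participants = tuple(
        ParticipantTruth(
            participant=p["participant"],
            fa_effects=tuple(p["fa_effects"]),
            md_effects=tuple(p["md_effects"]),
            lesions=tuple(
                LesionTruth(
                    lesion_id=les["lesion_id"],
                    tract=les["tract"],
                    kind=les["kind"],
                    voxels=np.asarray(les["voxels"], dtype=int),
                )
                for les in p["lesions"]
            ),
        )
        for p in raw["participants"]
    )
    return CohortTruth(
        participants=participants,
        tract_fa_effects={k: tuple(v) for k, v in raw["tract_fa_effects"].items()},
        tract_md_effects={k: tuple(v) for k, v in raw["tract_md_effects"].items()},
        gradient_params=GradientParams(**raw["gradient_params"]),
        seed=raw["seed"],
    )


# ---------------------------------------------------------------------------
# tract probability maps


def _polyline_distance_mm(grid: VolumeGrid, points_vox: np.ndarray) -> np.ndarray:
    """Euclidean distance (mm) from every voxel center to a polyline."""
    vox = np.asarray(grid.voxel_size_mm)
    idx = np.indices(grid.shape, dtype=float).reshape(3, -1).T  # (n, 3)
    coords = idx * vox
    pts = points_vox * vox
    best = np.full(coords.shape[0], np.inf)
    for a, b in zip(pts[:-1], pts[1:]):
        ab = b - a
        denom = float(ab @ ab)
        if denom == 0.0:
            proj = np.zeros(coords.shape[0])
        else:
            proj = np.clip((coords - a) @ ab / denom, 0.0, 1.0)
        closest = a + proj[:, None] * ab
        d = np.linalg.norm(coords - closest, axis=1)
        np.minimum(best, d, out=best)
    return best.reshape(grid.shape)


def make_tract_probability_map(spec: TractSpec, grid: VolumeGrid) -> ScalarVolume:
    """Deterministic tube-shaped probability map for a tract spec.

    The map is 1.0 within one voxel of the centerline, decays as a
    Gaussian of the excess distance, and is strictly below 0.01 beyond
    twice the tract radius (so the 1% binarization threshold yields a
    tube of bounded width).
    """
    pts = np.asarray(spec.control_points, dtype=float)
    for p in pts:
        if (p < 0).any() or (p >= np.asarray(grid.shape)).any():
            raise ValueError(f"centerline point {p} lies outside grid {grid.shape}")
    if spec.radius_mm < max(grid.voxel_size_mm) / 2:
        raise ValueError("tract radius must be at least half a voxel")
    dist = _polyline_distance_mm(grid, pts)
    core = float(max(grid.voxel_size_mm))  # flat top covers centerline voxels
    outer = 2.0 * spec.radius_mm
    if outer <= core:
        outer = core + float(max(grid.voxel_size_mm))
    k = math.log(1000.0) / (outer - core) ** 2
    prob = np.exp(-k * np.square(np.maximum(dist - core, 0.0)))
    prob[dist > outer] = 0.0  # hard support bound, already < 1e-3 there
    return ScalarVolume(grid, prob)


# ---------------------------------------------------------------------------
# lesion placement


def _ellipsoid_voxels(
    center: np.ndarray, semi_axes_vox: np.ndarray, shape: tuple[int, int, int]
) -> np.ndarray:
    lo = np.maximum(np.floor(center - semi_axes_vox).astype(int), 0)
    hi = np.minimum(np.ceil(center + semi_axes_vox).astype(int) + 1, shape)
    if (hi <= lo).any():
        return np.empty((0, 3), dtype=int)
    box = np.indices(tuple(hi - lo)).reshape(3, -1).T + lo
    rel = (box - center) / semi_axes_vox
    inside = (rel**2).sum(axis=1) <= 1.0
    return box[inside]


def _chebyshev_gap(voxels_a: np.ndarray, voxels_b: np.ndarray) -> int:
    """Minimum pairwise Chebyshev distance between two small voxel sets."""
    diff = np.abs(voxels_a[:, None, :] - voxels_b[None, :, :]).max(axis=2)
    return int(diff.min())


def place_lesions(
    tract_mask: MaskVolume,
    nawm_extent: MaskVolume,
    plan: LesionPlan,
    rng: np.random.Generator,
    tract_name: str = "tract",
    existing_lesions: list[np.ndarray] | None = None,
) -> tuple[MaskVolume, list[LesionTruth]]:
    """Place ellipsoidal lesions intersecting and near one tract.

    Intersecting lesions share voxels with the tract (fully contained
    when ``plan.contain_in_tract``); nearby lesions share none and sit at
    a sampled Chebyshev gap of 1-5 voxels (2-10 mm) from the tract.
    ``existing_lesions`` (voxel sets of other tracts' lesions) are kept
    at the plan's minimum separation. Deterministic given the generator
    state.
    """
    if not tract_mask.data.any():
        raise PlacementError(f"{tract_name}: tract mask is empty")
    shape = tract_mask.grid.shape
    vox_mm = float(max(tract_mask.grid.voxel_size_mm))
    placed = np.zeros(shape, dtype=bool)
    neighbours: list[np.ndarray] = list(existing_lesions or [])
    lesions: list[LesionTruth] = []

    tract_idx = np.argwhere(tract_mask.data)
    dt_tract = ndimage.distance_transform_cdt(~tract_mask.data, metric="chessboard")
    lo_mm, hi_mm = plan.semi_axes_range_mm

    def sample_axes() -> np.ndarray:
        ax_mm = rng.uniform(lo_mm, hi_mm, size=3)
        return np.maximum(ax_mm / vox_mm, 1.0)

    def admissible(vox: np.ndarray) -> bool:
        if vox.shape[0] == 0:
            return False
        sel = tuple(vox.T)
        if not nawm_extent.data[sel].all():
            return False
        for other in neighbours:
            if _chebyshev_gap(vox, other) < plan.min_separation_vox:
                return False
        return True

    for j in range(plan.n_intersecting_per_tract):
        ok = False
        for _ in range(plan.max_attempts):
            center = tract_idx[rng.integers(len(tract_idx))].astype(float)
            vox = _ellipsoid_voxels(center, sample_axes(), shape)
            if not admissible(vox):
                continue
            sel = tuple(vox.T)
            if not tract_mask.data[sel].any():
                continue
            if plan.contain_in_tract and not tract_mask.data[sel].all():
                continue
            ok = True
            break
        if not ok:
            raise PlacementError(
                f"{tract_name}: could not place intersecting lesion {j} after "
                f"{plan.max_attempts} attempts (containment/separation constraints)"
            )
        placed[sel] = True
        neighbours.append(vox)
        lesions.append(LesionTruth(f"{tract_name}_int{j}", tract_name, "intersecting", vox))

    glo, ghi = plan.nearby_gap_range_mm
    for j in range(plan.n_nearby_per_tract):
        ok = False
        for _ in range(plan.max_attempts):
            gap_vox = int(round(rng.uniform(glo, ghi) / vox_mm))
            gap_vox = min(max(gap_vox, 1), 5)
            axes = sample_axes()
            reach = gap_vox + int(math.ceil(axes.max())) + 1
            cand = np.argwhere((dt_tract >= gap_vox) & (dt_tract <= reach))
            if len(cand) == 0:
                continue
            center = cand[rng.integers(len(cand))].astype(float)
            vox = _ellipsoid_voxels(center, axes, shape)
            if not admissible(vox):
                continue
            sel = tuple(vox.T)
            if tract_mask.data[sel].any():
                continue
            if int(dt_tract[sel].min()) != gap_vox:
                continue
            ok = True
            break
        if not ok:
            raise PlacementError(
                f"{tract_name}: could not place nearby lesion {j} at a legal "
                f"2-10 mm gap after {plan.max_attempts} attempts"
            )
        placed[sel] = True
        neighbours.append(vox)
        lesions.append(LesionTruth(f"{tract_name}_nby{j}", tract_name, "nearby", vox))

    return MaskVolume(tract_mask.grid, placed), lesions


# ---------------------------------------------------------------------------
# map synthesis


def _planted_mean(
    d_mm: np.ndarray,
    intercept: np.ndarray | float,
    slope: np.ndarray | float,
    cap_mm: float,
    asymptote: float | None,
    slope_sign: float,
) -> np.ndarray:
    mu = intercept + slope * np.log1p(np.minimum(d_mm, cap_mm))
    if asymptote is not None:
        mu = np.minimum(mu, asymptote) if slope_sign >= 0 else np.maximum(mu, asymptote)
    return mu


def synthesize_maps(
    wmh_mask: MaskVolume,
    nawm_mask: MaskVolume,
    lesions: list[LesionTruth] | tuple[LesionTruth, ...],
    config: PhantomConfig,
    participant_fa: tuple[float, float],
    participant_md: tuple[float, float],
    tract_fa: dict[str, tuple[float, float]],
    tract_md: dict[str, tuple[float, float]],
    rng: np.random.Generator,
) -> tuple[ScalarVolume, ScalarVolume]:
    """Synthesize FA and MD maps around the given lesions.

    Each WMH/NAWM voxel is attributed to its nearest lesion (Chebyshev;
    ties broken by lesion order), which determines the planted curve's
    type offset and the tract whose random effects apply.
    """
    grid = wmh_mask.grid
    shape = grid.shape
    vox_mm = float(max(grid.voxel_size_mm))
    g = config.gradient_params

    if not lesions:
        raise ValueError("synthesize_maps requires at least one lesion")
    d_stack = np.empty((len(lesions),) + shape, dtype=np.int32)
    for i, les in enumerate(lesions):
        m = np.zeros(shape, dtype=bool)
        m[tuple(les.voxels.T)] = True
        d_stack[i] = ndimage.distance_transform_cdt(~m, metric="chessboard")
    nearest = d_stack.argmin(axis=0)
    d_vox = d_stack.min(axis=0)
    d_mm = d_vox.astype(float) * vox_mm

    is_nearby = np.asarray([les.kind == "nearby" for les in lesions])
    tract_of = [les.tract for les in lesions]

    fa = np.full(shape, config.fa_background, dtype=float)
    md = np.full(shape, config.md_background, dtype=float)
    region = wmh_mask.data | nawm_mask.data

    for i, les in enumerate(lesions):
        sel = region & (nearest == i)
        if not sel.any():
            continue
        t = tract_of[i]
        fa_i = g.fa_at_wmh + participant_fa[0] + tract_fa.get(t, (0.0, 0.0))[0]
        fa_s = g.fa_slope + participant_fa[1] + tract_fa.get(t, (0.0, 0.0))[1]
        md_i = g.md_at_wmh + participant_md[0] + tract_md.get(t, (0.0, 0.0))[0]
        md_s = g.md_slope + participant_md[1] + tract_md.get(t, (0.0, 0.0))[1]
        if is_nearby[i]:
            fa_i += g.fa_nearby_offset
            fa_s += g.fa_nearby_slope_delta
            md_i += g.md_nearby_offset
            md_s += g.md_nearby_slope_delta
        fa[sel] = _planted_mean(
            d_mm[sel], fa_i, fa_s, g.cap_distance_mm, g.fa_asymptote, g.fa_slope
        )
        md[sel] = _planted_mean(
            d_mm[sel], md_i, md_s, g.cap_distance_mm, g.md_asymptote, g.md_slope
        )

    if config.fa_noise_sd > 0:
        fa[region] += rng.normal(0.0, config.fa_noise_sd, size=int(region.sum()))
    if config.md_noise_sd > 0:
        md[region] += rng.normal(0.0, config.md_noise_sd, size=int(region.sum()))

    # CSF-like contamination: high MD in a fraction of non-NAWM border voxels
    border = _brain_mask(shape) & ~_brain_interior(shape)
    border &= ~wmh_mask.data & ~nawm_mask.data
    if config.csf_fraction > 0 and border.any():
        idx = np.argwhere(border)
        n_pick = int(round(config.csf_fraction * len(idx)))
        if n_pick > 0:
            pick = idx[rng.choice(len(idx), size=n_pick, replace=False)]
            md[tuple(pick.T)] = rng.uniform(*config.csf_md_range, size=n_pick)

    np.clip(fa, 0.0, 1.0, out=fa)
    np.clip(md, 0.0, None, out=md)
    return ScalarVolume(grid, fa), ScalarVolume(grid, md)


def _brain_mask(shape: tuple[int, int, int]) -> np.ndarray:
    m = np.zeros(shape, dtype=bool)
    m[1:-1, 1:-1, 1:-1] = True
    return m


def _brain_interior(shape: tuple[int, int, int]) -> np.ndarray:
    m = np.zeros(shape, dtype=bool)
    m[2:-2, 2:-2, 2:-2] = True
    return m


# ---------------------------------------------------------------------------
# cohort generation


def _participant_id(i: int) -> str:
    return f"sub{i + 1:03d}"


def build_participant(
    config: PhantomConfig,
    tract_masks: dict[str, MaskVolume],
    participant: str,
    rng: np.random.Generator,
    tract_fa: dict[str, tuple[float, float]],
    tract_md: dict[str, tuple[float, float]],
) -> tuple[dict[str, MaskVolume | ScalarVolume], ParticipantTruth]:
    """Lesions, masks and maps for one participant (in memory)."""
    grid = config.grid
    shape = grid.shape
    interior = _brain_interior(shape)
    nawm_extent = MaskVolume(grid, interior)

    fa_sd = config.fa_effects
    md_sd = config.md_effects
    p_fa = (
        rng.normal(0.0, fa_sd.sd_participant_intercept),
        rng.normal(0.0, fa_sd.sd_participant_slope),
    )
    p_md = (
        rng.normal(0.0, md_sd.sd_participant_intercept),
        rng.normal(0.0, md_sd.sd_participant_slope),
    )

    wmh = np.zeros(shape, dtype=bool)
    all_lesions: list[LesionTruth] = []
    for name in sorted(tract_masks):
        lesion_mask, lesions = place_lesions(
            tract_masks[name],
            nawm_extent,
            config.lesion_plan,
            rng,
            tract_name=name,
            existing_lesions=[les.voxels for les in all_lesions],
        )
        wmh |= lesion_mask.data
        all_lesions.extend(lesions)

    wmh_mask = MaskVolume(grid, wmh)
    nawm_mask = MaskVolume(grid, interior & ~wmh)
    fa, md = synthesize_maps(
        wmh_mask,
        nawm_mask,
        all_lesions,
        config,
        p_fa,
        p_md,
        tract_fa,
        tract_md,
        rng,
    )
    truth = ParticipantTruth(
        participant=participant,
        lesions=tuple(all_lesions),
        fa_effects=tuple(float(x) for x in p_fa),
        md_effects=tuple(float(x) for x in p_md),
    )
    volumes: dict[str, MaskVolume | ScalarVolume] = {
        "wmh_mask": wmh_mask,
        "nawm_mask": nawm_mask,
        "fa": fa,
        "md": md,
    }
    return volumes, truth


def build_cohort(
    config: PhantomConfig,
) -> tuple[
    dict[str, ScalarVolume],
    list[tuple[str, dict[str, MaskVolume | ScalarVolume]]],
    CohortTruth,
]:
    """Generate the full cohort in memory (tract maps, bundles, truth)."""
    grid = config.grid
    tract_probs = {
        spec.name: make_tract_probability_map(spec, grid) for spec in config.tract_specs
    }
    from .geometry import binarize_tract

    tract_masks = {name: binarize_tract(p) for name, p in tract_probs.items()}
    ss = np.random.SeedSequence(config.seed)
    cohort_rng = np.random.default_rng(ss.spawn(1)[0])
    tract_fa: dict[str, tuple[float, float]] = {}
    tract_md: dict[str, tuple[float, float]] = {}
    for spec in sorted(config.tract_specs, key=lambda s: s.name):
        tract_fa[spec.name] = (
            float(cohort_rng.normal(0.0, config.fa_effects.sd_tract_intercept)),
            float(cohort_rng.normal(0.0, config.fa_effects.sd_tract_slope)),
        )
        tract_md[spec.name] = (
            float(cohort_rng.normal(0.0, config.md_effects.sd_tract_intercept)),
            float(cohort_rng.normal(0.0, config.md_effects.sd_tract_slope)),
        )

    participants = []
    truths = []
    child_seeds = ss.spawn(config.n_participants + 1)[1:]
    for i in range(config.n_participants):
        pid = _participant_id(i)
        rng = np.random.default_rng(child_seeds[i])
        volumes, truth = build_participant(
            config, tract_masks, pid, rng, tract_fa, tract_md
        )
        participants.append((pid, volumes))
        truths.append(truth)
    truth = CohortTruth(
        participants=tuple(truths),
        tract_fa_effects=tract_fa,
        tract_md_effects=tract_md,
        gradient_params=config.gradient_params,
        seed=config.seed,
    )
    return tract_probs, participants, truth


def generate_cohort(config: PhantomConfig, out_dir: str | os.PathLike) -> Path:
    """Write the cohort to ``out_dir`` (one directory per participant).

    Layout::

        out_dir/
          ground_truth.json
          config.json
          sub001/
            tract_<name>.nii   (one per tract, posterior-probability map)
            wmh_mask.nii  nawm_mask.nii  fa.nii  md.nii
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    tract_probs, participants, truth = build_cohort(config)
    for pid, volumes in participants:
        pdir = out / pid
        pdir.mkdir(exist_ok=True)
        for name, prob in tract_probs.items():
            write_volume(prob, pdir / f"tract_{name}.nii")
        for key in ("wmh_mask", "nawm_mask", "fa", "md"):
            write_volume(volumes[key], pdir / f"{key}.nii")
    (out / "ground_truth.json").write_text(truth.to_json())
    (out / "config.json").write_text(config.to_json())
    return out


def default_config(
    n_participants: int = 2,
    seed: int = 0,
    n_tracts: int = 1,
    grid_shape: tuple[int, int, int] = (64, 64, 40),
    **overrides,
) -> PhantomConfig:
    """A ready-to-run config: straight parallel tubes along the x axis."""
    nx, ny, nz = grid_shape
    names = ["tractA", "tractB", "tractC"][:n_tracts]
    if n_tracts > 3:
        names = [f"tract{chr(65 + i)}" for i in range(n_tracts)]
    ys = np.linspace(ny * 0.25, ny * 0.75, max(n_tracts, 2))[:n_tracts]
    specs = tuple(
        TractSpec(
            name=nm,
            control_points=((3.0, float(y), nz / 2.0), (nx - 4.0, float(y), nz / 2.0)),
            radius_mm=5.0,
        )
        for nm, y in zip(names, ys)
    )
    return PhantomConfig(
        n_participants=n_participants,
        grid_shape=grid_shape,
        tract_specs=specs,
        seed=seed,
        **overrides,
    )
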