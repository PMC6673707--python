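"""Sample FA/MD over shells into the long-format analysis table.

One record per participant x tract x WMH type x distance. The lesion
region itself is measured only for tract-intersecting lesions (distance
0); nearby lesions contribute distances 2-10 mm only. Records whose mean
MD exceeds the CSF threshold are flagged and dropped from model input
(but retained in the table for accounting).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

from .geometry import ShellSet, TractPartition
from .volume_io import MaskVolume, ScalarVolume, ShellRecord, assert_common_grid

__all__ = [
    "ParticipantData",
    "shell_mean",
    "assemble_table",
    "apply_csf_exclusion",
    "CSF_MD_THRESHOLD",
]

#: Mean-MD cut above which a contour is considered CSF-contaminated (mm^2/s).
CSF_MD_THRESHOLD = 1e-3


@dataclass(frozen=True)
class ParticipantData:
    """Geometry outputs plus scalar maps for one participant."""

    participant: str
    partitions: dict[str, TractPartition] = field(repr=False)
    tract_wmh_shells: dict[str, ShellSet] = field(repr=False)
    nearby_shells: dict[str, list[ShellSet]] = field(repr=False)
    fa: ScalarVolume = field(repr=False)
    md: ScalarVolume = field(repr=False)


def shell_mean(region: MaskVolume, scalar: ScalarVolume) -> tuple[float | None, int]:
    """Arithmetic mean of ``scalar`` over ``region``; (None, 0) if empty."""
    assert_common_grid([region, scalar])
    sel = region.data
    n = int(sel.sum())
    if n == 0:
        return None, 0
    vals = scalar.data[sel]
    if not np.isfinite(vals).all():
        bad = tuple(int(v) for v in np.argwhere(sel)[~np.isfinite(vals)][0])
        raise ValueError(f"non-finite scalar value inside region at voxel {bad}")
    return float(vals.mean()), n


def _pooled(entries: list[tuple[float | None, int]]) -> tuple[float | None, int]:
    """Voxel-count-weighted pool of per-component shell means."""
    n_total = sum(n for _, n in entries)
    if n_total == 0:
        return None, 0
    num = sum(m * n for m, n in entries if n > 0 and m is not None)
    return num / n_total, n_total


def assemble_table(cohort: Iterable[ParticipantData]) -> list[ShellRecord]:
    """Build the long table, ordered by (participant, tract, type, distance).

    Emits 6 tract-WMH records (0-10 mm) per lesioned tract and 5 nearby
    records (2-10 mm) per tract with at least one eligible nearby lesion;
    shells from multiple nearby components are pooled per distance by
    voxel-count-weighted mean. Empty shells appear with n_voxels=0 and
    missing means.
    """
    records: list[ShellRecord] = []
    for pdata in sorted(cohort, key=lambda p: p.participant):
        for tract in sorted(pdata.partitions):
            part = pdata.partitions[tract]
            shell_set = pdata.tract_wmh_shells.get(tract)
            if part.has_lesion and shell_set is not None:
                mean_fa, n = shell_mean(part.tract_wmh, pdata.fa)
                mean_md, _ = shell_mean(part.tract_wmh, pdata.md)
                records.append(
                    ShellRecord(pdata.participant, tract, "tract_wmh", 0, n, mean_fa, mean_md)
                )
                for dist, mask in shell_set.shells:
                    mean_fa, n = shell_mean(mask, pdata.fa)
                    mean_md, _ = shell_mean(mask, pdata.md)
                    records.append(
                        ShellRecord(
                            pdata.participant, tract, "tract_wmh", int(round(dist)), n, mean_fa, mean_md
                        )
                    )
            near_sets = pdata.nearby_shells.get(tract, [])
            if near_sets:
                distances = near_sets[0].distances_mm
                for dist in distances:
                    fa_entries = []
                    md_entries = []
                    for ss in near_sets:
                        mask = dict(ss.shells)[dist]
                        fa_entries.append(shell_mean(mask, pdata.fa))
                        md_entries.append(shell_mean(mask, pdata.md))
                    mean_fa, n = _pooled(fa_entries)
                    mean_md, _ = _pooled(md_entries)
                    records.append(
                        ShellRecord(
                            pdata.participant, tract, "nearby", int(round(dist)), n, mean_fa, mean_md
                        )
                    )
    return records


def apply_csf_exclusion(
    records: Sequence[ShellRecord], md_threshold: float = CSF_MD_THRESHOLD
) -> list[ShellRecord]:
    """Flag records whose mean MD strictly exceeds ``md_threshold``.

    The flag applies to the whole contour (both FA and MD analyses);
    records at exactly the threshold are retained. Idempotent.
    """
    out = []
    for rec in records:
        excluded = rec.mean_md is not None and rec.mean_md > md_threshold
        if excluded != rec.excluded_csf:
            rec = ShellRecord(
                rec.participant,
                rec.tract,
                rec.wmh_type,
                rec.distance_mm,
                rec.n_voxels,
                rec.mean_fa,
                rec.mean_md,
                excluded_csf=excluded,
            )
        out.append(rec)
    return out
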