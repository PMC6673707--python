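"""Tract-lesion geometry: partition, distance shells, nearby lesions.

A tract mask is partitioned against the WMH and NAWM masks into its
lesioned (tract-WMH) and normal-appearing (tract-NAWM) parts. Around the
tract-WMH seed, concentric shells are grown by repeated one-voxel binary
dilation (2 mm per step on the nominal isotropic grid) and restricted to
the tract-NAWM, giving approximately equidistant contours at 2..10 mm.
The same construction is applied to lesions that do not touch the tract
but whose 2-10 mm shells reach it ("nearby" lesions), with voxels already
claimed by a tract-WMH contour excluded.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .volume_io import MaskVolume, assert_common_grid

__all__ = [
    "TractPartition",
    "ShellSet",
    "GeometryError",
    "PlacementError",
    "binarize_tract",
    "partition_tract",
    "dilate_step",
    "build_tract_wmh_shells",
    "find_nearby_wmh",
    "build_nearby_shells",
    "DEFAULT_N_SHELLS",
    "DEFAULT_SHELL_STEP_MM",
    "TRACT_PROBABILITY_THRESHOLD",
]

DEFAULT_N_SHELLS = 5
DEFAULT_SHELL_STEP_MM = 2.0
#: Posterior-probability cut applied before binarizing tract maps (strict >).
TRACT_PROBABILITY_THRESHOLD = 0.01


class GeometryError(ValueError):
    """Geometry precondition violated (e.g. anisotropic grid)."""


class PlacementError(RuntimeError):
    """Synthetic lesion placement could not satisfy its constraints."""


def _structure(connectivity: int) -> np.ndarray:
    if connectivity == 6:
        return ndimage.generate_binary_structure(3, 1)
    if connectivity == 18:
        return ndimage.generate_binary_structure(3, 2)
    if connectivity == 26:
        return ndimage.generate_binary_structure(3, 3)
    raise ValueError(f"connectivity must be 6, 18 or 26, got {connectivity}")


@dataclass(frozen=True)
class TractPartition:
    """A tract mask split into its WMH-intersecting and NAWM parts.

    ``pct_wmh_vol`` is 100 * |tract-WMH| / (|tract-WMH| + |tract-NAWM|),
    or ``None`` when the tract meets neither mask. Tract voxels in
    neither mask (e.g. CSF-adjacent) belong to neither part.
    """

    tract_name: str
    tract_mask: MaskVolume = field(repr=False)
    tract_wmh: MaskVolume = field(repr=False)
    tract_nawm: MaskVolume = field(repr=False)
    pct_wmh_vol: float | None

    def __post_init__(self) -> None:
        t, w, n = self.tract_mask.data, self.tract_wmh.data, self.tract_nawm.data
        if (w & ~t).any() or (n & ~t).any():
            raise ValueError("partition parts must be subsets of the tract mask")
        if (w & n).any():
            raise ValueError("tract-WMH and tract-NAWM must be disjoint")

    @property
    def has_lesion(self) -> bool:
        return bool(self.tract_wmh.data.any())


@dataclass(frozen=True)
class ShellSet:
    """Ordered equidistant shells grown from a seed mask.

    ``shells`` maps each distance (mm) to the contour mask at that
    distance; shells are pairwise disjoint and restricted to the tract's
    NAWM. Empty shells are retained (downstream stats drop them).
    """

    source_type: str  # {'tract_wmh', 'nearby_wmh'}
    seed_mask: MaskVolume = field(repr=False)
    shells: tuple[tuple[float, MaskVolume], ...] = field(repr=False, default=())

    def __post_init__(self) -> None:
        if self.source_type not in ("tract_wmh", "nearby_wmh"):
            raise ValueError(f"bad source_type {self.source_type!r}")
        dists = [d for d, _ in self.shells]
        if any(b <= a for a, b in zip(dists, dists[1:])):
            raise ValueError("shell distances must be strictly increasing")
        union = np.zeros(self.seed_mask.grid.shape, dtype=bool)
        for _, shell in self.shells:
            if (shell.data & union).any():
                raise ValueError("shells must be pairwise disjoint")
            union |= shell.data

    @property
    def distances_mm(self) -> tuple[float, ...]:
        return tuple(d for d, _ in self.shells)

    def union_mask(self) -> MaskVolume:
        union = np.zeros(self.seed_mask.grid.shape, dtype=bool)
        for _, shell in self.shells:
            union |= shell.data
        return MaskVolume(self.seed_mask.grid, union)


def binarize_tract(prob_map, threshold: float = TRACT_PROBABILITY_THRESHOLD) -> MaskVolume:
    """Binarize a tract posterior-probability map at ``threshold`` (strict >)."""
    if not 0.0 < threshold < 1.0:
        raise ValueError(f"threshold must be in (0, 1), got {threshold}")
    data = np.asarray(prob_map.data, dtype=float)
    if data.min() < 0.0 or data.max() > 1.0:
        raise ValueError("probability map values outside [0, 1]")
    return MaskVolume(prob_map.grid, data > threshold)


def partition_tract(
    tract_mask: MaskVolume,
    wmh_mask: MaskVolume,
    nawm_mask: MaskVolume,
    tract_name: str = "tract",
) -> TractPartition:
    """Split ``tract_mask`` into its WMH intersection and NAWM intersection."""
    assert_common_grid([tract_mask, wmh_mask, nawm_mask])
    t = tract_mask.data
    tw = t & wmh_mask.data
    tn = t & nawm_mask.data & ~wmh_mask.data
    n_w, n_n = int(tw.sum()), int(tn.sum())
    pct = 100.0 * n_w / (n_w + n_n) if (n_w + n_n) > 0 else None
    grid = tract_mask.grid
    return TractPartition(
        tract_name=tract_name,
        tract_mask=tract_mask,
        tract_wmh=MaskVolume(grid, tw),
        tract_nawm=MaskVolume(grid, tn),
        pct_wmh_vol=pct,
    )


def _check_isotropic(mask: MaskVolume, allow_anisotropic: bool) -> None:
    if not mask.grid.is_isotropic:
        if not allow_anisotropic:
            raise GeometryError(
                f"anisotropic voxel size {mask.grid.voxel_size_mm}; one dilation "
                "step equals one voxel only on isotropic grids "
                "(pass allow_anisotropic=True to override)"
            )
        warnings.warn(
            "anisotropic grid: one dilation step means one voxel; reported "
            "distances use the maximum voxel dimension",
            stacklevel=3,
        )


def dilate_step(
    mask: MaskVolume,
    connectivity: int = 26,
    allow_anisotropic: bool = False,
) -> MaskVolume:
    """One-voxel binary dilation (the 2 mm increment on the nominal grid)."""
    _check_isotropic(mask, allow_anisotropic)
    out = ndimage.binary_dilation(mask.data, structure=_structure(connectivity))
    return MaskVolume(mask.grid, out)


def _shell_step_mm(mask: MaskVolume) -> float:
    # on anisotropic grids (override path) the reported step is the max dim
    return float(max(mask.grid.voxel_size_mm))


def _grow_shells(
    seed: np.ndarray,
    keep: np.ndarray,
    exclude: np.ndarray | None,
    n_shells: int,
    connectivity: int,
    step_mm: float,
) -> list[tuple[float, np.ndarray]]:
    structure = _structure(connectivity)
    shells = []
    prev = seed
    for k in range(1, n_shells + 1):
        grown = ndimage.binary_dilation(prev, structure=structure)
        band = grown & ~prev & keep
        if exclude is not None:
            band = band & ~exclude
        shells.append((step_mm * k, band))
        prev = grown
    return shells


def build_tract_wmh_shells(
    partition: TractPartition,
    n_shells: int = DEFAULT_N_SHELLS,
    connectivity: int = 26,
    allow_anisotropic: bool = False,
) -> ShellSet:
    """Equidistant contours around the tract-WMH, inside the tract-NAWM.

    Shell k is the k-step dilation of the tract-WMH seed minus the
    (k-1)-step dilation, intersected with the tract-NAWM. With an empty
    seed (no lesion in this tract) all shells are empty.
    """
    grid = partition.tract_mask.grid
    seed = partition.tract_wmh
    _check_isotropic(seed, allow_anisotropic)
    step = _shell_step_mm(seed)
    if not partition.has_lesion:
        shells = tuple(
            (step * k, MaskVolume(grid, np.zeros(grid.shape, dtype=bool)))
            for k in range(1, n_shells + 1)
        )
        return ShellSet(source_type="tract_wmh", seed_mask=seed, shells=shells)
    bands = _grow_shells(
        seed.data, partition.tract_nawm.data, None, n_shells, connectivity, step
    )
    shells = tuple((d, MaskVolume(grid, b)) for d, b in bands)
    return ShellSet(source_type="tract_wmh", seed_mask=seed, shells=shells)


def find_nearby_wmh(
    wmh_mask: MaskVolume,
    partition: TractPartition,
    component_connectivity: int = 26,
    max_steps: int = DEFAULT_N_SHELLS,
    allow_anisotropic: bool = False,
) -> list[MaskVolume]:
    """Connected WMH components near, but not touching, the tract.

    A component is *nearby* for this tract when it shares no voxel with
    the tract mask and its ``max_steps``-step dilation (the union of its
    2-10 mm shells) reaches the tract's NAWM. Components are returned in
    deterministic order (component centroid, then first voxel index).
    """
    assert_common_grid([wmh_mask, partition.tract_mask])
    _check_isotropic(wmh_mask, allow_anisotropic)
    labels, n_comp = ndimage.label(wmh_mask.data, structure=_structure(component_connectivity))
    grid = wmh_mask.grid
    dil_structure = _structure(26)
    keyed: list[tuple[tuple, MaskVolume]] = []
    tract = partition.tract_mask.data
    tnawm = partition.tract_nawm.data
    for lab in range(1, n_comp + 1):
        comp = labels == lab
        if (comp & tract).any():
            continue  # intersecting for this tract, not nearby
        reach = ndimage.binary_dilation(comp, structure=dil_structure, iterations=max_steps)
        if not (reach & tnawm).any():
            continue
        idx = np.argwhere(comp)
        centroid = tuple(idx.mean(axis=0))
        first = tuple(int(v) for v in idx[0])
        keyed.append(((centroid, first), MaskVolume(grid, comp)))
    keyed.sort(key=lambda kv: kv[0])
    return [m for _, m in keyed]


def build_nearby_shells(
    nearby_component: MaskVolume,
    partition: TractPartition,
    tract_wmh_shell_union: MaskVolume | None,
    wmh_mask: MaskVolume | None = None,
    n_shells: int = DEFAULT_N_SHELLS,
    connectivity: int = 26,
    allow_anisotropic: bool = False,
) -> ShellSet:
    """Contours around a nearby lesion, excluding tract-WMH contour voxels.

    The seed lesion itself is never measured (no distance-0 entry): its
    diffusion values are not attributable to the tract under study.
    ``wmh_mask``, when given, is additionally subtracted so shells can
    never contain lesion voxels even if the NAWM mask overlaps the WMH.
    """
    _check_isotropic(nearby_component, allow_anisotropic)
    grid = nearby_component.grid
    exclude = np.zeros(grid.shape, dtype=bool)
    if tract_wmh_shell_union is not None:
        exclude |= tract_wmh_shell_union.data
    if wmh_mask is not None:
        exclude |= wmh_mask.data
    step = _shell_step_mm(nearby_component)
    bands = _grow_shells(
        nearby_component.data,
        partition.tract_nawm.data,
        exclude,
        n_shells,
        connectivity,
        step,
    )
    shells = tuple((d, MaskVolume(grid, b)) for d, b in bands)
    return ShellSet(source_type="nearby_wmh", seed_mask=nearby_component, shells=shells)
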