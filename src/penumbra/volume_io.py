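"""NIfTI volume I/O and the common-grid contract.

All geometry downstream assumes every per-participant volume (tract
probability maps, WMH/NAWM masks, FA/MD maps) lives on one voxel grid.
This module reads typed volumes, validates them, and enforces that
contract, and reads/writes the long-format shell-record table.
"""

from __future__ import annotations

import dataclasses
import math
import os
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import nibabel as nib
import numpy as np
import pandas as pd

__all__ = [
    "VolumeGrid",
    "MaskVolume",
    "ScalarVolume",
    "ShellRecord",
    "GridMismatchError",
    "VolumeValidationError",
    "read_volume",
    "write_volume",
    "assert_common_grid",
    "write_records",
    "read_records",
    "RECORD_COLUMNS",
]

#: Fixed column order of the long-format table (deterministic diffs).
RECORD_COLUMNS = (
    "participant",
    "tract",
    "wmh_type",
    "distance_mm",
    "n_voxels",
    "mean_fa",
    "mean_md",
    "excluded_csf",
)

VOXEL_SIZE_ATOL_MM = 1e-3


class VolumeValidationError(ValueError):
    """A volume's data violates the contract for its declared kind."""


class GridMismatchError(ValueError):
    """Volumes expected on one grid differ in shape or voxel size."""


@dataclass(frozen=True)
class VolumeGrid:
    """Voxel grid shared by all volumes of one participant.

    Parameters
    ----------
    shape : tuple of 3 int
        Number of voxels along each axis.
    voxel_size_mm : tuple of 3 float
        Voxel edge lengths in millimetres.
    affine : ndarray, shape (4, 4)
        Voxel-index to world-mm mapping.
    """

    shape: tuple[int, int, int]
    voxel_size_mm: tuple[float, float, float]
    affine: np.ndarray = field(repr=False, default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        shape = tuple(int(s) for s in self.shape)
        vox = tuple(float(v) for v in self.voxel_size_mm)
        if len(shape) != 3 or any(s < 1 for s in shape):
            raise VolumeValidationError(f"grid shape must be 3 positive ints, got {self.shape}")
        if len(vox) != 3 or any(not math.isfinite(v) or v <= 0 for v in vox):
            raise VolumeValidationError(f"voxel sizes must be positive, got {self.voxel_size_mm}")
        affine = self.affine
        if affine is None:
            affine = np.diag([vox[0], vox[1], vox[2], 1.0])
        affine = np.asarray(affine, dtype=float)
        if affine.shape != (4, 4):
            raise VolumeValidationError(f"affine must be 4x4, got shape {affine.shape}")
        if abs(np.linalg.det(affine[:3, :3])) <= 0.0:
            raise VolumeValidationError("affine upper-left 3x3 block is singular")
        object.__setattr__(self, "shape", shape)
        object.__setattr__(self, "voxel_size_mm", vox)
        object.__setattr__(self, "affine", affine)

    @property
    def is_isotropic(self) -> bool:
        v = self.voxel_size_mm
        return (
            abs(v[0] - v[1]) <= VOXEL_SIZE_ATOL_MM
            and abs(v[1] - v[2]) <= VOXEL_SIZE_ATOL_MM
        )

    def compatible_with(self, other: "VolumeGrid") -> bool:
        return self.shape == other.shape and all(
            abs(a - b) <= VOXEL_SIZE_ATOL_MM
            for a, b in zip(self.voxel_size_mm, other.voxel_size_mm)
        )


@dataclass(frozen=True)
class MaskVolume:
    """Binary 3D label volume on a :class:`VolumeGrid`."""

    grid: VolumeGrid
    data: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        data = np.asarray(self.data)
        if data.shape != self.grid.shape:
            raise VolumeValidationError(
                f"mask shape {data.shape} != grid shape {self.grid.shape}"
            )
        if data.dtype != bool:
            uniq = np.unique(data)
            if not np.isin(uniq, (0, 1)).all():
                raise VolumeValidationError(
                    f"mask values must be 0/1, found values {uniq[:5]!r}"
                )
            data = data.astype(bool)
        object.__setattr__(self, "data", data)

    @property
    def n_foreground(self) -> int:
        return int(self.data.sum())

    def with_data(self, data: np.ndarray) -> "MaskVolume":
        return MaskVolume(self.grid, data)


@dataclass(frozen=True)
class ScalarVolume:
    """Floating-point 3D volume (FA, MD, or tract probability map)."""

    grid: VolumeGrid
    data: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        data = np.asarray(self.data, dtype=float)
        if data.shape != self.grid.shape:
            raise VolumeValidationError(
                f"scalar shape {data.shape} != grid shape {self.grid.shape}"
            )
        object.__setattr__(self, "data", data)


@dataclass(frozen=True)
class ShellRecord:
    """One measured contour: participant x tract x WMH type x distance.

    ``distance_mm`` 0 denotes the tract-WMH region itself and occurs only
    with ``wmh_type='tract_wmh'``. Means are ``None`` iff the region is
    empty (``n_voxels == 0``).
    """

    participant: str
    tract: str
    wmh_type: str  # {'tract_wmh', 'nearby'}
    distance_mm: int
    n_voxels: int
    mean_fa: float | None
    mean_md: float | None
    excluded_csf: bool = False

    def __post_init__(self) -> None:
        if self.wmh_type not in ("tract_wmh", "nearby"):
            raise ValueError(f"bad wmh_type {self.wmh_type!r}")
        if self.wmh_type == "nearby" and self.distance_mm == 0:
            raise ValueError("distance 0 is not measurable for nearby lesions")
        if (self.n_voxels == 0) != (self.mean_fa is None):
            raise ValueError("mean_fa must be missing iff region is empty")
        if (self.n_voxels == 0) != (self.mean_md is None):
            raise ValueError("mean_md must be missing iff region is empty")


def _grid_from_img(img: nib.Nifti1Image) -> VolumeGrid:
    shape = tuple(int(s) for s in img.shape[:3])
    zooms = tuple(float(z) for z in img.header.get_zooms()[:3])
    return VolumeGrid(shape=shape, voxel_size_mm=zooms, affine=np.asarray(img.affine))


def read_volume(path: str | os.PathLike, kind: str) -> MaskVolume | ScalarVolume:
    """Read a NIfTI file as a typed volume.

    Parameters
    ----------
    path : path-like
        A ``.nii`` or ``.nii.gz`` file.
    kind : {'mask', 'scalar', 'probability'}
        ``mask`` binarizes at 0.5 (absorbs interpolation dust only; genuine
        probability maps must use ``kind='probability'``); ``probability``
        requires values in [0, 1]; ``scalar`` is unvalidated floats.
    """
    if kind not in ("mask", "scalar", "probability"):
        raise ValueError(f"unknown kind {kind!r}")
    try:
        img = nib.load(os.fspath(path))
        data = np.asarray(img.dataobj, dtype=float)
    except Exception as exc:  # noqa: BLE001 - surface as I/O error
        raise IOError(f"cannot read NIfTI volume {path!r}: {exc}") from exc
    if data.ndim == 4 and data.shape[3] == 1:
        data = data[..., 0]
    if data.ndim != 3:
        raise VolumeValidationError(f"{path}: expected 3D volume, got ndim={data.ndim}")
    grid = _grid_from_img(img)
    if kind == "mask":
        return MaskVolume(grid, data > 0.5)
    if kind == "probability":
        lo, hi = float(np.nanmin(data)), float(np.nanmax(data))
        if lo < 0.0 or hi > 1.0:
            raise VolumeValidationError(
                f"{path}: probability values outside [0, 1] (range [{lo:g}, {hi:g}])"
            )
    if not np.isfinite(data).all():
        raise VolumeValidationError(f"{path}: non-finite values in scalar volume")
    return ScalarVolume(grid, data)


def write_volume(volume: MaskVolume | ScalarVolume, path: str | os.PathLike) -> None:
    """Write a typed volume as NIfTI-1 (masks as uint8, scalars as float64)."""
    data = volume.data
    if isinstance(volume, MaskVolume):
        data = data.astype(np.uint8)
    img = nib.Nifti1Image(data, affine=volume.grid.affine)
    img.header.set_zooms(volume.grid.voxel_size_mm)
    nib.save(img, os.fspath(path))


def assert_common_grid(
    volumes: Sequence[MaskVolume | ScalarVolume],
) -> VolumeGrid:
    """Return the shared grid of ``volumes`` or raise :class:`GridMismatchError`.

    Shapes must match exactly; voxel sizes within 1e-3 mm. The returned
    grid is that of the first volume.
    """
    if not volumes:
        raise ValueError("assert_common_grid requires at least one volume")
    ref = volumes[0].grid
    problems = []
    for i, vol in enumerate(volumes[1:], start=1):
        g = vol.grid
        if g.shape != ref.shape:
            problems.append(f"volume {i}: shape {g.shape} != {ref.shape}")
        for ax, (a, b) in enumerate(zip(g.voxel_size_mm, ref.voxel_size_mm)):
            if abs(a - b) > VOXEL_SIZE_ATOL_MM:
                problems.append(
                    f"volume {i}: voxel_size_mm[{ax}] {a:g} != {b:g} (tol {VOXEL_SIZE_ATOL_MM})"
                )
    if problems:
        raise GridMismatchError("grid mismatch: " + "; ".join(problems))
    return ref


def records_to_frame(records: Iterable[ShellRecord]) -> pd.DataFrame:
    rows = [dataclasses.asdict(r) for r in records]
    df = pd.DataFrame(rows, columns=list(RECORD_COLUMNS))
    return df


def write_records(records: Iterable[ShellRecord], path: str | os.PathLike) -> None:
    """Write records as a CSV table with the fixed column order.

    Missing means are encoded as empty fields; the table round-trips
    losslessly through :func:`read_records`.
    """
    df = records_to_frame(records)
    df.to_csv(path, index=False, float_format="%.17g")


def read_records(path: str | os.PathLike) -> list[ShellRecord]:
    """Read a table written by :func:`write_records` back into records."""
    df = pd.read_csv(
        path,
        dtype={"participant": str, "tract": str, "wmh_type": str},
    )
    missing = [c for c in RECORD_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: table lacks columns {missing}")
    out = []
    for row in df.itertuples(index=False):
        out.append(
            ShellRecord(
                participant=str(row.participant),
                tract=str(row.tract),
                wmh_type=str(row.wmh_type),
                distance_mm=int(row.distance_mm),
                n_voxels=int(row.n_voxels),
                mean_fa=None if pd.isna(row.mean_fa) else float(row.mean_fa),
                mean_md=None if pd.isna(row.mean_md) else float(row.mean_md),
                excluded_csf=bool(row.excluded_csf),
            )
        )
    return out
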