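"""Shared fixtures and independent oracles for the test suite."""

from __future__ import annotations

import numpy as np
import pytest

from penumbra.volume_io import MaskVolume, ScalarVolume, ShellRecord, VolumeGrid


def chebyshev_distance_bruteforce(seed: np.ndarray) -> np.ndarray:
    """Brute-force Chebyshev distance to a seed mask (independent oracle).

    For every voxel, the minimum over seed voxels of the max absolute
    coordinate difference. O(n_voxels * n_seed); only for small grids.
    """
    seed = np.asarray(seed, dtype=bool)
    seed_idx = np.argwhere(seed)
    if len(seed_idx) == 0:
        return np.full(seed.shape, np.iinfo(np.int64).max)
    all_idx = np.indices(seed.shape).reshape(3, -1).T
    d = np.abs(all_idx[:, None, :] - seed_idx[None, :, :]).max(axis=2).min(axis=1)
    return d.reshape(seed.shape)


def make_grid(shape=(16, 16, 16), voxel=2.0) -> VolumeGrid:
    return VolumeGrid(shape=shape, voxel_size_mm=(voxel, voxel, voxel))


def mask_from_indices(grid: VolumeGrid, indices) -> MaskVolume:
    data = np.zeros(grid.shape, dtype=bool)
    for idx in indices:
        data[tuple(idx)] = True
    return MaskVolume(grid, data)


def full_mask(grid: VolumeGrid, value: bool = True) -> MaskVolume:
    return MaskVolume(grid, np.full(grid.shape, value, dtype=bool))


def constant_scalar(grid: VolumeGrid, value: float) -> ScalarVolume:
    return ScalarVolume(grid, np.full(grid.shape, value, dtype=float))


def make_record(
    participant="p1",
    tract="t1",
    wmh_type="tract_wmh",
    distance_mm=2,
    n_voxels=10,
    mean_fa=0.3,
    mean_md=8e-4,
    excluded_csf=False,
) -> ShellRecord:
    return ShellRecord(
        participant, tract, wmh_type, distance_mm, n_voxels, mean_fa, mean_md, excluded_csf
    )


@pytest.fixture
def grid16():
    return make_grid((16, 16, 16))


@pytest.fixture
def rng():
    return np.random.default_rng(20240915)


def simulate_records(
    n_participants: int,
    b0: float,
    b1: float,
    seed: int,
    n_tracts: int = 1,
    sd_p_intercept: float = 0.0,
    sd_p_slope: float = 0.0,
    sd_t_intercept: float = 0.0,
    sd_t_slope: float = 0.0,
    noise_sd: float = 0.0,
    nearby_offset: float | None = None,
    nearby_slope_delta: float = 0.0,
    outcome: str = "fa",
) -> list[ShellRecord]:
    """Record-level simulation of the planted model (no imaging involved).

    An independent data generator for the model module: draws random
    intercepts/slopes per participant and tract, evaluates the planted
    log-distance curve at 0-10 mm (2-10 mm for nearby records when
    ``nearby_offset`` is not None), and adds record-level noise.
    """
    rng = np.random.default_rng(seed)
    tract_fx = {
        f"t{j}": (rng.normal(0, sd_t_intercept), rng.normal(0, sd_t_slope))
        for j in range(n_tracts)
    }
    records = []
    for i in range(n_participants):
        u0, u1 = rng.normal(0, sd_p_intercept), rng.normal(0, sd_p_slope)
        for tract, (v0, v1) in tract_fx.items():
            for d in (0, 2, 4, 6, 8, 10):
                y = (b0 + u0 + v0) + (b1 + u1 + v1) * np.log1p(d) + rng.normal(0, noise_sd)
                records.append(_rec(f"p{i}", tract, "tract_wmh", d, y, outcome))
            if nearby_offset is not None:
                for d in (2, 4, 6, 8, 10):
                    y = (
                        (b0 + u0 + v0 + nearby_offset)
                        + (b1 + u1 + v1 + nearby_slope_delta) * np.log1p(d)
                        + rng.normal(0, noise_sd)
                    )
                    records.append(_rec(f"p{i}", tract, "nearby", d, y, outcome))
    return records


def _rec(pid, tract, wtype, d, y, outcome) -> ShellRecord:
    from penumbra.models import MD_FIT_SCALE

    y = float(y)
    if outcome == "fa":
        return ShellRecord(pid, tract, wtype, d, 10, y, 8e-4)
    return ShellRecord(pid, tract, wtype, d, 10, 0.3, y / MD_FIT_SCALE)
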