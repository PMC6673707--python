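import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from penumbra.geometry import (
    GeometryError,
    ShellSet,
    binarize_tract,
    build_nearby_shells,
    build_tract_wmh_shells,
    dilate_step,
    find_nearby_wmh,
    partition_tract,
)
from penumbra.volume_io import MaskVolume, ScalarVolume, VolumeGrid

from conftest import chebyshev_distance_bruteforce, full_mask, make_grid, mask_from_indices


class TestBinarizeTract:
    def test_strict_threshold(self, grid16):
        data = np.zeros(grid16.shape)
        data[0, 0, :5] = [0, 0.005, 0.01, 0.011, 0.9]
        mask = binarize_tract(ScalarVolume(grid16, data), threshold=0.01)
        assert mask.n_foreground == 2  # 0.01 itself is excluded

    def test_all_zero(self, grid16):
        mask = binarize_tract(ScalarVolume(grid16, np.zeros(grid16.shape)))
        assert mask.n_foreground == 0

    def test_identity_on_binary_map(self, grid16, rng):
        data = (rng.random(grid16.shape) > 0.5).astype(float)
        mask = binarize_tract(ScalarVolume(grid16, data), threshold=0.5)
        assert np.array_equal(mask.data, data.astype(bool))

    def test_rejects_bad_threshold(self, grid16):
        with pytest.raises(ValueError):
            binarize_tract(ScalarVolume(grid16, np.zeros(grid16.shape)), threshold=1.5)


class TestPartitionTract:
    def test_ten_percent(self, grid16):
        tract = np.zeros(grid16.shape, bool)
        tract.flat[:100] = True
        wmh = np.zeros(grid16.shape, bool)
        wmh.flat[:10] = True
        nawm = tract & ~wmh
        part = partition_tract(
            MaskVolume(grid16, tract), MaskVolume(grid16, wmh), MaskVolume(grid16, nawm)
        )
        assert part.pct_wmh_vol == pytest.approx(10.0)
        assert part.tract_wmh.n_foreground == 10
        assert part.tract_nawm.n_foreground == 90

    def test_disjoint_wmh(self, grid16):
        tract = mask_from_indices(grid16, [(1, 1, 1), (1, 1, 2)])
        wmh = mask_from_indices(grid16, [(10, 10, 10)])
        nawm = full_mask(grid16)
        part = partition_tract(tract, wmh, nawm)
        assert part.tract_wmh.n_foreground == 0
        assert part.pct_wmh_vol == 0.0
        assert not part.has_lesion

    def test_neither_mask_undefined(self, grid16):
        tract = mask_from_indices(grid16, [(1, 1, 1)])
        empty = mask_from_indices(grid16, [])
        part = partition_tract(tract, empty, empty)
        assert part.pct_wmh_vol is None

    @settings(max_examples=20, deadline=None)
    @given(seed=st.integers(0, 10**6))
    def test_partition_conservation(self, seed):
        grid = make_grid((10, 10, 10))
        rng = np.random.default_rng(seed)
        tract = rng.random(grid.shape) > 0.6
        wmh = rng.random(grid.shape) > 0.8
        nawm = (rng.random(grid.shape) > 0.4) & ~wmh
        part = partition_tract(
            MaskVolume(grid, tract), MaskVolume(grid, wmh), MaskVolume(grid, nawm)
        )
        neither = tract & ~(part.tract_wmh.data | part.tract_nawm.data)
        total = part.tract_wmh.n_foreground + part.tract_nawm.n_foreground + int(neither.sum())
        assert total == int(tract.sum())
        assert not (part.tract_wmh.data & part.tract_nawm.data).any()


class TestDilateStep:
    def test_single_voxel_26(self):
        grid = make_grid((9, 9, 9))
        out = dilate_step(mask_from_indices(grid, [(4, 4, 4)]), connectivity=26)
        assert out.n_foreground == 27

    def test_single_voxel_6(self):
        grid = make_grid((9, 9, 9))
        out = dilate_step(mask_from_indices(grid, [(4, 4, 4)]), connectivity=6)
        assert out.n_foreground == 7

    def test_superset_of_input(self, grid16, rng):
        mask = MaskVolume(grid16, rng.random(grid16.shape) > 0.9)
        out = dilate_step(mask)
        assert (mask.data <= out.data).all()

    @pytest.mark.parametrize("k", [1, 2, 3])
    def test_repeated_dilation_is_chebyshev_ball(self, k):
        # brute-force oracle on grids <= 21^3
        grid = make_grid((21, 21, 21))
        mask = mask_from_indices(grid, [(10, 10, 10)])
        out = mask
        for _ in range(k):
            out = dilate_step(out, connectivity=26)
        oracle = chebyshev_distance_bruteforce(mask.data) <= k
        assert np.array_equal(out.data, oracle)

    def test_anisotropic_refused(self):
        g = VolumeGrid(shape=(5, 5, 5), voxel_size_mm=(1, 1, 4))
        mask = MaskVolume(g, np.zeros((5, 5, 5), bool))
        with pytest.raises(GeometryError):
            dilate_step(mask)
        with pytest.warns(UserWarning):
            dilate_step(mask, allow_anisotropic=True)

    def test_bad_connectivity(self, grid16):
        with pytest.raises(ValueError):
            dilate_step(MaskVolume(grid16, np.zeros(grid16.shape, bool)), connectivity=4)


def _uniform_partition(grid, seed_indices):
    """All-tract, all-NAWM grid with a given tract-WMH seed."""
    wmh = mask_from_indices(grid, seed_indices)
    tract = full_mask(grid)
    nawm = MaskVolume(grid, ~wmh.data)
    return partition_tract(tract, wmh, nawm)


class TestTractWmhShells:
    def test_worked_example_shell_counts(self):
        # single-voxel seed: (2k+1)^3 - (2k-1)^3 voxels per shell
        grid = make_grid((15, 15, 15))
        part = _uniform_partition(grid, [(7, 7, 7)])
        shells = build_tract_wmh_shells(part)
        counts = [m.n_foreground for _, m in shells.shells]
        assert counts == [26, 98, 218, 386, 602]
        assert shells.distances_mm == (2.0, 4.0, 6.0, 8.0, 10.0)

    def test_empty_nawm_gives_empty_shells(self, grid16):
        wmh = mask_from_indices(grid16, [(8, 8, 8)])
        tract = full_mask(grid16)
        nawm = mask_from_indices(grid16, [])
        part = partition_tract(tract, wmh, nawm)
        shells = build_tract_wmh_shells(part)
        assert all(m.n_foreground == 0 for _, m in shells.shells)

    def test_no_lesion_flagged_empty(self, grid16):
        part = partition_tract(
            full_mask(grid16), mask_from_indices(grid16, []), full_mask(grid16)
        )
        shells = build_tract_wmh_shells(part)
        assert all(m.n_foreground == 0 for _, m in shells.shells)

    def test_disjoint_and_exclude_seed(self, rng):
        grid = make_grid((14, 14, 14))
        seeds = [tuple(v) for v in rng.integers(3, 11, size=(4, 3))]
        part = _uniform_partition(grid, seeds)
        shells = build_tract_wmh_shells(part)
        union = np.zeros(grid.shape, bool)
        for _, m in shells.shells:
            assert not (m.data & union).any()
            assert not (m.data & part.tract_wmh.data).any()
            union |= m.data

    @settings(max_examples=20, deadline=None)
    @given(seed=st.integers(0, 10**6))
    def test_shells_match_chebyshev_bands(self, seed):
        # union of shells 1..k equals the Chebyshev band (0, k], brute force
        grid = make_grid((12, 12, 12))
        rng = np.random.default_rng(seed)
        n_seed = rng.integers(1, 6)
        seeds = [tuple(v) for v in rng.integers(0, 12, size=(n_seed, 3))]
        part = _uniform_partition(grid, seeds)
        shells = build_tract_wmh_shells(part)
        dists = chebyshev_distance_bruteforce(part.tract_wmh.data)
        union = np.zeros(grid.shape, bool)
        for k, (_, m) in enumerate(shells.shells, start=1):
            union |= m.data
            assert np.array_equal(union, (dists > 0) & (dists <= k))


class TestFindNearbyWmh:
    def _setup(self, lesion_indices, tract_plane_x=2):
        grid = make_grid((16, 16, 16))
        tract = np.zeros(grid.shape, bool)
        tract[tract_plane_x, :, :] = True
        wmh = mask_from_indices(grid, lesion_indices)
        nawm = MaskVolume(grid, ~wmh.data)
        part = partition_tract(MaskVolume(grid, tract), wmh, nawm)
        return wmh, part

    def test_intersecting_component_not_returned(self):
        wmh, part = self._setup([(2, 8, 8), (3, 8, 8)])
        assert find_nearby_wmh(wmh, part) == []

    def test_component_at_3_voxels_returned(self):
        wmh, part = self._setup([(5, 8, 8)])  # Chebyshev distance 3 from plane
        comps = find_nearby_wmh(wmh, part)
        assert len(comps) == 1
        assert comps[0].n_foreground == 1

    def test_component_at_6_voxels_not_returned(self):
        wmh, part = self._setup([(8, 8, 8)])  # distance 6 > 5 steps
        assert find_nearby_wmh(wmh, part) == []

    def test_deterministic_ordering(self):
        wmh, part = self._setup([(6, 12, 12), (5, 3, 3)])
        comps = find_nearby_wmh(wmh, part)
        assert len(comps) == 2
        # ordered by centroid lexicographic order
        first = np.argwhere(comps[0].data)[0]
        assert tuple(first) == (5, 3, 3)


class TestBuildNearbyShells:
    def test_exclusion_of_tract_contour_voxels(self):
        grid = make_grid((16, 16, 16))
        tract = full_mask(grid)
        wmh = mask_from_indices(grid, [(4, 8, 8), (8, 8, 8)])
        nawm = MaskVolume(grid, ~wmh.data)
        part = partition_tract(tract, wmh, nawm)
        # both lesions intersect the (full) tract; treat the second as the
        # nearby component of a *different* tract occupying only x<6
        tract2 = np.zeros(grid.shape, bool)
        tract2[:6, :, :] = True
        part2 = partition_tract(MaskVolume(grid, tract2), wmh, nawm)
        comp = mask_from_indices(grid, [(8, 8, 8)])
        union = build_tract_wmh_shells(part2).union_mask()
        shells = build_nearby_shells(comp, part2, union, wmh_mask=wmh)
        for _, m in shells.shells:
            assert not (m.data & union.data).any()
            assert not (m.data & wmh.data).any()

    def test_no_exclusion_equals_plain_shells(self):
        grid = make_grid((15, 15, 15))
        comp = mask_from_indices(grid, [(7, 7, 7)])
        wmh = comp
        nawm = MaskVolume(grid, ~wmh.data)
        part = partition_tract(full_mask(grid), wmh, nawm)
        # exclusion empty: seed lesion intersects, so reuse geometry without union
        shells_excl = build_nearby_shells(comp, part, None, wmh_mask=None)
        shells_plain = build_tract_wmh_shells(part)
        for (_, a), (_, b) in zip(shells_excl.shells, shells_plain.shells):
            assert np.array_equal(a.data, b.data)

    def test_first_nonempty_shell_at_gap(self):
        # single-voxel component 2 voxels from a 1-voxel NAWM plane:
        # the 2 mm shell misses the plane, the 4 mm shell reaches it
        grid = make_grid((15, 15, 15))
        tract = np.zeros(grid.shape, bool)
        tract[4, :, :] = True
        comp = mask_from_indices(grid, [(6, 7, 7)])
        nawm = MaskVolume(grid, tract.copy())
        part = partition_tract(
            MaskVolume(grid, tract), mask_from_indices(grid, []), nawm
        )
        shells = build_nearby_shells(comp, part, None)
        counts = [m.n_foreground for _, m in shells.shells]
        assert counts[0] == 0
        assert counts[1] > 0


class TestShellSetInvariants:
    def test_rejects_overlapping_shells(self, grid16):
        a = mask_from_indices(grid16, [(1, 1, 1)])
        with pytest.raises(ValueError, match="disjoint"):
            ShellSet("tract_wmh", a, ((2.0, a), (4.0, a)))

    def test_rejects_nonincreasing_distances(self, grid16):
        a = mask_from_indices(grid16, [(1, 1, 1)])
        b = mask_from_indices(grid16, [(2, 2, 2)])
        with pytest.raises(ValueError, match="increasing"):
            ShellSet("tract_wmh", a, ((4.0, a), (2.0, b)))
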