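import dataclasses

import numpy as np
import pytest

from penumbra.geometry import PlacementError, binarize_tract
from penumbra.synthetic import (
    EffectSDs,
    GradientParams,
    LesionPlan,
    PhantomConfig,
    TractSpec,
    build_cohort,
    default_config,
    generate_cohort,
    load_truth,
    make_tract_probability_map,
    place_lesions,
    synthesize_maps,
)
from penumbra.volume_io import MaskVolume, VolumeGrid

from conftest import chebyshev_distance_bruteforce, make_grid


def straight_spec(grid, radius_mm=4.0, name="t"):
    nx, ny, nz = grid.shape
    return TractSpec(
        name=name,
        control_points=((2.0, ny / 2, nz / 2), (nx - 3.0, ny / 2, nz / 2)),
        radius_mm=radius_mm,
    )


class TestTractProbabilityMap:
    def test_tube_and_centerline(self):
        grid = make_grid((32, 32, 32))
        spec = straight_spec(grid, radius_mm=4.0)
        prob = make_tract_probability_map(spec, grid)
        assert prob.data.min() >= 0.0 and prob.data.max() <= 1.0
        # every centerline voxel is >= 0.9
        for x in range(2, 30):
            assert prob.data[x, 16, 16] >= 0.9
        # support is strictly below 0.01 beyond 2x radius (4 voxels here)
        dist = np.abs(np.arange(32) - 16) * 2.0  # mm from centerline in y
        far = dist > 8.0
        assert (prob.data[16, far, 16] < 0.01).all()

    def test_determinism(self):
        grid = make_grid((24, 24, 24))
        spec = straight_spec(grid)
        a = make_tract_probability_map(spec, grid)
        b = make_tract_probability_map(spec, grid)
        assert np.array_equal(a.data, b.data)

    def test_radius_one_voxel_support_width(self):
        # brute-force distance-to-centerline oracle: support <= 5 voxels across
        grid = make_grid((24, 24, 24))
        spec = straight_spec(grid, radius_mm=2.0)
        prob = make_tract_probability_map(spec, grid)
        support = prob.data > 0.01
        for x in range(3, 21):
            ys = np.where(support[x, :, 12])[0]
            assert ys.max() - ys.min() + 1 <= 5

    def test_centerline_outside_grid_rejected(self):
        grid = make_grid((16, 16, 16))
        spec = TractSpec("t", ((2, 8, 8), (20, 8, 8)), radius_mm=4.0)
        with pytest.raises(ValueError, match="outside"):
            make_tract_probability_map(spec, grid)


def _tract_setup(grid_shape=(32, 32, 24)):
    grid = make_grid(grid_shape)
    spec = straight_spec(grid, radius_mm=5.0)
    prob = make_tract_probability_map(spec, grid)
    tract = binarize_tract(prob)
    interior = np.zeros(grid.shape, bool)
    interior[2:-2, 2:-2, 2:-2] = True
    return grid, tract, MaskVolume(grid, interior)


class TestPlaceLesions:
    def test_intersecting_overlaps_tract(self):
        grid, tract, extent = _tract_setup()
        plan = LesionPlan(n_intersecting_per_tract=1, n_nearby_per_tract=0)
        wmh, lesions = place_lesions(tract, extent, plan, np.random.default_rng(0))
        assert (wmh.data & tract.data).any()
        assert lesions[0].kind == "intersecting"

    def test_nearby_gap_exact(self):
        # fixed 4 mm gap -> min Chebyshev distance to tract is exactly 2 voxels
        grid, tract, extent = _tract_setup()
        plan = LesionPlan(
            n_intersecting_per_tract=0,
            n_nearby_per_tract=1,
            nearby_gap_range_mm=(4.0, 4.0),
        )
        wmh, lesions = place_lesions(tract, extent, plan, np.random.default_rng(1))
        assert not (wmh.data & tract.data).any()
        # independent brute-force all-pairs voxel distance
        lesion_idx = np.argwhere(wmh.data)
        tract_idx = np.argwhere(tract.data)
        d = np.abs(lesion_idx[:, None, :] - tract_idx[None, :, :]).max(axis=2).min()
        assert d == 2

    def test_determinism(self):
        grid, tract, extent = _tract_setup((48, 32, 24))
        plan = LesionPlan(n_intersecting_per_tract=1, n_nearby_per_tract=1)
        a, _ = place_lesions(tract, extent, plan, np.random.default_rng(7))
        b, _ = place_lesions(tract, extent, plan, np.random.default_rng(7))
        assert np.array_equal(a.data, b.data)

    def test_infeasible_plan_raises(self):
        grid, tract, extent = _tract_setup((16, 16, 12))
        plan = LesionPlan(n_intersecting_per_tract=6, n_nearby_per_tract=0, max_attempts=20)
        with pytest.raises(PlacementError):
            place_lesions(tract, extent, plan, np.random.default_rng(2))

    def test_pairwise_disjoint_and_separated(self):
        grid, tract, extent = _tract_setup((48, 32, 24))
        plan = LesionPlan(n_intersecting_per_tract=2, n_nearby_per_tract=0)
        wmh, lesions = place_lesions(tract, extent, plan, np.random.default_rng(3))
        a, b = (l.voxels for l in lesions)
        gap = np.abs(a[:, None, :] - b[None, :, :]).max(axis=2).min()
        assert gap >= plan.min_separation_vox


class TestSynthesizeMaps:
    def _one_lesion(self, grid_shape=(24, 24, 24)):
        grid, tract, extent = _tract_setup(grid_shape)
        plan = LesionPlan(n_intersecting_per_tract=1, n_nearby_per_tract=0)
        wmh, lesions = place_lesions(tract, extent, plan, np.random.default_rng(5), tract_name="t")
        nawm = MaskVolume(grid, extent.data & ~wmh.data)
        return grid, wmh, nawm, lesions

    def test_closed_form_at_2mm(self):
        grid, wmh, nawm, lesions = self._one_lesion()
        cfg = default_config()
        fa, md = synthesize_maps(
            wmh, nawm, lesions, cfg, (0, 0), (0, 0), {}, {}, np.random.default_rng(0)
        )
        dist = chebyshev_distance_bruteforce(wmh.data)
        at2 = nawm.data & (dist == 1)
        expected = 0.30 + 0.024 * np.log(3.0)
        assert np.allclose(fa.data[at2], expected, atol=1e-12)
        assert round(expected, 4) == 0.3264
        assert np.allclose(fa.data[wmh.data], 0.30)

    def test_md_strictly_decreasing(self):
        grid, wmh, nawm, lesions = self._one_lesion()
        cfg = default_config()
        _, md = synthesize_maps(
            wmh, nawm, lesions, cfg, (0, 0), (0, 0), {}, {}, np.random.default_rng(0)
        )
        dist = chebyshev_distance_bruteforce(wmh.data)
        means = []
        for k in range(1, 6):
            sel = nawm.data & (dist == k)
            if sel.any():
                means.append(md.data[sel].mean())
        assert all(a > b for a, b in zip(means, means[1:]))

    def test_noise_determinism(self):
        grid, wmh, nawm, lesions = self._one_lesion()
        cfg = dataclasses.replace(default_config(), fa_noise_sd=0.05, md_noise_sd=1e-5)
        out = [
            synthesize_maps(
                wmh, nawm, lesions, cfg, (0, 0), (0, 0), {}, {}, np.random.default_rng(9)
            )
            for _ in range(2)
        ]
        assert np.array_equal(out[0][0].data, out[1][0].data)
        assert np.array_equal(out[0][1].data, out[1][1].data)

    def test_distance_field_matches_bruteforce(self):
        # planted values decode back to the brute-force Chebyshev distance
        grid, wmh, nawm, lesions = self._one_lesion((20, 20, 20))
        cfg = default_config()
        fa, _ = synthesize_maps(
            wmh, nawm, lesions, cfg, (0, 0), (0, 0), {}, {}, np.random.default_rng(0)
        )
        g = cfg.gradient_params
        dist = chebyshev_distance_bruteforce(wmh.data)
        sel = nawm.data
        d_mm = np.minimum(dist[sel] * 2.0, g.cap_distance_mm)
        expected = g.fa_at_wmh + g.fa_slope * np.log1p(d_mm)
        assert np.allclose(fa.data[sel], expected, atol=1e-12)

    def test_csf_fraction_plants_high_md(self):
        grid, wmh, nawm, lesions = self._one_lesion()
        cfg = dataclasses.replace(default_config(), csf_fraction=0.5)
        _, md = synthesize_maps(
            wmh, nawm, lesions, cfg, (0, 0), (0, 0), {}, {}, np.random.default_rng(0)
        )
        assert (md.data > 1e-3).any()


class TestGenerateCohort:
    def test_file_count_and_layout(self, tmp_path):
        cfg = default_config(n_participants=2, seed=7, n_tracts=1, grid_shape=(24, 24, 16))
        out = generate_cohort(cfg, tmp_path / "cohort")
        dirs = sorted(d for d in out.iterdir() if d.is_dir())
        assert [d.name for d in dirs] == ["sub001", "sub002"]
        for d in dirs:
            assert len(list(d.glob("*.nii"))) == 5  # 1 tract + 4 volumes
        assert (out / "ground_truth.json").exists()

    def test_nawm_wmh_disjoint(self, tmp_path):
        cfg = default_config(n_participants=2, seed=3, grid_shape=(24, 24, 16))
        out = generate_cohort(cfg, tmp_path / "c")
        from penumbra.volume_io import read_volume

        for d in sorted(p for p in out.iterdir() if p.is_dir()):
            wmh = read_volume(d / "wmh_mask.nii", kind="mask")
            nawm = read_volume(d / "nawm_mask.nii", kind="mask")
            assert not (wmh.data & nawm.data).any()
            assert wmh.n_foreground > 0

    def test_ledger_byte_identical(self, tmp_path):
        cfg = default_config(n_participants=2, seed=5, grid_shape=(24, 24, 16))
        a = generate_cohort(cfg, tmp_path / "a")
        b = generate_cohort(cfg, tmp_path / "b")
        assert (a / "ground_truth.json").read_bytes() == (b / "ground_truth.json").read_bytes()

    def test_truth_round_trip(self, tmp_path):
        cfg = default_config(n_participants=1, seed=5, grid_shape=(24, 24, 16))
        out = generate_cohort(cfg, tmp_path / "c")
        truth = load_truth(out / "ground_truth.json")
        assert truth.seed == 5
        assert len(truth.participants) == 1
        assert all(l.kind in ("intersecting", "nearby") for l in truth.participants[0].lesions)


class TestConfigValidation:
    def test_json_round_trip(self):
        cfg = default_config(n_participants=3, seed=11, n_tracts=2)
        back = PhantomConfig.from_json(cfg.to_json())
        assert back == cfg

    def test_rejects_negative_sd(self):
        with pytest.raises(ValueError):
            EffectSDs(sd_participant_intercept=-0.1)

    def test_rejects_bad_fa(self):
        with pytest.raises(ValueError):
            GradientParams(fa_at_wmh=1.5)

    def test_rejects_bad_gap(self):
        with pytest.raises(ValueError):
            LesionPlan(nearby_gap_range_mm=(0.5, 4.0))
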