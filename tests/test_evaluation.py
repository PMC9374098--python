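import numpy as np
import pytest

from protondl.evaluation import (
    DegenerateInputError,
    GammaCriteria,
    compute_dvh,
    dose_diff_histogram,
    evaluate_case,
    gamma_index_3d,
    mse_above_threshold,
)
from protondl.grid import GridSpec, ScalarVolume

from oracles import brute_force_gamma, perturbed_pair, random_dose_blobs


def grid(shape=(24, 24, 8), spacing=(2.0, 2.0, 2.5)):
    return GridSpec(shape, spacing)


def blob_volume(seed=0, shape=(24, 24, 8)):
    g = grid(shape)
    rng = np.random.default_rng(seed)
    return ScalarVolume(g, random_dose_blobs(rng, shape), "dose_gy")


class TestGammaAnalyticLimits:
    def test_identity_pair_all_zero(self):
        v = blob_volume()
        res = gamma_index_3d(v, v.with_values(v.values.copy()))
        assert res.passing_rate == 100.0
        vals = res.gamma_map.values[res.evaluated_mask]
        assert np.all(vals == 0.0)

    def test_uniform_two_percent_scaling_fails_everywhere(self):
        # a uniform field has no gradients to exploit: scaling by +2% leaves
        # every voxel exactly 2 dose tolerances away, so gamma = 2 everywhere
        g = grid()
        ref = ScalarVolume(g, np.full(g.shape, 10.0), "dose_gy")
        ev = ref.with_values(1.02 * ref.values)
        res = gamma_index_3d(ref, ev)
        assert res.passing_rate == 0.0

    def test_exact_one_voxel_translation_passes(self):
        # translate by exactly the distance tolerance along an axis where the
        # spacing is 1 mm: every voxel finds its dose at distance dta
        g = GridSpec((24, 24, 8), (1.0, 2.0, 2.5))
        rng = np.random.default_rng(3)
        ref = ScalarVolume(g, random_dose_blobs(rng, g.shape), "dose_gy")
        ev = ref.with_values(np.roll(ref.values, 1, axis=0))
        res = gamma_index_3d(ref, ev, GammaCriteria(distance_tolerance_mm=1.0))
        # interior voxels all pass; only the wrapped boundary slice may not
        interior = res.gamma_map.values[1:-1][res.evaluated_mask[1:-1]]
        assert np.all(interior <= 1.0 + 1e-9)


class TestGammaAgainstBruteForce:
    def test_matches_exhaustive_search(self):
        g = grid((20, 20, 8))
        rng = np.random.default_rng(7)
        for _ in range(3):
            ref, ev = perturbed_pair(rng, g)
            res = gamma_index_3d(ref, ev)
            bf_vals, bf_pass = brute_force_gamma(ref, ev, GammaCriteria())
            assert res.passing_rate == bf_pass
            mine = res.gamma_map.values[res.evaluated_mask]
            assert np.max(np.abs(mine - bf_vals)) < 1e-3


class TestGammaEdges:
    def test_zero_reference_rejected(self):
        g = grid()
        zero = ScalarVolume(g, np.zeros(g.shape), "dose_gy")
        with pytest.raises(DegenerateInputError):
            gamma_index_3d(zero, zero)

    def test_grid_mismatch_rejected(self):
        from protondl.grid import GridMismatchError

        a = blob_volume()
        b = ScalarVolume(GridSpec(a.grid.shape, (1.0, 2.0, 2.5)), a.values.copy())
        with pytest.raises(GridMismatchError):
            gamma_index_3d(a, b)

    def test_invalid_criteria_rejected(self):
        with pytest.raises(ValueError):
            GammaCriteria(dose_tolerance_fraction=0.0)
        with pytest.raises(ValueError):
            GammaCriteria(search_radius_mm=1.0)

    def test_local_normalization_stricter_in_low_dose(self):
        g = grid()
        rng = np.random.default_rng(5)
        ref, ev = perturbed_pair(rng, g)
        glob = gamma_index_3d(ref, ev, GammaCriteria(normalization="global"))
        loc = gamma_index_3d(ref, ev, GammaCriteria(normalization="local"))
        assert loc.passing_rate <= glob.passing_rate


class TestMSE:
    def test_identical_is_zero(self):
        v = blob_volume()
        assert mse_above_threshold(v, v) == 0.0

    def test_constant_offset_inside_mask(self):
        v = blob_volume()
        ev = v.with_values(v.values + 0.5)
        assert mse_above_threshold(v, ev) == pytest.approx(0.25)


class TestDVH:
    def test_uniform_dose_step_curve(self):
        g = grid()
        dose = ScalarVolume(g, np.full(g.shape, 5.0), "dose_gy")
        mask = np.zeros(g.shape, bool)
        mask[4:10, 4:10, 2:5] = True
        curve = compute_dvh(dose, mask, bin_width_gy=0.5)
        assert curve.volume_at(4.9) == 100.0
        assert curve.volume_at(5.6) == 0.0

    def test_monotone_nonincreasing(self):
        v = blob_volume()
        mask = v.values > 0.2
        curve = compute_dvh(v, mask)
        assert np.all(np.diff(curve.volume_fraction_pct) <= 1e-12)

    def test_empty_mask_rejected(self):
        v = blob_volume()
        with pytest.raises(ValueError):
            compute_dvh(v, np.zeros(v.grid.shape, bool))


class TestDiffHistogram:
    def test_identical_volumes_no_qualifying_voxels(self):
        v = blob_volume()
        hist = dose_diff_histogram(v, v)
        assert hist.n_qualifying == 0

    def test_counts_known_perturbation(self):
        g = grid()
        vals = np.full(g.shape, 10.0)
        ref = ScalarVolume(g, vals, "dose_gy")
        cand = vals.copy()
        cand[0:2, 0:2, 0:2] += 1.0  # 8 voxels off by 10% of max
        hist = dose_diff_histogram(ScalarVolume(g, cand, "dose_gy"), ref)
        assert hist.n_qualifying == 8


class TestEvaluateCase:
    def test_report_structure_and_files(self, tmp_path, tiny_case):
        converted = tiny_case.pb_composite
        report = evaluate_case(tiny_case, converted, out_dir=tmp_path / "out")
        assert set(report) >= {"case_id", "site", "pb_vs_mc", "converted_vs_mc"}
        # converted == PB here, so both halves must agree exactly
        assert (
            report["pb_vs_mc"]["gamma_passing_rate_pct"]
            == report["converted_vs_mc"]["gamma_passing_rate_pct"]
        )
        out = tmp_path / "out"
        for name in ("report.json", "metrics.csv", "dvh.png",
                     "gamma_pb_vs_mc.nii.gz", "gamma_converted_vs_mc.nii.gz"):
            assert (out / name).exists()
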