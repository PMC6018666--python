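import numpy as np
import pytest

from loopbind.nmr import (PRESeries, RelaxationSeries, ShiftTable, combined_csp,
                          compare_pre_profiles, fit_relaxation,
                          gamma2_from_distance, gamma2_from_ratio, pre_constant,
                          pre_distance, ratio_from_gamma2)
from loopbind.synth import T1_DELAYS_MS


def shift_table(res, h, n, state="free", broadened=None):
    return ShiftTable(res_id=np.array(res), shift_h=np.array(h, float),
                      shift_n=np.array(n, float), state=state,
                      broadened=None if broadened is None else np.array(broadened))


class TestCSP:
    def test_identical_tables_zero(self):
        t = shift_table([1, 2, 3], [8.1, 8.2, 8.3], [118, 120, 122])
        result = combined_csp(t, t)
        np.testing.assert_allclose(result["csp_ppm"], 0.0)

    def test_weighting_formula(self):
        free = shift_table([1], [8.0], [120.0])
        bound = shift_table([1], [8.1], [120.5], state="bound")
        result = combined_csp(free, bound, alpha=0.2)
        assert result["csp_ppm"][0] == pytest.approx(np.sqrt(0.01 + 0.01), rel=1e-9)

    def test_random_tables_match_formula(self):
        rng = np.random.default_rng(0)
        res = np.arange(1, 31)
        free = shift_table(res, 8 + rng.normal(size=30) * 0.3,
                           120 + rng.normal(size=30) * 3)
        bound = shift_table(res, free.shift_h + rng.normal(size=30) * 0.1,
                            free.shift_n + rng.normal(size=30) * 1.0, "bound")
        result = combined_csp(free, bound, alpha=0.2)
        expected = np.sqrt((bound.shift_h - free.shift_h) ** 2
                           + (0.2 * (bound.shift_n - free.shift_n)) ** 2)
        np.testing.assert_allclose(result["csp_ppm"], expected, rtol=1e-9)

    def test_state_swap_invariance(self):
        rng = np.random.default_rng(1)
        res = np.arange(1, 11)
        a = shift_table(res, 8 + rng.normal(size=10) * 0.2, 120 + rng.normal(size=10))
        b = shift_table(res, 8 + rng.normal(size=10) * 0.2, 120 + rng.normal(size=10))
        np.testing.assert_allclose(combined_csp(a, b)["csp_ppm"],
                                   combined_csp(b, a)["csp_ppm"])

    def test_broadened_residues_reported_separately(self):
        free = shift_table([1, 2], [8.0, 8.1], [120, 121])
        bound = shift_table([1, 2], [8.2, 8.3], [121, 122], "bound",
                            broadened=[False, True])
        result = combined_csp(free, bound)
        assert not result["broadened"][0]
        assert result["broadened"][1]
        assert np.isnan(result["csp_ppm"][1])

    def test_residues_in_one_state_excluded(self):
        free = shift_table([1, 2, 3], [8.0, 8.1, 8.2], [120, 121, 122])
        bound = shift_table([2, 3, 4], [8.0, 8.1, 8.2], [120, 121, 122], "bound")
        result = combined_csp(free, bound)
        assert list(result["res_id"]) == [2, 3]


class TestRelaxation:
    def test_exact_exponential_recovered(self):
        t_true = 500.0
        delays = np.array(T1_DELAYS_MS)
        series = RelaxationSeries(res_id=np.array([1]), delays_ms=delays,
                                  intensities=np.exp(-delays / t_true)[None, :])
        result = fit_relaxation(series)
        assert result["valid"][0]
        assert result["T_ms"][0] == pytest.approx(t_true, rel=1e-6)

    def test_any_delay_subset_recovers(self):
        t_true = 120.0
        rng = np.random.default_rng(2)
        for _ in range(5):
            delays = np.sort(rng.choice(T1_DELAYS_MS, size=5, replace=False))
            series = RelaxationSeries(res_id=np.array([1]), delays_ms=delays,
                                      intensities=np.exp(-delays / t_true)[None, :])
            assert fit_relaxation(series)["T_ms"][0] == pytest.approx(t_true, rel=1e-6)

    def test_duplicate_scatter_drives_uncertainty(self):
        t_true = 400.0
        delays = np.array(list(T1_DELAYS_MS) + [T1_DELAYS_MS[1], T1_DELAYS_MS[5]])
        clean = np.exp(-delays / t_true)

        def with_discrepancy(frac):
            y = clean.copy()
            y[-2:] = y[-2:] * (1 + frac)
            return RelaxationSeries(res_id=np.array([1]), delays_ms=delays,
                                    intensities=y[None, :])

        err_small = fit_relaxation(with_discrepancy(0.02))["T_err_ms"][0]
        err_large = fit_relaxation(with_discrepancy(0.08))["T_err_ms"][0]
        assert err_small > 0
        assert err_large > err_small

    def test_flat_series_flagged_invalid(self):
        delays = np.array(T1_DELAYS_MS)
        series = RelaxationSeries(res_id=np.array([1]), delays_ms=delays,
                                  intensities=np.ones((1, len(delays))))
        result = fit_relaxation(series)
        assert not result["valid"][0]
        assert np.isnan(result["T_ms"][0])

    def test_too_few_distinct_delays_rejected(self):
        with pytest.raises(ValueError):
            RelaxationSeries(res_id=np.array([1]),
                             delays_ms=np.array([5.0, 5.0, 10.0, 10.0]),
                             intensities=np.ones((1, 4)))


class TestPRE:
    def test_unit_ratio_is_lower_bound(self):
        series = PRESeries(res_id=np.array([1]), ratio=np.array([1.0]))
        row = pre_distance(series).iloc[0]
        assert row["bound"] == "lower"
        assert row["gamma2_s"] == 0.0

    def test_r_minus_six_scaling(self):
        k = pre_constant()
        g = 50.0
        d1 = (k / g) ** (1 / 6)
        d2 = (k / (g / 2)) ** (1 / 6)
        assert d2 / d1 == pytest.approx(2 ** (1 / 6), rel=1e-12)

    def test_roundtrip_gamma_ratio_gamma(self):
        for g in (1.0, 15.0, 80.0, 300.0):
            ratio = ratio_from_gamma2(g, r2_dia=15.0, t_evol=0.01)
            back = gamma2_from_ratio(ratio, r2_dia=15.0, t_evol=0.01)
            assert back == pytest.approx(g, rel=1e-8)

    def test_distance_monotone_decreasing_in_gamma(self):
        k = pre_constant()
        gammas = np.array([1.0, 5.0, 25.0, 125.0])
        distances = (k / gammas) ** (1 / 6)
        assert np.all(np.diff(distances) < 0)

    def test_forward_invert_recovers_distances(self):
        rng = np.random.default_rng(3)
        distances = rng.uniform(9.0, 19.0, 20)
        gammas = np.array([gamma2_from_distance(d) for d in distances])
        ratios = np.array([ratio_from_gamma2(g, 15.0, 0.01) for g in gammas])
        series = PRESeries(res_id=np.arange(1, 21), ratio=ratios)
        result = pre_distance(series)
        point = result[result["bound"] == "point"]
        np.testing.assert_allclose(point["distance_A"],
                                   distances[point.index], rtol=1e-6)

    def test_out_of_range_ratio_rejected(self):
        with pytest.raises(ValueError):
            PRESeries(res_id=np.array([1]), ratio=np.array([1.5]))


class TestProfileComparison:
    def _series(self, ratios):
        return PRESeries(res_id=np.arange(1, len(ratios) + 1),
                         ratio=np.asarray(ratios, dtype=float))

    def test_identical_profiles_zero(self):
        p = self._series([0.2, 0.5, 0.9, 1.0])
        result = compare_pre_profiles(p, p)
        np.testing.assert_allclose(result["difference"], 0.0)
        assert result["rms"] == 0.0

    def test_single_residue_shift_localised(self):
        a = self._series([0.2, 0.5, 0.9, 1.0])
        b = self._series([0.2, 0.8, 0.9, 1.0])
        result = compare_pre_profiles(a, b)
        assert result["difference"][1] == pytest.approx(0.3)
        assert np.count_nonzero(np.abs(result["difference"]) > 1e-12) == 1

    def test_domain_rotation_detectable(self, toy):
        """PRE profiles before/after a 30° domain rotation differ measurably."""
        from scipy.spatial.transform import Rotation
        from loopbind.model_core import apply_move
        from loopbind.synth import simulate_nmr

        truth, part = toy["truth"], toy["partition"]
        rot = Rotation.from_rotvec(np.deg2rad(30) * np.array([0, 0, 1.0])).as_matrix()
        rotated = apply_move(truth, part, "RRM2", rotation=rot)
        *_, pre_a, _, _ = simulate_nmr(truth)
        *_, pre_b, _, _ = simulate_nmr(rotated)
        same = compare_pre_profiles(pre_a, pre_a)
        different = compare_pre_profiles(pre_a, pre_b)
        assert different["rms"] > same["rms"] + 0.01

    def test_mismatched_indexing_rejected(self):
        a = self._series([0.2, 0.5])
        b = PRESeries(res_id=np.array([3, 4]), ratio=np.array([0.2, 0.5]))
        with pytest.raises(ValueError):
            compare_pre_profiles(a, b)
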