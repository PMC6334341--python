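"""Recovery, RMSE, paired t-test and the EJCR accuracy test."""

import numpy as np
import pytest

from teaspec.validate import (
    calibration_report,
    compare_models,
    ejcr,
    paired_t_test,
    recovery,
    rmse,
)


class TestRMSE:
    def test_identical_vectors(self):
        assert rmse([1.0, 2.0, 3.0], [1.0, 2.0, 3.0]) == 0.0

    def test_constant_offset(self):
        assert rmse([1.0, 2.0, 3.0], [2.0, 3.0, 4.0]) == pytest.approx(1.0)

    def test_matches_loop_computation(self, rng):
        a = rng.normal(0, 1, 20)
        b = rng.normal(0, 1, 20)
        acc = 0.0
        for x, y in zip(a, b):
            acc += (x - y) ** 2
        assert rmse(a, b) == pytest.approx(np.sqrt(acc / 20))

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            rmse([], [])


class TestRecovery:
    def test_perfect_prediction_100_percent(self):
        per, mean, sd = recovery([2.0, 4.0], [2.0, 4.0])
        assert np.allclose(per, 100.0)
        assert mean == 100.0

    def test_reported_style_rounding(self):
        # 100 x 35.02 / 36.07 = 97.1 % to one decimal
        per, _, _ = recovery([36.07], [35.02])
        assert round(per[0], 1) == 97.1
        per_exact, _, _ = recovery([36.07], [36.07])
        assert per_exact[0] == pytest.approx(100.0)

    def test_zero_actual_rejected(self):
        with pytest.raises(ValueError):
            recovery([0.0, 1.0], [1.0, 1.0])


class TestPairedT:
    def test_identical_vectors_t_zero(self):
        t, crit, sig = paired_t_test(np.arange(5.0), np.arange(5.0))
        assert t == 0.0 and not sig

    def test_critical_value_df29(self):
        rng = np.random.default_rng(0)
        a = rng.normal(0, 1, 30)
        _, crit, _ = paired_t_test(a, a + rng.normal(0, 1, 30))
        assert round(crit, 3) == 2.045

    def test_constructed_t_exactly_two(self):
        """Differences with mean = 2 sd/sqrt(30) give t = 2.00 < 2.045."""
        rng = np.random.default_rng(1)
        e = rng.normal(0, 1, 30)
        e = (e - e.mean()) / e.std(ddof=1)  # zero mean, unit sd
        d = 0.5 * e + 0.5 * 2.0 / np.sqrt(30)
        actual = rng.normal(10, 1, 30)
        t, crit, sig = paired_t_test(actual, actual - d)
        assert t == pytest.approx(2.0)
        assert not sig

    def test_antisymmetric_under_swap(self, rng):
        a = rng.normal(0, 1, 15)
        b = rng.normal(0, 1, 15)
        t_ab, _, _ = paired_t_test(a, b)
        t_ba, _, _ = paired_t_test(b, a)
        assert t_ab == pytest.approx(-t_ba)

    def test_zero_variance_nonzero_mean_significant(self):
        t, _, sig = paired_t_test([1.0, 2.0, 3.0], [0.0, 1.0, 2.0])
        assert np.isinf(t) and sig


class TestEJCR:
    def test_near_ideal_line_contains_ideal(self, rng):
        pred = rng.uniform(0, 10, 30)
        actual = pred + rng.normal(0, 1e-6, 30)
        assert ejcr(actual, pred).contains_ideal

    def test_halved_slope_excludes_ideal(self, rng):
        pred = rng.uniform(0, 10, 100)
        actual = 0.5 * pred + rng.normal(0, 1e-3, 100)
        res = ejcr(actual, pred)
        assert not res.contains_ideal
        assert res.slope == pytest.approx(0.5, abs=1e-3)

    def test_monte_carlo_coverage_95_percent(self):
        """Under a true (0, 1) line with Gaussian noise the ideal point
        falls inside the 95 % region in ~95 % of replicates."""
        rng = np.random.default_rng(7)
        x = rng.uniform(0, 10, 30)
        hits = sum(ejcr(x + rng.normal(0, 1, 30), x).contains_ideal for _ in range(2000))
        assert 0.93 <= hits / 2000 <= 0.97

    def test_verdict_matches_quadratic_form(self, rng):
        pred = rng.uniform(0, 5, 25)
        actual = 0.9 * pred + 0.3 + rng.normal(0, 0.2, 25)
        res = ejcr(actual, pred)
        delta = np.array([res.intercept - 0.0, res.slope - 1.0])
        inside = delta @ res.xtx @ delta <= 2 * res.s2 * res.f_critical
        assert res.contains_ideal == inside
        assert res.contains(res.intercept, res.slope)  # center always inside

    def test_affine_invariance_with_transformed_ideal(self, rng):
        """Rescaling actual and predicted by the same affine map moves the
        region consistently: the transformed center stays inside."""
        pred = rng.uniform(0, 10, 40)
        actual = pred + rng.normal(0, 0.5, 40)
        res = ejcr(actual, pred)
        res2 = ejcr(2.0 * actual + 1.0, 2.0 * pred + 1.0)
        # the line actual'=pred' still holds, so (0,1) remains ideal
        assert res.contains_ideal == res2.contains_ideal

    def test_area_grows_with_residual_variance_and_shrinks_with_n(self, rng):
        pred = rng.uniform(0, 10, 30)
        small = ejcr(pred + rng.normal(0, 0.1, 30), pred).area
        large = ejcr(pred + rng.normal(0, 1.0, 30), pred).area
        assert large > small
        pred_big = rng.uniform(0, 10, 300)
        many = ejcr(pred_big + rng.normal(0, 0.1, 300), pred_big).area
        assert many < small

    def test_boundary_points_on_ellipse(self, rng):
        pred = rng.uniform(0, 10, 30)
        res = ejcr(pred + rng.normal(0, 0.3, 30), pred)
        pts = res.boundary(64)
        c = 2 * res.s2 * res.f_critical
        center = np.array([res.intercept, res.slope])
        q = np.einsum("ij,jk,ik->i", pts - center, res.xtx, pts - center)
        assert np.allclose(q, c, rtol=1e-8)

    def test_constant_predictor_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            ejcr([1.0, 2.0, 3.0], [5.0, 5.0, 5.0])


class TestCompareModels:
    @staticmethod
    def report(block, rmsep_scale, rng):
        pred = rng.uniform(20, 50, 30)
        actual = pred + rng.normal(0, rmsep_scale, 30)
        return calibration_report(block, "dpph", actual, pred, rmsec=rmsep_scale / 2)

    def test_orders_by_rmsep(self, rng):
        reports = {
            "mir": self.report("mir", 1.0, rng),
            "nir": self.report("nir", 1.1, rng),
            "fused": self.report("fused", 0.4, rng),
        }
        ranking = compare_models(reports)
        assert ranking.order[0] == "fused"
        assert ranking.fused_wins

    def test_tie_broken_by_ejcr_area(self, rng):
        a = self.report("mir", 0.5, rng)
        b = self.report("nir", 0.5, rng)
        b.rmsep = a.rmsep  # force an exact RMSEP tie
        expected = "mir" if a.ejcr.area <= b.ejcr.area else "nir"
        assert compare_models({"mir": a, "nir": b}).order[0] == expected

    def test_single_report_rejected(self, rng):
        with pytest.raises(ValueError):
            compare_models({"mir": self.report("mir", 1.0, rng)})
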