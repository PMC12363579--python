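import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from fxtrend import DeviationSeries, lmm_trend, ols_trend, per_fraction_tests
from fxtrend.trends import cooks_outliers, refit_after_exclusion


def closed_form_line(fr, dev):
    """Normal-equation oracle for the straight-line fit."""
    fr = np.asarray(fr, float)
    dev = np.asarray(dev, float)
    sxx = ((fr - fr.mean()) ** 2).sum()
    slope = ((fr - fr.mean()) * (dev - dev.mean())).sum() / sxx
    return slope, dev.mean() - slope * fr.mean()


def brute_force_cooks(fr, dev):
    """Leave-one-out definition: D_i = sum_j (yhat_j - yhat_j(i))^2 / (p s^2)."""
    fr, dev = np.asarray(fr, float), np.asarray(dev, float)
    n, p = len(fr), 2
    slope, intercept = closed_form_line(fr, dev)
    yhat = intercept + slope * fr
    s2 = ((dev - yhat) ** 2).sum() / (n - p)
    out = np.empty(n)
    for i in range(n):
        keep = np.arange(n) != i
        s_i, b_i = closed_form_line(fr[keep], dev[keep])
        yhat_i = b_i + s_i * fr
        out[i] = ((yhat - yhat_i) ** 2).sum() / (p * s2)
    return out


class TestOlsTrend:
    def test_noiseless_line_recovered(self):
        fr = np.tile(np.arange(1, 31), 3)
        slope, intercept, resid = ols_trend(fr, -0.33 * fr - 4.675)
        assert slope == pytest.approx(-0.33, abs=1e-12)
        assert intercept == pytest.approx(-4.675, abs=1e-10)
        assert np.abs(resid).max() < 1e-10

    def test_four_point_hand_example(self):
        slope, intercept, _ = ols_trend([1, 2, 3, 4], [1, 2, 2, 3])
        assert slope == pytest.approx(0.6)
        assert intercept == pytest.approx(0.5)

    def test_constant_deviations_give_zero_slope(self):
        slope, _, _ = ols_trend([1, 2, 3, 4], [5.0, 5.0, 5.0, 5.0])
        assert slope == pytest.approx(0.0, abs=1e-12)

    def test_degenerate_design_rejected(self):
        with pytest.raises(ValueError, match="degenerate|fraction"):
            ols_trend([3, 3, 3], [1.0, 2.0, 3.0])

    def test_matches_normal_equations(self, rng):
        for _ in range(25):
            n = rng.integers(3, 40)
            fr = rng.integers(1, 31, size=n).astype(float)
            if len(np.unique(fr)) < 2:
                continue
            dev = rng.normal(size=n)
            slope, intercept, _ = ols_trend(fr, dev)
            s0, b0 = closed_form_line(fr, dev)
            assert slope == pytest.approx(s0, rel=1e-10, abs=1e-12)
            assert intercept == pytest.approx(b0, rel=1e-10, abs=1e-12)


class TestCooksDistance:
    def test_collinear_points_unflagged(self):
        fr = np.arange(1.0, 21.0)
        report = cooks_outliers(fr, 2 * fr + 1)
        assert np.abs(report.cooks_distance).max() < 1e-12
        assert not report.flagged.any()

    def test_gross_outlier_has_maximal_distance(self, rng):
        fr = np.arange(1.0, 21.0)
        dev = 0.5 * fr
        dev[17] += 40.0
        report = cooks_outliers(fr, dev)
        assert np.argmax(report.cooks_distance) == 17
        assert report.flagged[17]

    def test_matches_leave_one_out_bruteforce(self, rng):
        for _ in range(20):
            n = int(rng.integers(5, 13))
            fr = rng.uniform(1, 30, size=n)
            dev = rng.normal(size=n) + 0.3 * fr
            report = cooks_outliers(fr, dev)
            np.testing.assert_allclose(
                report.cooks_distance, brute_force_cooks(fr, dev), rtol=1e-8
            )

    def test_cap_limits_flags_to_74_of_1200(self, rng):
        fr = np.tile(np.arange(1.0, 31.0), 40)
        dev = 0.1 * fr + rng.normal(scale=0.01, size=1200)
        idx = rng.choice(1200, size=100, replace=False)
        dev[idx] += rng.choice([-30.0, 30.0], size=100)
        report = cooks_outliers(fr, dev)
        assert report.cap_applied
        assert report.flagged.sum() == 74  # floor(0.062 * 1200)

    def test_too_few_points_rejected(self):
        with pytest.raises(ValueError):
            cooks_outliers([1.0, 2.0], [1.0, 2.0])


class TestRefitAfterExclusion:
    def test_no_flags_identical_to_plain_fit(self):
        fr = np.arange(1.0, 21.0)
        dev = 0.5 * fr + np.sin(fr)
        report = cooks_outliers(fr, dev, threshold=np.inf)
        fit = refit_after_exclusion(fr, dev, report)
        slope, intercept, _ = ols_trend(fr, dev)
        assert fit.slope == pytest.approx(slope)
        assert fit.n_outliers_removed == 0

    def test_excluding_gross_outlier_restores_truth(self):
        fr = np.arange(1.0, 31.0)
        dev = -0.33 * fr
        contaminated = dev.copy()
        contaminated[5] += 60.0
        slope_dirty, _, _ = ols_trend(fr, contaminated)
        report = cooks_outliers(fr, contaminated)
        fit = refit_after_exclusion(fr, contaminated, report)
        assert abs(fit.slope + 0.33) < abs(slope_dirty + 0.33)
        assert fit.slope == pytest.approx(-0.33, abs=1e-9)

    def test_degenerate_leftover_propagates_error(self):
        fr = np.array([1.0, 1.0, 1.0, 2.0, 3.0])
        dev = np.array([0.0, 0.1, -0.1, 5.0, 10.0])
        report = cooks_outliers(fr, dev, threshold=np.inf)
        report.flagged[3:] = True  # only one distinct fraction survives
        with pytest.raises(ValueError):
            refit_after_exclusion(fr, dev, report)


def _series_set(dev_matrix):
    return {
        f"P{i}": DeviationSeries(f"P{i}", "GTV", row) for i, row in enumerate(dev_matrix)
    }


class TestLmmTrend:
    def test_deterministic_limit_recovers_slope_exactly(self):
        f = np.arange(1, 31)
        series = _series_set([-4.675 - 0.33 * f] * 5)
        fit = lmm_trend(series)
        assert fit.slope == pytest.approx(-0.33, abs=1e-8)

    def test_balanced_offsets_give_within_patient_slope(self):
        f = np.arange(1, 31)
        series = _series_set([0.2 * f + off for off in (-3.0, -1.0, 2.0, 5.0)])
        fit = lmm_trend(series)
        assert fit.slope == pytest.approx(0.2, abs=1e-8)

    def test_ci_brackets_slope(self, rng):
        f = np.arange(1, 31)
        series = _series_set(
            [0.1 * f + rng.normal(0, 1) + rng.normal(0, 0.5, size=30) for _ in range(8)]
        )
        fit = lmm_trend(series)
        lo, hi = fit.slope_ci
        assert lo <= fit.slope <= hi
        assert hi - lo < 0.5

    def test_requires_two_patients(self):
        with pytest.raises(ValueError):
            lmm_trend({"P0": DeviationSeries("P0", "GTV", np.arange(30.0))})


class TestPerFractionTests:
    def test_all_zero_deviations_never_significant(self):
        series = _series_set([np.zeros(30)] * 6)
        p, thr, earliest = per_fraction_tests(series)
        assert earliest is None
        assert thr == pytest.approx(0.05 / 30)

    def test_step_signal_detected_at_onset(self, rng):
        f = np.arange(1, 31)
        mat = [
            np.where(f >= 10, 10.0, 0.0) + rng.normal(0, 0.05, size=30)
            for _ in range(40)
        ]
        _, _, earliest = per_fraction_tests(_series_set(mat))
        assert earliest == 10

    def test_fraction_with_one_patient_masked(self):
        a = DeviationSeries("P0", "GTV", np.arange(1.0, 31.0))
        mask_dev = np.arange(1.0, 31.0)
        mask_dev[0] = np.nan
        b = DeviationSeries("P1", "GTV", mask_dev)
        p, _, _ = per_fraction_tests({"P0": a, "P1": b})
        assert np.isnan(p[0])
        assert np.isfinite(p[1])

    @given(st.floats(min_value=1e-4, max_value=0.05))
    @settings(derandomize=True, max_examples=20, deadline=None)
    def test_bonferroni_monotonicity(self, alpha):
        rng = np.random.default_rng(7)
        f = np.arange(1, 31)
        mat = [0.2 * f + rng.normal(0, 2.0, size=30) for _ in range(12)]
        series = _series_set(mat)
        _, _, strict = per_fraction_tests(series, alpha=alpha)
        _, _, loose = per_fraction_tests(series, alpha=0.05)
        if strict is not None:
            assert loose is not None and loose <= strict
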