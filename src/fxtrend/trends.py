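"""Temporal trend estimation for per-fraction percent deviations.

The trend half of the pipeline: a pooled least-squares fit of deviation on
fraction number, Cook's-distance screening of high-leverage points (capped at
6.2 % of the data), a random-intercept linear mixed model for the cohort
deviation rate, and per-fraction one-sample tests with Bonferroni correction
yielding the earliest fraction at which the cohort deviates significantly
from plan.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .data import DeviationSeries
from .simulate import TREND_TABLE

OUTLIER_CAP_RATE = 0.062  # published ceiling: 74 of 1200 points


@dataclass
class OutlierReport:
    """Cook's-distance screening result for one pooled fit."""

    cooks_distance: np.ndarray
    flagged: np.ndarray  # boolean, aligned with the fitted points
    threshold: float
    cap_applied: bool
    point_keys: list[tuple[str, int]]  # (patient_id, fraction) per fitted point

    @property
    def flagged_keys(self) -> list[tuple[str, int]]:
        return [k for k, fl in zip(self.point_keys, self.flagged) if fl]


@dataclass
class TrendFit:
    """Cohort trend summary for one parameter."""

    parameter: str
    slope: float
    slope_ci: tuple[float, float]
    intercept: float
    p_values: np.ndarray | None = None  # per fraction, length F (NaN = masked)
    bonferroni_alpha: float | None = None
    earliest_significant_fraction: int | None = None
    n_points_used: int = 0
    n_outliers_removed: int = 0
    singular: bool = False


def _pooled_points(
    series: Mapping[str, DeviationSeries]
) -> tuple[np.ndarray, np.ndarray, list[tuple[str, int]]]:
    """Stack all present (fraction, deviation) points over patients."""
    fr, dev, keys = [], [], []
    for pid, s in series.items():
        f, d = s.present()
        fr.append(f)
        dev.append(d)
        keys.extend((pid, int(fi)) for fi in f)
    if not fr:
        return np.empty(0), np.empty(0), []
    return np.concatenate(fr).astype(float), np.concatenate(dev), keys


def ols_trend(
    fractions: np.ndarray, deviations: np.ndarray
) -> tuple[float, float, np.ndarray]:
    """Pooled least-squares fit of deviation on fraction number.

    Returns (slope, intercept, residuals).  Requires >= 3 points on >= 2
    distinct fractions.
    """
    fractions = np.asarray(fractions, dtype=float)
    deviations = np.asarray(deviations, dtype=float)
    if len(fractions) < 3:
        raise ValueError("need >= 3 points for a trend fit")
    if len(np.unique(fractions)) < 2:
        raise ValueError("degenerate design: all points at one fraction")
    X = sm.add_constant(fractions)
    fit = sm.OLS(deviations, X).fit()
    intercept, slope = fit.params
    return float(slope), float(intercept), np.asarray(fit.resid)


def cooks_outliers(
    fractions: np.ndarray,
    deviations: np.ndarray,
    point_keys: Sequence[tuple[str, int]] | None = None,
    threshold: float | None = None,
    cap_rate: float = OUTLIER_CAP_RATE,
) -> OutlierReport:
    """Flag influential points of the pooled fit by Cook's distance.

    ``D_i = r_i^2 / (p s^2) * h_i / (1 - h_i)^2`` with p = 2 fitted
    parameters.  Points with ``D_i`` above the threshold (default 4/n) are
    flagged; if more than ``cap_rate * n`` points exceed it, only the top
    ``floor(cap_rate * n)`` by ``D_i`` are flagged and the cap is recorded.
    """
    fractions = np.asarray(fractions, dtype=float)
    deviations = np.asarray(deviations, dtype=float)
    n = len(fractions)
    if n <= 2:
        raise ValueError("need more points than fitted parameters")
    X = sm.add_constant(fractions)
    fit = sm.OLS(deviations, X).fit()
    if np.allclose(fit.resid, 0.0, atol=1e-10):  # perfect fit: no influence
        cooks = np.zeros(n)
    else:
        cooks = np.asarray(fit.get_influence().cooks_distance[0])
    if threshold is None:
        threshold = 4.0 / n
    flagged = cooks > threshold
    cap = int(np.floor(cap_rate * n))
    cap_applied = False
    if flagged.sum() > cap:
        cap_applied = True
        keep = np.argsort(cooks)[::-1][:cap]
        flagged = np.zeros(n, dtype=bool)
        flagged[keep] = True
    if point_keys is None:
        point_keys = [("", int(f)) for f in fractions]
    return OutlierReport(cooks, flagged, float(threshold), cap_applied, list(point_keys))


def refit_after_exclusion(
    fractions: np.ndarray,
    deviations: np.ndarray,
    report: OutlierReport,
    parameter: str = "",
) -> TrendFit:
    """Re-run the pooled fit on the unflagged points."""
    keep = ~report.flagged
    slope, intercept, _ = ols_trend(
        np.asarray(fractions)[keep], np.asarray(deviations)[keep]
    )
    return TrendFit(
        parameter=parameter,
        slope=slope,
        slope_ci=(np.nan, np.nan),
        intercept=intercept,
        n_points_used=int(keep.sum()),
        n_outliers_removed=int(report.flagged.sum()),
    )


def _mixedlm_fit(fractions, deviations, groups):
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model = sm.MixedLM(
            deviations, sm.add_constant(fractions), groups=groups
        )
        return model.fit(reml=True)


def lmm_trend(
    series: Mapping[str, DeviationSeries],
    robust: bool = True,
    alpha: float = 0.05,
) -> TrendFit:
    """Cohort deviation rate from a random-intercept linear mixed model.

    Fits ``deviation ~ fraction`` with a Gaussian response and a random
    intercept per patient by REML.  The default 95 % CI is a Wald interval
    with a cluster-robust (sandwich over patients, CR1 small-sample factor)
    standard error, which keeps nominal coverage when residuals are serially
    correlated within patients; ``robust=False`` gives the model-based Wald CI.

    Falls back to the pooled OLS point estimate when the mixed fit is singular
    (e.g. zero residual variance); the fallback is exact on balanced data,
    where the GLS and OLS slopes coincide.
    """
    if len(series) < 2:
        raise ValueError("need >= 2 patients")
    fractions, deviations, keys = _pooled_points(series)
    groups = np.array([k[0] for k in keys])
    parameter = next(iter(series.values())).parameter

    singular = False
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = _mixedlm_fit(fractions, deviations, groups)
            intercept, slope = float(res.params[0]), float(res.params[1])
            se_model = float(res.bse_fe[1])
            sigma_b2 = float(np.squeeze(res.cov_re)) if res.cov_re.size else 0.0
            sigma_e2 = float(res.scale)
        if not np.isfinite(se_model) or sigma_e2 <= 0:
            raise np.linalg.LinAlgError
        converged = bool(res.converged)
        if not converged:
            singular = True
    except Exception:
        slope, intercept, _ = ols_trend(fractions, deviations)
        sigma_b2, sigma_e2, se_model = 0.0, float(np.var(deviations)), np.nan
        singular = True

    z = stats.norm.ppf(1 - alpha / 2)
    if robust:
        se = _cluster_robust_se(fractions, deviations, groups, intercept, slope, sigma_b2, sigma_e2)
    else:
        se = se_model
    if not np.isfinite(se):
        se = _cluster_robust_se(fractions, deviations, groups, intercept, slope, sigma_b2, sigma_e2)
    return TrendFit(
        parameter=parameter,
        slope=slope,
        slope_ci=(slope - z * se, slope + z * se),
        intercept=intercept,
        n_points_used=len(fractions),
        singular=singular,
    )


def _cluster_robust_se(
    fractions, deviations, groups, intercept, slope, sigma_b2, sigma_e2
) -> float:
    """CR1 sandwich SE of the slope for the random-intercept GLS estimator."""
    if sigma_e2 <= 0:
        sigma_e2 = 1e-12
    bread = np.zeros((2, 2))
    meat = np.zeros((2, 2))
    ids = pd.unique(groups)
    for pid in ids:
        m = groups == pid
        Xi = np.column_stack([np.ones(m.sum()), fractions[m]])
        ri = deviations[m] - (intercept + slope * fractions[m])
        ni = len(ri)
        # V_i^{-1} via Sherman-Morrison for sigma_b2 * J + sigma_e2 * I
        a = 1.0 / sigma_e2
        b = -sigma_b2 / (sigma_e2 * (sigma_e2 + ni * sigma_b2))
        XtVi = a * Xi.T + b * np.outer(Xi.sum(axis=0), np.ones(ni))
        bread += XtVi @ Xi
        u = XtVi @ ri
        meat += np.outer(u, u)
    G = len(ids)
    if G < 2:
        return np.nan
    binv = np.linalg.inv(bread)
    cov = binv @ meat @ binv * (G / (G - 1))
    return float(np.sqrt(cov[1, 1]))


def per_fraction_tests(
    series: Mapping[str, DeviationSeries],
    alpha: float = 0.05,
    n_fractions: int | None = None,
) -> tuple[np.ndarray, float, int | None]:
    """Per-fraction two-sided one-sample t-tests of mean deviation = 0.

    At each fraction the deviations of all patients with data there are tested
    against zero; the Bonferroni-adjusted threshold is ``alpha / F`` with F the
    series length.  Returns (p-values of length F with NaN where fewer than two
    patients contribute, adjusted threshold, earliest significant fraction or
    None).
    """
    if not series:
        raise ValueError("empty series set")
    if n_fractions is None:
        n_fractions = next(iter(series.values())).n_fractions
    p_values = np.full(n_fractions, np.nan)
    for f in range(1, n_fractions + 1):
        vals = [
            s.deviations[f - 1]
            for s in series.values()
            if f <= s.n_fractions and s.mask[f - 1]
        ]
        if len(vals) < 2:
            continue
        vals = np.asarray(vals)
        if np.allclose(vals, vals[0]):
            # zero variance: p = 1 if the common value is 0, else limiting p = 0
            p_values[f - 1] = 1.0 if np.isclose(vals[0], 0.0) else 0.0
            continue
        p_values[f - 1] = stats.ttest_1samp(vals, 0.0).pvalue
    threshold = alpha / n_fractions
    sig = np.flatnonzero(p_values < threshold)
    earliest = int(sig[0]) + 1 if sig.size else None
    return p_values, threshold, earliest


def fit_parameter_trend(
    series: Mapping[str, DeviationSeries],
    alpha: float = 0.05,
    screen_outliers: bool = True,
    robust: bool = True,
) -> TrendFit:
    """Full trend analysis for one parameter's cohort of series.

    Pooled OLS with Cook's-distance screening characterises and removes
    high-leverage points; the reported slope and CI come from the
    random-intercept mixed model (fitted on all points, matching the published
    procedure where exclusion applies to the pooled regression stage); the
    per-fraction tests supply the earliest significant fraction.
    """
    fractions, deviations, keys = _pooled_points(series)
    n_removed = 0
    if screen_outliers and len(fractions) > 2:
        report = cooks_outliers(fractions, deviations, keys)
        n_removed = int(report.flagged.sum())
    fit = lmm_trend(series, robust=robust, alpha=alpha)
    p_values, threshold, earliest = per_fraction_tests(series, alpha=alpha)
    fit.p_values = p_values
    fit.bonferroni_alpha = threshold
    fit.earliest_significant_fraction = earliest
    fit.n_outliers_removed = n_removed
    return fit


def trend_table(
    series: Mapping[tuple[str, str], DeviationSeries],
    alpha: float = 0.05,
    robust: bool = True,
) -> pd.DataFrame:
    """Published-style trend table: one row per monitored parameter."""
    rows = []
    for param in TREND_TABLE:
        sub = {pid: s for (pid, p), s in series.items() if p == param}
        if not sub:
            continue
        fractions, deviations, _ = _pooled_points(sub)
        fit = fit_parameter_trend(sub, alpha=alpha, robust=robust)
        rows.append(
            {
                "parameter": param,
                "average_deviation_pct": float(np.mean(deviations)),
                "rate_pct_per_fraction": fit.slope,
                "ci_low": fit.slope_ci[0],
                "ci_high": fit.slope_ci[1],
                "earliest_significant_fraction": fit.earliest_significant_fraction,
                "n_outliers_removed": fit.n_outliers_removed,
            }
        )
    return pd.DataFrame(rows)
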