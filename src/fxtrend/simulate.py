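"""Synthetic per-fraction radiotherapy cohorts with planted longitudinal structure.

No per-fraction dose tables are publicly deposited for this kind of study, so
the analyses here run on a synthetic cohort whose statistical structure mirrors
what the pipeline assumes: a linear per-fraction trend for each monitored
parameter, a persistent patient-level offset, AR(1) interfractional noise whose
scale differs between a stable majority cluster and a high-variability minority
cluster, and sparse high-leverage outlier points.

Calibration of the default configuration
----------------------------------------
The published cohort-level trend table reports, per parameter, the average
percent deviation over the course, the per-fraction rate of deviation and its
95 % CI.  These three columns identify the generator's first and second
moments in closed form:

* slope = published rate (% per fraction);
* intercept = average − slope × 15.5, since the mean of a linear ramp over
  fractions 1..30 is intercept + slope × (1 + 30)/2;
* residual (within-patient) SD from the CI half-width ``hw``: the sampling SD
  of a fitted cohort slope is ``sd · kappa / sqrt(N · Sxx)`` where
  ``Sxx = Σ(f − 15.5)² = 2247.5`` and ``kappa`` is the slope-variance inflation
  induced by AR(1) serial correlation, so ``sd = (hw / 1.96) · sqrt(N · Sxx) / kappa``.
  With this identity the CI of a trend fitted to a simulated cohort reproduces
  the published CI width.

The patient-offset SD (not constrained by the published table) defaults to a
third of the residual SD; cluster-2 noise is 3x cluster-1 noise, with the
pooled mixture equal to the calibrated residual SD.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.linalg import toeplitz

from .data import PARAMETERS, FractionRecord

N_FRACTIONS_DEFAULT = 30
N_PATIENTS_DEFAULT = 40
_FBAR = (1 + N_FRACTIONS_DEFAULT) / 2.0  # 15.5

#: Published cohort trend table: parameter -> (average deviation %, rate %/fraction,
#: CI low, CI high, earliest significant fraction or None).  Two volume CIs are
#: printed with an impossible sign on one bound; they are read with the sign that
#: makes the interval contain its point estimate.
TREND_TABLE: dict[str, tuple[float, float, float, float, int | None]] = {
    "GTV": (-9.79, -0.33, -0.36, -0.29, 5),
    "CTV": (-7.14, -0.24, -0.26, -0.21, 5),
    "PTV": (-5.34, -0.18, -0.20, -0.16, 7),
    "Lung": (0.53, 0.02, 0.00, 0.03, None),
    "Esophagus": (2.56, 0.09, 0.07, 0.10, None),
    "Heart": (-1.67, -0.06, -0.08, -0.03, 20),
    "SpinalCord": (-0.38, -0.01, -0.02, -0.01, None),
    "GTV_D95": (0.37, 0.01, 0.01, 0.02, 2),
    "CTV_D95": (0.29, 0.01, 0.01, 0.01, 2),
    "PTV_D95": (0.65, 0.02, 0.01, 0.03, None),
    "Lung_Dmean": (3.87, 0.13, 0.12, 0.14, 3),
    "Esophagus_Dmean": (3.40, 0.11, 0.09, 0.14, 7),
    "Heart_Dmean": (2.07, 0.07, 0.02, 0.11, None),
    "SpinalCord_Dmax": (0.57, 0.02, -0.00, 0.04, None),
}

#: Baseline (planned) scales: parameter -> (mean, SD across patients).
#: Target volumes follow the published patient-characteristics table; OAR volumes
#: and dose levels are typical values for thoracic radiotherapy at 60 Gy / 30
#: fractions (they only set the absolute scale of the records; all analyses run
#: on percent deviations).
BASELINES: dict[str, tuple[float, float]] = {
    "GTV": (287.5, 208.5),
    "CTV": (496.8, 282.5),
    "PTV": (730.5, 354.3),
    "Lung": (3400.0, 700.0),
    "Esophagus": (35.0, 8.0),
    "Heart": (600.0, 120.0),
    "SpinalCord": (30.0, 6.0),
    "GTV_D95": (59.5, 0.8),
    "CTV_D95": (59.0, 0.8),
    "PTV_D95": (57.5, 1.0),
    "Lung_Dmean": (14.0, 3.5),
    "Esophagus_Dmean": (20.0, 6.0),
    "Heart_Dmean": (9.0, 4.0),
    "SpinalCord_Dmax": (40.0, 5.0),
}

#: CI half-width floor: half of the table's last printed digit (0.01), used where
#: the printed CI has zero width at printed precision (CTV_D95).
_HALFWIDTH_FLOOR = 0.0025


def ar1_slope_inflation(rho: float, n_fractions: int) -> float:
    """Variance inflation of a per-fraction trend slope under AR(1) residuals.

    ``kappa^2 = wᵀR w / wᵀw`` for the centred fraction contrast ``w`` and the
    AR(1) correlation matrix ``R``; 1.0 at rho = 0.
    """
    f = np.arange(1, n_fractions + 1, dtype=float)
    w = f - f.mean()
    R = toeplitz(rho ** np.arange(n_fractions))
    return float((w @ R @ w) / (w @ w))


@dataclass(frozen=True)
class ParameterSpec:
    """Generating parameters for one monitored quantity.

    All deviation-scale fields are in percent units; ``baseline_mean``/``sd``
    are in the parameter's natural units (cm^3 or Gy).
    """

    parameter: str
    baseline_mean: float
    baseline_sd: float
    slope: float  # percent per fraction
    intercept: float  # percent at fraction 0
    noise_sd_cluster1: float
    noise_sd_cluster2: float
    patient_offset_sd: float
    ar1_rho: float = 0.3
    outlier_magnitude: float | None = None  # percent; None -> 6x pooled residual SD

    def __post_init__(self) -> None:
        if self.parameter not in PARAMETERS:
            raise ValueError(f"unknown parameter {self.parameter!r}")
        if self.noise_sd_cluster1 < 0 or self.noise_sd_cluster2 < 0:
            raise ValueError("noise SDs must be >= 0")
        if not abs(self.ar1_rho) < 1:
            raise ValueError("|ar1_rho| must be < 1")
        if not self.baseline_mean > 0:
            raise ValueError("baseline mean must be > 0")


@dataclass(frozen=True)
class CohortConfig:
    """Full cohort-generator configuration."""

    n_patients: int = N_PATIENTS_DEFAULT
    n_fractions: int = N_FRACTIONS_DEFAULT
    cluster1_proportion: float = 0.65
    outlier_point_rate: float = 0.04
    outlier_magnitude: float | None = None  # global percent override
    seed: int = 0
    specs: dict[str, ParameterSpec] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not 0 < self.cluster1_proportion < 1:
            raise ValueError("cluster1_proportion must be in (0, 1)")
        if not 0 <= self.outlier_point_rate <= 0.062:
            raise ValueError("outlier_point_rate must be in [0, 0.062]")
        if self.n_patients < 2 or self.n_fractions < 1:
            raise ValueError("need >= 2 patients and >= 1 fraction")


@dataclass
class CohortTruth:
    """Ground truth of a simulated cohort, for parameter-recovery tests."""

    cluster_labels: dict[str, int]  # patient -> 1 (stable) or 2 (variable)
    specs: dict[str, ParameterSpec]
    offsets: pd.DataFrame  # patients x parameters, percent
    outlier_points: dict[str, list[tuple[str, int]]]  # parameter -> (patient, fraction)


def default_config(
    seed: int = 0,
    n_patients: int = N_PATIENTS_DEFAULT,
    n_fractions: int = N_FRACTIONS_DEFAULT,
    ar1_rho: float = 0.3,
    cluster_noise_ratio: float = 3.0,
    cluster1_proportion: float = 0.65,
    offset_fraction: float = 1.0 / 3.0,
) -> CohortConfig:
    """The calibrated default cohort: 40 patients x 30 fractions.

    Slopes, intercepts and residual SDs come from the published trend table via
    the closed-form identities in the module docstring.  The pooled residual SD
    is split between the two noise regimes so that
    ``sqrt(p1 * s1^2 + p2 * (ratio * s1)^2)`` equals the calibrated value.
    """
    f = np.arange(1, n_fractions + 1, dtype=float)
    sxx = float(np.sum((f - f.mean()) ** 2))
    kappa = np.sqrt(ar1_slope_inflation(ar1_rho, n_fractions))
    p1 = cluster1_proportion
    mix = np.sqrt(p1 + (1 - p1) * cluster_noise_ratio**2)
    specs = {}
    for param, (avg, rate, lo, hi, _earliest) in TREND_TABLE.items():
        hw = max((hi - lo) / 2.0, _HALFWIDTH_FLOOR)
        resid_sd = (hw / 1.96) * np.sqrt(n_patients * sxx) / kappa
        base_mean, base_sd = BASELINES[param]
        specs[param] = ParameterSpec(
            parameter=param,
            baseline_mean=base_mean,
            baseline_sd=base_sd,
            slope=rate,
            intercept=avg - rate * float(f.mean()),
            noise_sd_cluster1=resid_sd / mix,
            noise_sd_cluster2=cluster_noise_ratio * resid_sd / mix,
            patient_offset_sd=offset_fraction * resid_sd,
            ar1_rho=ar1_rho,
        )
    return CohortConfig(
        n_patients=n_patients,
        n_fractions=n_fractions,
        cluster1_proportion=cluster1_proportion,
        seed=seed,
        specs=specs,
    )


def _pooled_residual_sd(spec: ParameterSpec, p1: float) -> float:
    return float(
        np.sqrt(p1 * spec.noise_sd_cluster1**2 + (1 - p1) * spec.noise_sd_cluster2**2)
    )


def _ar1_series(rng: np.random.Generator, n: int, sd: float, rho: float) -> np.ndarray:
    """Stationary AR(1) sample of length n with marginal SD sd."""
    if sd == 0:
        return np.zeros(n)
    e = np.empty(n)
    e[0] = rng.normal(0.0, sd)
    innov_sd = sd * np.sqrt(1 - rho**2)
    for t in range(1, n):
        e[t] = rho * e[t - 1] + rng.normal(0.0, innov_sd)
    return e


def simulate_cohort(config: CohortConfig) -> tuple[list[FractionRecord], CohortTruth]:
    """Draw one synthetic cohort.  Same config (incl. seed) -> identical output.

    Deviation of patient i at fraction f is
    ``intercept + slope * f + offset_i + AR(1) noise`` with the noise SD taken
    from the patient's cluster; a fixed number of uniformly chosen points per
    parameter have their noise term replaced by ±outlier_magnitude.  Absolute
    record values are reconstructed as ``planned * (1 + deviation / 100)``.

    CTV_D95 deviations are rescaled in the rare case the per-fraction cohort
    mean leaves ±1 %, preserving the published target-coverage behaviour.
    """
    if not config.specs:
        raise ValueError("config.specs is empty; use default_config()")
    rng = np.random.default_rng(config.seed)
    n, F = config.n_patients, config.n_fractions
    patients = [f"P{i + 1:03d}" for i in range(n)]

    n_cluster1 = int(round(config.cluster1_proportion * n))
    labels_arr = np.array([1] * n_cluster1 + [2] * (n - n_cluster1))
    rng.shuffle(labels_arr)
    labels = {pid: int(lab) for pid, lab in zip(patients, labels_arr)}

    fractions = np.arange(1, F + 1, dtype=float)
    records: list[FractionRecord] = []
    offsets = pd.DataFrame(0.0, index=patients, columns=list(config.specs))
    outlier_points: dict[str, list[tuple[str, int]]] = {}

    n_outliers = int(np.floor(config.outlier_point_rate * n * F))
    for param, spec in config.specs.items():
        dev = np.empty((n, F))
        planned = np.empty(n)
        for i, pid in enumerate(patients):
            base = -np.inf
            while base <= 0.1 * spec.baseline_mean:  # keep planned values physical
                base = rng.normal(spec.baseline_mean, spec.baseline_sd)
            planned[i] = base
            offset = rng.normal(0.0, spec.patient_offset_sd)
            offsets.loc[pid, param] = offset
            noise_sd = (
                spec.noise_sd_cluster1 if labels[pid] == 1 else spec.noise_sd_cluster2
            )
            noise = _ar1_series(rng, F, noise_sd, spec.ar1_rho)
            dev[i] = spec.intercept + spec.slope * fractions + offset + noise

        magnitude = config.outlier_magnitude
        if magnitude is None:
            magnitude = spec.outlier_magnitude
        if magnitude is None:
            magnitude = 6.0 * _pooled_residual_sd(spec, config.cluster1_proportion)
        slots = rng.choice(n * F, size=n_outliers, replace=False)
        signs = rng.choice([-1.0, 1.0], size=n_outliers)
        pts = []
        for slot, sign in zip(slots, signs):
            i, j = divmod(int(slot), F)
            dev[i, j] = (
                spec.intercept + spec.slope * fractions[j]
                + offsets.loc[patients[i], param] + sign * magnitude
            )
            pts.append((patients[i], j + 1))
        outlier_points[param] = pts

        if param == "CTV_D95":
            frac_means = np.abs(dev.mean(axis=0))
            if frac_means.max() >= 1.0:
                dev *= 0.99 / frac_means.max()

        for i, pid in enumerate(patients):
            for j, f in enumerate(fractions):
                value = planned[i] * (1.0 + dev[i, j] / 100.0)
                records.append(FractionRecord(pid, int(f), param, value, planned[i]))

    truth = CohortTruth(labels, dict(config.specs), offsets, outlier_points)
    return records, truth


def truth_report(truth: CohortTruth) -> pd.DataFrame:
    """Tabulate the generating parameters (one row per monitored quantity)."""
    rows = []
    for param, spec in truth.specs.items():
        rows.append(
            {
                "parameter": param,
                "slope": spec.slope,
                "intercept": spec.intercept,
                "noise_sd_cluster1": spec.noise_sd_cluster1,
                "noise_sd_cluster2": spec.noise_sd_cluster2,
                "patient_offset_sd": spec.patient_offset_sd,
                "ar1_rho": spec.ar1_rho,
                "n_outlier_points": len(truth.outlier_points.get(param, [])),
            }
        )
    return pd.DataFrame(rows)


def zero_noise_config(seed: int = 0) -> CohortConfig:
    """Deterministic limit of the default cohort (no offsets, noise or outliers)."""
    cfg = default_config(seed=seed)
    specs = {
        p: replace(
            s,
            noise_sd_cluster1=0.0,
            noise_sd_cluster2=0.0,
            patient_offset_sd=0.0,
            baseline_sd=0.0,
        )
        for p, s in cfg.specs.items()
    }
    return replace(cfg, specs=specs, outlier_point_rate=0.0)
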