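"""Distinctiveness, representative-measure selection and trajectory clustering.

The clustering half of the pipeline stratifies a cohort by the shape and
volatility of per-fraction dose-deviation trajectories:

1. *distinctiveness* — each patient's mean DTW dissimilarity to every other
   patient; its variance across patients measures how unevenly a dosimetric
   measure behaves in the cohort.
2. The target-coverage measure (GTV/CTV/PTV D95) with the lowest
   distinctiveness variance is the *representative* target measure.
3. For each organ at risk, patients' paired (representative D95, OAR dose)
   2-D series are compared by dependent DTW; k-means is run on the rows of the
   resulting distance matrix.  The cluster count is the elbow of the
   within-cluster sum-of-squares scree, conservatively increased by one
   (k + 1), and clusters with fewer than ``min_size`` members are excluded as
   outlier patients.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd
from sklearn.cluster import KMeans

from .data import BivariateSeries, DeviationSeries, pair_series
from .dtw import DistanceMatrix, DtwConfig, distance_matrix

TARGET_PRECEDENCE = ("GTV_D95", "CTV_D95", "PTV_D95")


def distinctiveness(dmat: DistanceMatrix) -> pd.Series:
    """Mean dissimilarity of each series to all others (diagonal excluded)."""
    if dmat.n < 2:
        raise ValueError("need >= 2 series")
    total = dmat.values.sum(axis=1)  # diagonal is 0
    return pd.Series(total / (dmat.n - 1), index=dmat.ids, name="distinctiveness")


@dataclass
class RepresentativeSelection:
    parameter: str
    variances: dict[str, float]
    tie: bool


def select_representative(
    tables: Mapping[str, pd.Series], precedence: tuple[str, ...] = TARGET_PRECEDENCE
) -> RepresentativeSelection:
    """Pick the candidate measure with the lowest distinctiveness variance.

    Ties are broken by the fixed precedence order and reported.
    """
    if not tables:
        raise ValueError("no candidate parameters")
    ordered = [p for p in precedence if p in tables]
    ordered += [p for p in tables if p not in ordered]
    variances = {p: float(np.var(tables[p], ddof=1)) if len(tables[p]) > 1 else 0.0
                 for p in ordered}
    best = min(ordered, key=lambda p: variances[p])
    tie = sum(np.isclose(variances[p], variances[best]) for p in ordered) > 1
    return RepresentativeSelection(best, variances, tie)


def kmeans_rows(
    dmat: DistanceMatrix, k: int, seed: int = 0, n_restarts: int = 50
) -> tuple[np.ndarray, float]:
    """k-means (Lloyd, k-means++ seeding, best of ``n_restarts``) on the rows
    of the distance matrix taken as feature vectors.

    Returns (labels aligned with ``dmat.ids``, total within-cluster sum of
    squares).  Deterministic given ``seed``.
    """
    if not 2 <= k <= dmat.n:
        raise ValueError(f"k must be in [2, {dmat.n}], got {k}")
    import warnings

    from sklearn.exceptions import ConvergenceWarning

    km = KMeans(
        n_clusters=k,
        init="k-means++",
        n_init=n_restarts,
        random_state=seed,
        algorithm="lloyd",
    )
    with warnings.catch_warnings():
        # duplicate rows (degenerate cohorts) legitimately yield < k clusters
        warnings.simplefilter("ignore", ConvergenceWarning)
        km.fit(dmat.values)
    return km.labels_.copy(), float(km.inertia_)


def wss_curve(
    dmat: DistanceMatrix, k_max: int, seed: int = 0, n_restarts: int = 50
) -> np.ndarray:
    """Total within-cluster sum of squares for k = 1..k_max (the scree)."""
    rows = dmat.values
    wss = [float(((rows - rows.mean(axis=0)) ** 2).sum())]  # k = 1
    for k in range(2, min(k_max, dmat.n) + 1):
        wss.append(kmeans_rows(dmat, k, seed=seed, n_restarts=n_restarts)[1])
    return np.asarray(wss)


@dataclass
class ElbowResult:
    k_elbow: int
    second_differences: np.ndarray
    tie: bool = False
    degenerate: bool = False


def elbow_k(wss: np.ndarray, rtol: float = 1e-9) -> ElbowResult:
    """Maximum-curvature elbow of a WSS scree over k = 1..k_max.

    The scree is monotonised (restart noise can produce tiny increases), then
    the interior k maximising the second difference
    ``WSS(k-1) - 2 WSS(k) + WSS(k+1)`` is returned; ties take the smallest k
    and are flagged.  A scree with no decrease at all is degenerate and yields
    k_elbow = 1 (no evidence of structure).
    """
    wss = np.asarray(wss, dtype=float)
    if len(wss) < 3:
        raise ValueError("need WSS for at least 3 values of k")
    wss = np.minimum.accumulate(wss)
    scale = max(abs(wss[0]), 1.0)
    if wss[0] - wss[-1] <= rtol * scale:
        return ElbowResult(1, np.zeros(len(wss) - 2), tie=True, degenerate=True)
    d2 = wss[:-2] - 2 * wss[1:-1] + wss[2:]
    best = int(np.argmax(d2))
    tie = bool(np.sum(np.isclose(d2, d2[best], rtol=1e-9, atol=rtol * scale)) > 1)
    return ElbowResult(best + 2, d2, tie=tie)  # interior k starts at 2


@dataclass
class ClusterResult:
    """Cohort stratification for one (target measure, OAR) pairing."""

    parameter_pair: tuple[str, str]
    k_scree: np.ndarray
    k_elbow: int
    k_used: int
    assignments: dict[str, int]
    retained_clusters: dict[int, list[str]]
    outlier_patients: list[str]
    seed: int
    n_restarts: int
    elbow_tie: bool = False
    elbow_degenerate: bool = False
    distance: DistanceMatrix | None = field(default=None, repr=False)

    @property
    def cluster_sizes(self) -> dict[int, int]:
        sizes: dict[int, int] = {}
        for c in self.assignments.values():
            sizes[c] = sizes.get(c, 0) + 1
        return sizes


def cluster_cohort(
    target_series: Mapping[str, DeviationSeries],
    oar_series: Mapping[str, DeviationSeries],
    k_max: int = 8,
    min_size: int = 10,
    seed: int = 0,
    n_restarts: int = 50,
    dtw_config: DtwConfig | None = None,
) -> ClusterResult:
    """Full 2-D trajectory clustering for one OAR.

    Pairs each patient's representative-target and OAR deviation series,
    computes the dependent-DTW distance matrix, picks k by elbow + 1, runs
    k-means on the distance rows, and excludes clusters smaller than
    ``min_size`` as outlier patients.
    """
    if set(target_series) != set(oar_series):
        raise ValueError("target and OAR series cover different patients")
    paired: dict[str, BivariateSeries] = {
        pid: pair_series(target_series[pid], oar_series[pid]) for pid in target_series
    }
    dmat = distance_matrix(paired, dtw_config)
    wss = wss_curve(dmat, k_max, seed=seed, n_restarts=n_restarts)
    elbow = elbow_k(wss)
    k_used = min(elbow.k_elbow + 1, dmat.n)
    labels, _ = kmeans_rows(dmat, k_used, seed=seed, n_restarts=n_restarts)
    assignments = {pid: int(lab) for pid, lab in zip(dmat.ids, labels)}
    members: dict[int, list[str]] = {}
    for pid, lab in assignments.items():
        members.setdefault(lab, []).append(pid)
    retained = {c: pids for c, pids in sorted(members.items()) if len(pids) >= min_size}
    outliers = sorted(pid for c, pids in members.items() if c not in retained for pid in pids)
    if not retained:
        raise ValueError("no retained clusters: every cluster is below min_size")
    pair = next(iter(paired.values())).parameter_pair
    return ClusterResult(
        parameter_pair=pair,
        k_scree=wss,
        k_elbow=elbow.k_elbow,
        k_used=k_used,
        assignments=assignments,
        retained_clusters=retained,
        outlier_patients=outliers,
        seed=seed,
        n_restarts=n_restarts,
        elbow_tie=elbow.tie,
        elbow_degenerate=elbow.degenerate,
        distance=dmat,
    )
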