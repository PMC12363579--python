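"""Dynamic time warping for univariate and dependent-bivariate deviation series.

DTW finds the minimum cumulative local cost over monotone alignments of two
time axes, so two trajectories with the same shape but slightly shifted or
stretched timing compare as similar.  This is the dissimilarity underlying the
distinctiveness statistic and the trajectory clustering.

Series are compared in raw percent-deviation units without z-normalisation:
amplitude differences are exactly what separates a stable from a fluctuating
patient, and normalising them away would erase the signal of interest.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal, Mapping, Sequence

import numpy as np
import pandas as pd

from .data import BivariateSeries, DeviationSeries


@dataclass(frozen=True)
class DtwConfig:
    """Step pattern, windowing and normalisation choices.

    ``symmetric2`` (diagonal steps weighted twice) with no window and no
    normalisation is the default, matching the conventions of the standard
    time-series-clustering packages; ``symmetric1`` is kept for textbook
    examples.  ``window`` is a Sakoe-Chiba radius on |i - j|.
    """

    step_pattern: Literal["symmetric1", "symmetric2"] = "symmetric2"
    window: int | None = None
    normalize: Literal["none", "path_length"] = "none"

    def __post_init__(self) -> None:
        if self.step_pattern not in ("symmetric1", "symmetric2"):
            raise ValueError(f"unknown step pattern {self.step_pattern!r}")
        if self.window is not None and self.window < 0:
            raise ValueError("window radius must be >= 0")
        if self.normalize not in ("none", "path_length"):
            raise ValueError(f"unknown normalization {self.normalize!r}")
        if self.normalize == "path_length" and self.step_pattern == "symmetric1":
            raise ValueError("path_length normalization requires symmetric2")


def _local_cost(x: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Pairwise local cost: |xi - yj| in 1-D, Euclidean row distance in 2-D."""
    if x.ndim == 1:
        return np.abs(x[:, None] - y[None, :])
    diff = x[:, None, :] - y[None, :, :]
    return np.sqrt(np.einsum("ijk,ijk->ij", diff, diff))


def _dtw_cost(cost: np.ndarray, config: DtwConfig) -> float:
    n, m = cost.shape
    r = config.window
    if r is not None and r < abs(n - m):
        raise ValueError(
            f"Sakoe-Chiba radius {r} admits no warping path for lengths {n} and {m}"
        )
    sym2 = config.step_pattern == "symmetric2"
    big = np.inf
    # The initial cell carries weight 1; diagonal *steps* carry weight 2 under
    # symmetric2.  Row i of the cumulative table is built from row i - 1.
    prev = np.full(m, big)
    for i in range(n):
        cur = np.full(m, big)
        lo = 0 if r is None else max(0, i - r)
        hi = m - 1 if r is None else min(m - 1, i + r)
        ci = cost[i]
        for j in range(lo, hi + 1):
            c = ci[j]
            if i == 0 and j == 0:
                cur[j] = c
                continue
            diag = prev[j - 1] + (2.0 * c if sym2 else c) if j > 0 else big
            up = prev[j] + c
            left = cur[j - 1] + c if j > 0 else big
            cur[j] = min(up, left, diag)
        prev = cur
    d = prev[m - 1]
    if not np.isfinite(d):
        raise ValueError("window admits no warping path")
    if config.normalize == "path_length":
        d /= n + m
    return float(d)


def dtw(x: Sequence[float], y: Sequence[float], config: DtwConfig | None = None) -> float:
    """DTW distance between two univariate series (absolute local cost)."""
    config = config or DtwConfig()
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.ndim != 1 or y.ndim != 1:
        raise ValueError("dtw expects 1-D series; use dtw_multivariate for 2-D")
    if x.size == 0 or y.size == 0:
        raise ValueError("empty series")
    return _dtw_cost(_local_cost(x, y), config)


def dtw_multivariate(
    X: np.ndarray, Y: np.ndarray, config: DtwConfig | None = None
) -> float:
    """Dependent multivariate DTW: one shared alignment, Euclidean local cost.

    Both series must be (length x d) with the same dimensionality d; the two
    dimensions are warped jointly, as in clustering of paired
    (target D95, OAR dose) trajectories.
    """
    config = config or DtwConfig()
    X = np.atleast_2d(np.asarray(X, dtype=float))
    Y = np.atleast_2d(np.asarray(Y, dtype=float))
    if X.shape[0] == 0 or Y.shape[0] == 0:
        raise ValueError("empty series")
    if X.shape[1] != Y.shape[1]:
        raise ValueError(f"dimension mismatch: {X.shape[1]} vs {Y.shape[1]}")
    return _dtw_cost(_local_cost(X, Y), config)


@dataclass
class DistanceMatrix:
    """Symmetric cohort dissimilarity matrix with series identifiers."""

    ids: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.ids)
        if self.values.shape != (n, n):
            raise ValueError("matrix shape does not match identifiers")
        if not np.allclose(self.values, self.values.T):
            raise ValueError("distance matrix must be symmetric")
        if np.any(self.values < 0) or not np.all(np.isfinite(self.values)):
            raise ValueError("distances must be finite and non-negative")

    @property
    def n(self) -> int:
        return len(self.ids)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.ids, columns=self.ids)

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index_label="id")

    @classmethod
    def from_csv(cls, path) -> "DistanceMatrix":
        df = pd.read_csv(path, index_col=0)
        return cls(list(df.index.astype(str)), df.to_numpy(dtype=float))


def distance_matrix(
    series: Mapping[str, DeviationSeries] | Mapping[str, BivariateSeries],
    config: DtwConfig | None = None,
) -> DistanceMatrix:
    """All-pairs DTW over a cohort (upper triangle computed, then mirrored).

    Masked fractions are dropped before alignment, so patients with missing
    fractions are compared on their observed trajectories.
    """
    config = config or DtwConfig()
    if len(series) < 2:
        raise ValueError("need >= 2 series")
    ids = sorted(series)
    arrays = []
    for pid in ids:
        s = series[pid]
        if isinstance(s, BivariateSeries):
            arrays.append(s.present())
        else:
            arrays.append(s.present()[1])
    n = len(ids)
    D = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            a, b = arrays[i], arrays[j]
            if a.ndim == 2:
                D[i, j] = dtw_multivariate(a, b, config)
            else:
                D[i, j] = dtw(a, b, config)
            D[j, i] = D[i, j]
    return DistanceMatrix(ids, D)
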