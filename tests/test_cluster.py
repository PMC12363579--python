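import itertools

import numpy as np
import pandas as pd
import pytest

from fxtrend import (
    DeviationSeries,
    DistanceMatrix,
    cluster_cohort,
    distinctiveness,
    elbow_k,
    kmeans_rows,
    select_representative,
    wss_curve,
)


def _dmat(values, ids=None):
    values = np.asarray(values, float)
    ids = ids or [f"P{i}" for i in range(len(values))]
    return DistanceMatrix(ids, values)


class TestDistinctiveness:
    def test_identical_series_zero(self):
        d = distinctiveness(_dmat(np.zeros((4, 4))))
        assert (d == 0).all()

    def test_pair_at_distance_d(self):
        d = distinctiveness(_dmat([[0.0, 3.5], [3.5, 0.0]]))
        assert (d == 3.5).all()

    def test_hand_computed_row_means(self):
        m = [
            [0.0, 1.0, 2.0, 3.0],
            [1.0, 0.0, 4.0, 5.0],
            [2.0, 4.0, 0.0, 6.0],
            [3.0, 5.0, 6.0, 0.0],
        ]
        d = distinctiveness(_dmat(m))
        np.testing.assert_allclose(d.to_numpy(), [2.0, 10 / 3, 4.0, 14 / 3])

    def test_single_series_rejected(self):
        with pytest.raises(ValueError):
            distinctiveness(_dmat([[0.0]]))


class TestSelectRepresentative:
    def _tables(self, variances):
        rng = np.random.default_rng(0)
        out = {}
        for p, v in variances.items():
            vals = rng.normal(size=41)
            vals = (vals - vals.mean()) / vals.std(ddof=1) * np.sqrt(v) + 10
            out[p] = pd.Series(vals[:40])
        return out

    def test_lowest_variance_wins(self):
        tables = self._tables({"GTV_D95": 5.0, "CTV_D95": 1.0, "PTV_D95": 1385.9})
        sel = select_representative(tables)
        assert sel.parameter == "CTV_D95"
        assert sel.variances["PTV_D95"] == max(sel.variances.values())

    def test_tie_broken_by_precedence(self):
        t = pd.Series([1.0, 2.0, 3.0])
        sel = select_representative({"PTV_D95": t.copy(), "GTV_D95": t.copy()})
        assert sel.parameter == "GTV_D95"
        assert sel.tie

    def test_single_candidate(self):
        sel = select_representative({"PTV_D95": pd.Series([1.0, 4.0])})
        assert sel.parameter == "PTV_D95"

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            select_representative({})


def brute_force_two_partition(rows):
    """Exhaustive minimum WSS over all 2-partitions (oracle for n <= 8)."""
    n = len(rows)
    best, best_labels = np.inf, None
    for bits in range(1, 2 ** (n - 1)):
        labels = np.array([(bits >> i) & 1 for i in range(n)])
        wss = 0.0
        for c in (0, 1):
            grp = rows[labels == c]
            if len(grp):
                wss += ((grp - grp.mean(axis=0)) ** 2).sum()
        if wss < best:
            best, best_labels = wss, labels
    return best, best_labels


class TestKmeansRows:
    def test_two_identical_groups_recovered(self):
        rows = np.array([[0.0, 0, 0]] * 3 + [[9.0, 9, 9]] * 3)
        labels, wss = kmeans_rows(_dmat(_rows_to_dmat(rows)), 2, seed=0)
        assert wss == pytest.approx(0.0, abs=1e-12)
        assert len({tuple(labels[:3]), tuple(labels[3:])}) == 2

    def test_k_equals_n_gives_zero_wss(self, rng):
        m = _random_dmat(rng, 5)
        labels, wss = kmeans_rows(m, 5, seed=1)
        assert wss == pytest.approx(0.0, abs=1e-9)
        assert len(set(labels)) == 5

    def test_matches_exhaustive_bipartition_search(self, rng):
        for n in (6, 7, 8):
            m = _random_dmat(rng, n)
            labels, wss = kmeans_rows(m, 2, seed=3)
            best, _ = brute_force_two_partition(m.values)
            assert wss == pytest.approx(best, rel=1e-9)

    def test_k_out_of_range(self, rng):
        m = _random_dmat(rng, 4)
        with pytest.raises(ValueError):
            kmeans_rows(m, 5)
        with pytest.raises(ValueError):
            kmeans_rows(m, 1)

    def test_deterministic_given_seed(self, rng):
        m = _random_dmat(rng, 10)
        assert np.array_equal(kmeans_rows(m, 3, seed=9)[0], kmeans_rows(m, 3, seed=9)[0])


def _random_dmat(rng, n):
    a = np.abs(rng.normal(size=(n, n)))
    a = (a + a.T) / 2
    np.fill_diagonal(a, 0.0)
    return _dmat(a)


def _rows_to_dmat(rows):
    from scipy.spatial.distance import cdist

    d = cdist(rows, rows)
    np.fill_diagonal(d, 0.0)
    return d


class TestElbow:
    def test_sharp_knee_at_two(self):
        assert elbow_k([100, 20, 18, 17, 16]).k_elbow == 2

    def test_knee_at_three(self):
        assert elbow_k([100, 60, 20, 19, 18]).k_elbow == 3

    def test_linear_decay_ties_to_smallest_interior(self):
        res = elbow_k([100, 80, 60, 40, 20])
        assert res.k_elbow == 2
        assert res.tie

    def test_flat_scree_degenerate(self):
        res = elbow_k([1e-12, 1e-13, 1e-13, 1e-13])
        assert res.degenerate
        assert res.k_elbow == 1

    def test_needs_three_points(self):
        with pytest.raises(ValueError):
            elbow_k([5.0, 1.0])

    def test_nonmonotone_input_monotonized(self):
        assert elbow_k([100, 20, 21, 17, 16]).k_elbow == 2


def _series_cohort(trajectories):
    return {
        pid: DeviationSeries(pid, "CTV_D95", np.asarray(t, float))
        for pid, t in trajectories.items()
    }


class TestClusterCohort:
    def _paired(self, targets, oars):
        return _series_cohort(targets), {
            pid: DeviationSeries(pid, "Lung_Dmean", np.asarray(t, float))
            for pid, t in oars.items()
        }

    def test_small_cluster_excluded_as_outliers(self, rng):
        """A tight 32-patient group plus 8 mutually scattered patients leaves
        one retained cluster and 8 outlier patients."""
        f = np.arange(30.0)
        targets, oars = {}, {}
        for i in range(32):
            targets[f"A{i:02d}"] = 0.01 * f + rng.normal(0, 0.02, 30)
            oars[f"A{i:02d}"] = 0.05 * f + rng.normal(0, 0.02, 30)
        for i in range(8):
            # two far-out subgroups of four, well away from the tight majority
            level = (50.0 + 5.0 * (i % 4)) * (1 if i < 4 else -1)
            targets[f"B{i}"] = np.full(30, level / 10) + rng.normal(0, 0.02, 30)
            oars[f"B{i}"] = np.full(30, level) + rng.normal(0, 0.02, 30)
        t, o = self._paired(targets, oars)
        res = cluster_cohort(t, o, seed=0)
        assert len(res.retained_clusters) == 1
        (members,) = res.retained_clusters.values()
        assert sorted(members) == sorted(k for k in targets if k.startswith("A"))
        assert len(res.outlier_patients) == 8

    def test_partition_accounting(self, default_cohort, default_series):
        from fxtrend import series_by_parameter

        res = cluster_cohort(
            series_by_parameter(default_series, "CTV_D95"),
            series_by_parameter(default_series, "Lung_Dmean"),
            seed=0,
        )
        retained = sum(len(p) for p in res.retained_clusters.values())
        assert retained + len(res.outlier_patients) == 40
        assert all(len(p) >= 10 for p in res.retained_clusters.values())
        assert res.k_used == res.k_elbow + 1

    def test_identical_cohort_degenerate(self):
        f = np.arange(30.0)
        targets = {f"P{i}": 0.01 * f for i in range(12)}
        oars = {f"P{i}": 0.1 * f for i in range(12)}
        t, o = self._paired(targets, oars)
        res = cluster_cohort(t, o, min_size=2, seed=0)
        assert res.elbow_degenerate
        assert res.k_used == 2

    def test_all_clusters_too_small_is_an_error(self, rng):
        f = np.arange(30.0)
        targets = {f"P{i}": rng.normal(0, 5, 30) for i in range(6)}
        oars = {f"P{i}": rng.normal(0, 50, 30) for i in range(6)}
        t, o = self._paired(targets, oars)
        with pytest.raises(ValueError, match="retained"):
            cluster_cohort(t, o, min_size=10, seed=0)

    def test_determinism_end_to_end(self, rng):
        f = np.arange(30.0)
        targets = {f"P{i}": rng.normal(0, 1, 30) for i in range(12)}
        oars = {f"P{i}": rng.normal(0, 3, 30) for i in range(12)}
        t, o = self._paired(targets, oars)
        a = cluster_cohort(t, o, min_size=2, seed=4)
        b = cluster_cohort(t, o, min_size=2, seed=4)
        assert a.assignments == b.assignments
        np.testing.assert_array_equal(a.k_scree, b.k_scree)
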