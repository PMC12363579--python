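"""Per-cluster mean deviation trajectories and report assembly.

For each retained cluster the per-fraction mean percent deviation is
summarised with a 95 % confidence band under the standard normal
approximation, mean ± 1.96 · SD/√n (sample SD, n − 1 denominator).  The
normal z is used even for small clusters, honouring the published procedure;
for cluster sizes near the retention minimum of 10 the band is therefore
slightly anticonservative.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .data import DeviationSeries
from .cluster import ClusterResult

Z95 = 1.96


@dataclass
class TrajectorySummary:
    """Per-fraction mean and 95 % band for one cluster and parameter."""

    cluster_id: int
    parameter: str
    table: pd.DataFrame  # columns: fraction, n, mean, ci_low, ci_high


def mean_trajectory(
    members: Mapping[str, DeviationSeries] | Iterable[DeviationSeries],
    cluster_id: int = 0,
) -> TrajectorySummary:
    """Cross-patient mean trajectory with normal-approximation 95 % band.

    Fractions where fewer than two members have data are masked (NaN band and
    mean).
    """
    series = list(members.values()) if isinstance(members, Mapping) else list(members)
    if not series:
        raise ValueError("empty cluster")
    parameter = series[0].parameter
    F = max(s.n_fractions for s in series)
    rows = []
    for f in range(1, F + 1):
        vals = np.array(
            [s.deviations[f - 1] for s in series if f <= s.n_fractions and s.mask[f - 1]]
        )
        n = len(vals)
        if n < 2:
            rows.append((f, n, np.nan, np.nan, np.nan))
            continue
        mean = vals.mean()
        half = Z95 * vals.std(ddof=1) / np.sqrt(n)
        rows.append((f, n, mean, mean - half, mean + half))
    table = pd.DataFrame(rows, columns=["fraction", "n", "mean", "ci_low", "ci_high"])
    return TrajectorySummary(cluster_id, parameter, table)


def cluster_trajectories(
    result: ClusterResult, series: Mapping[str, DeviationSeries]
) -> dict[int, TrajectorySummary]:
    """Mean trajectory of one parameter for every retained cluster."""
    out = {}
    for cid, members in result.retained_clusters.items():
        out[cid] = mean_trajectory({pid: series[pid] for pid in members}, cid)
    return out


def assemble_report(
    trends: pd.DataFrame,
    distinctiveness_tables: Mapping[str, pd.Series] | None = None,
    cluster_results: Mapping[str, ClusterResult] | None = None,
    trajectories: Mapping[str, Mapping[int, TrajectorySummary]] | None = None,
) -> dict:
    """Bundle one cohort run's outputs into a machine-readable report.

    Patient sets must agree between the clustering inputs; an absent
    clustering section is recorded explicitly rather than silently dropped.
    """
    report: dict = {"tables": {"trends": trends}, "index": {"sections": ["trends"]}}
    if distinctiveness_tables:
        dist = pd.DataFrame(distinctiveness_tables)
        dist.index.name = "patient_id"
        report["tables"]["distinctiveness"] = dist.reset_index()
        report["index"]["sections"].append("distinctiveness")
    if cluster_results:
        patient_sets = {frozenset(r.assignments) for r in cluster_results.values()}
        if len(patient_sets) > 1:
            raise ValueError("mismatched patient sets across cluster results")
        if distinctiveness_tables:
            dist_patients = {frozenset(t.index) for t in distinctiveness_tables.values()}
            if dist_patients and dist_patients != patient_sets:
                raise ValueError("mismatched patient sets between sections")
        rows = []
        for oar, res in cluster_results.items():
            for pid, cid in sorted(res.assignments.items()):
                rows.append(
                    {
                        "oar": oar,
                        "patient_id": pid,
                        "cluster": cid,
                        "retained": cid in res.retained_clusters,
                    }
                )
        report["tables"]["clusters"] = pd.DataFrame(rows)
        report["index"]["sections"].append("clusters")
        report["index"]["clustering"] = {
            oar: {
                "k_elbow": res.k_elbow,
                "k_used": res.k_used,
                "wss": [float(w) for w in res.k_scree],
                "retained_sizes": {str(c): len(p) for c, p in res.retained_clusters.items()},
                "n_outlier_patients": len(res.outlier_patients),
            }
            for oar, res in cluster_results.items()
        }
    else:
        report["index"]["clustering"] = "absent"
    if trajectories:
        rows = []
        for oar, by_cluster in trajectories.items():
            for cid, summ in by_cluster.items():
                t = summ.table.copy()
                t.insert(0, "parameter", summ.parameter)
                t.insert(0, "cluster", cid)
                t.insert(0, "oar", oar)
                rows.append(t)
        report["tables"]["trajectories"] = pd.concat(rows, ignore_index=True)
        report["index"]["sections"].append("trajectories")
    return report


def write_report(report: dict, out_dir) -> None:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for name, table in report["tables"].items():
        table.to_csv(out / f"{name}.csv", index=False)
    with open(out / "index.json", "w", encoding="utf-8") as fh:
        json.dump(report["index"], fh, indent=2)


def read_report(out_dir) -> dict:
    out = Path(out_dir)
    with open(out / "index.json", encoding="utf-8") as fh:
        index = json.load(fh)
    tables = {
        p.stem: pd.read_csv(p) for p in sorted(out.glob("*.csv"))
    }
    return {"tables": tables, "index": index}
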