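#!/usr/bin/env python
"""Stratify patients by 2-D dose-deviation trajectory clustering.

For each organ-at-risk dose measure, each patient's paired (representative
target D95, OAR dose) percent-deviation series is compared by dependent DTW;
k-means on the distance-matrix rows with the elbow + 1 cluster count and the
minimum-size-10 exclusion rule yields the retained clusters, whose mean
trajectories with normal-approximation 95 % bands are tabulated.

Reads results/records.csv and results/representative.txt (run 01-03 first);
writes results/clusters.csv, results/cluster_summary.csv and
results/trajectories.csv.
"""

import argparse
from pathlib import Path

import pandas as pd

from fxtrend import build_series, cluster_cohort, read_records, series_by_parameter
from fxtrend.data import OAR_DOSE_PARAMETERS
from fxtrend.trajectory import cluster_trajectories

RESULTS = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--records", type=Path, default=RESULTS / "records.csv")
    parser.add_argument("--seed", type=int, default=0)
    parser.add_argument("--out-dir", type=Path, default=RESULTS)
    args = parser.parse_args()

    series = build_series(read_records(args.records))
    rep_file = args.out_dir / "representative.txt"
    representative = rep_file.read_text().strip() if rep_file.exists() else "CTV_D95"
    target = series_by_parameter(series, representative)

    assignment_rows, summary_rows, traj_rows = [], [], []
    for oar in OAR_DOSE_PARAMETERS:
        result = cluster_cohort(
            target, series_by_parameter(series, oar), seed=args.seed
        )
        sizes = {c: len(p) for c, p in result.retained_clusters.items()}
        print(
            f"{representative} + {oar}: k_elbow={result.k_elbow}, "
            f"k_used={result.k_used}, retained sizes {sizes}, "
            f"{len(result.outlier_patients)} outlier patients"
        )
        summary_rows.append(
            {
                "oar": oar,
                "k_elbow": result.k_elbow,
                "k_used": result.k_used,
                "n_retained_clusters": len(sizes),
                "retained_sizes": "+".join(str(s) for s in sorted(sizes.values())),
                "n_outlier_patients": len(result.outlier_patients),
            }
        )
        for pid, cid in sorted(result.assignments.items()):
            assignment_rows.append(
                {
                    "oar": oar,
                    "patient_id": pid,
                    "cluster": cid,
                    "retained": cid in result.retained_clusters,
                }
            )
        for parameter, pseries in ((representative, target),
                                   (oar, series_by_parameter(series, oar))):
            for cid, summ in cluster_trajectories(result, pseries).items():
                t = summ.table.copy()
                t.insert(0, "parameter", parameter)
                t.insert(0, "cluster", cid)
                t.insert(0, "oar", oar)
                traj_rows.append(t)

    args.out_dir.mkdir(parents=True, exist_ok=True)
    pd.DataFrame(assignment_rows).to_csv(args.out_dir / "clusters.csv", index=False)
    pd.DataFrame(summary_rows).to_csv(args.out_dir / "cluster_summary.csv", index=False)
    traj = pd.concat(traj_rows, ignore_index=True)
    traj.to_csv(args.out_dir / "trajectories.csv", index=False)

    ctv = traj[traj["parameter"] == representative]
    print(
        f"\nmax |cluster-mean {representative} deviation| over all fractions/clusters: "
        f"{ctv['mean'].abs().max():.2f} %"
    )
    print(f"wrote {args.out_dir / 'clusters.csv'}, cluster_summary.csv, trajectories.csv")


if __name__ == "__main__":
    main()
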