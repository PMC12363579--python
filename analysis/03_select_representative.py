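#!/usr/bin/env python
"""Choose the representative target-coverage measure by distinctiveness.

For each target D95 measure (GTV, CTV, PTV) the cohort DTW distance matrix is
computed and each patient's distinctiveness (mean dissimilarity to all other
patients) derived; the measure with the lowest distinctiveness variance across
patients is the most stable cohort-wide descriptor of target coverage and is
carried into the 2-D clustering stage.

Reads results/records.csv; writes results/distinctiveness.csv and
results/representative.txt.
"""

import argparse
from pathlib import Path

import pandas as pd

from fxtrend import build_series, distance_matrix, read_records, series_by_parameter
from fxtrend.cluster import distinctiveness, select_representative
from fxtrend.data import TARGET_D95_PARAMETERS

RESULTS = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--records", type=Path, default=RESULTS / "records.csv")
    parser.add_argument("--out-dir", type=Path, default=RESULTS)
    args = parser.parse_args()

    series = build_series(read_records(args.records))
    tables = {
        p: distinctiveness(distance_matrix(series_by_parameter(series, p)))
        for p in TARGET_D95_PARAMETERS
    }
    selection = select_representative(tables)

    args.out_dir.mkdir(parents=True, exist_ok=True)
    df = pd.DataFrame(tables)
    df.index.name = "patient_id"
    df.to_csv(args.out_dir / "distinctiveness.csv")
    (args.out_dir / "representative.txt").write_text(selection.parameter + "\n")

    for p, v in selection.variances.items():
        marker = " <- selected" if p == selection.parameter else ""
        print(f"{p}: distinctiveness variance {v:.2f}{marker}")
    if selection.tie:
        print("note: tie broken by fixed precedence order")


if __name__ == "__main__":
    main()
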