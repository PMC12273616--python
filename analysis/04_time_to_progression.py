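"""Kaplan-Meier time to first stage increase and to medication initiation.

Both endpoints are stratified by baseline stage with right censoring at the
last follow-up visit; medication analysis excludes participants already
medicated at baseline.  Writes per-stratum survival tables and a medians
summary with 95% log-log confidence intervals.
"""

import sys
from pathlib import Path

import pandas as pd

sys.path.insert(0, str(Path(__file__).resolve().parent))
from common import SCRATCH, save

from nsdiss import (
    build_med_initiation_dataset,
    build_stage_increase_dataset,
    build_trajectories,
    km_by_stratum,
)


def summarize(curves, endpoint):
    rows = []
    for stratum, curve in curves.items():
        save(curve.to_frame(), f"04_km_{endpoint}_stage{stratum}.csv", index=False)
        rows.append({"stratum": stratum, "n": curve.n,
                     "median_years": curve.median,
                     "ci_lower": curve.median_ci[0], "ci_upper": curve.median_ci[1]})
    table = pd.DataFrame(rows).set_index("stratum")
    save(table, f"04_km_{endpoint}_medians.csv")
    return table


def main() -> None:
    analysis = pd.read_csv(SCRATCH / "analysis_set.csv",
                           dtype={"stage": "string"})
    analysis["stage"] = analysis["stage"].astype(object)
    trajs = build_trajectories(analysis)

    inc = summarize(km_by_stratum(build_stage_increase_dataset(trajs)),
                    "stage_increase")
    med_ds, med_log = build_med_initiation_dataset(trajs)
    med = summarize(km_by_stratum(med_ds), "medication")
    save(med_log, "04_medication_baseline_exclusions.csv", index=False)

    def fmt(v):
        return "NR" if v != v or v == float("inf") else f"{v:.1f}"

    print("median years to first stage increase (95% CI):")
    for s, row in inc.iterrows():
        print(f"  stage {s}: {fmt(row.median_years)} "
              f"({fmt(row.ci_lower)}-{fmt(row.ci_upper)}), n={int(row.n)}")
    print("median years to medication initiation (95% CI):")
    for s, row in med.iterrows():
        print(f"  stage {s}: {fmt(row.median_years)} "
              f"({fmt(row.ci_lower)}-{fmt(row.ci_upper)}), n={int(row.n)}")


if __name__ == "__main__":
    main()
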