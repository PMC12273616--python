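"""Stage every visit and build the longitudinal analysis set.

Applies the NSD-ISS rulebook with carry-forward of missing fields, then the
longitudinal exclusion rules (no follow-up; baseline below 2A; stage-2A
baseline without follow-up DAT).  Writes the baseline stage distribution and
the exclusion log.
"""

import sys
from pathlib import Path

sys.path.insert(0, str(Path(__file__).resolve().parent))
from common import SCRATCH, load_staged, save

from nsdiss import apply_longitudinal_exclusions, table_percent, tabulate_stage_by_year


def main() -> None:
    staged, config = load_staged()
    staged.to_csv(SCRATCH / "staged_visits.csv", index=False)
    analysis, exclusions = apply_longitudinal_exclusions(staged)
    analysis.to_csv(SCRATCH / "analysis_set.csv", index=False)

    counts = tabulate_stage_by_year(analysis, "observed", horizon_years=0)
    base = counts[[0]].rename(columns={0: "n"})
    base["pct"] = table_percent(counts)[0]
    save(base, "02_baseline_stage_distribution.csv")
    save(exclusions, "02_exclusions.csv", index=False)

    n_all = staged["participant_id"].nunique()
    n_kept = analysis["participant_id"].nunique()
    carried = (staged["carried_fields"] != "").sum()
    print(f"anchor config {config.version} (hash {config.config_hash})")
    print(f"{carried} visits used carry-forward for at least one field")
    print(f"analysis set: {n_kept}/{n_all} participants "
          f"(excluded: {exclusions['reason'].value_counts().to_dict()})")
    print("baseline stage distribution of the analysis set:")
    print(base[base['n'] > 0])


if __name__ == "__main__":
    main()
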