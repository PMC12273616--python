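"""Impact of medication initiation on assigned stage.

Compares the last visit before medication start with the first on-medication
visit (at least 90 days of exposure, both visits stageable without
carry-forward), classifies each pair as reverted/stable/progressed by
pre-visit stage, and compares pre-visit tracks between reverters and
nonreverters.
"""

import sys
from pathlib import Path

sys.path.insert(0, str(Path(__file__).resolve().parent))
from common import load_cohort, save

from nsdiss import (
    collect_med_transitions,
    compare_reverter_tracks,
    default_anchor_config,
    reversion_table,
)


def main() -> None:
    config = default_anchor_config()
    visits = load_cohort()
    transitions, log = collect_med_transitions(visits, config)

    rev = reversion_table(transitions)
    save(rev, "06_med_reversion_by_prestage.csv")
    save(compare_reverter_tracks(transitions), "06_med_reverter_tracks.csv")
    save(log, "06_med_exclusions.csv", index=False)

    print(f"{len(transitions)} eligible medication transitions "
          f"({log['reason'].value_counts().to_dict()} excluded)")
    for stage in ("2B", "3", "4"):
        row = rev.loc[stage]
        if row["n"]:
            print(f"  pre-stage {stage} (n={int(row['n'])}): "
                  f"{row['reverted_pct']:.0f}% reverted, "
                  f"{row['stable_pct']:.0f}% stable, "
                  f"{row['progressed_pct']:.0f}% progressed")


if __name__ == "__main__":
    main()
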