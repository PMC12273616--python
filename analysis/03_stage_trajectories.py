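"""Stage frequencies over 5 years, completer flows, and the HY comparator.

Tabulates the NSD-ISS stage mix at each annual visit (observed and
LOCF-completers modes), exports the year-to-year transition flows for
baseline stages 2B/3/4 as a Sankey document, and tabulates Hoehn & Yahr
stage with the same rules for comparison.
"""

import json
import sys
from pathlib import Path

import pandas as pd

sys.path.insert(0, str(Path(__file__).resolve().parent))
from common import RESULTS, SCRATCH, save

from nsdiss import (
    sankey_export,
    table_percent,
    tabulate_hy_by_year,
    tabulate_stage_by_year,
    transition_flows,
)


def main() -> None:
    analysis = pd.read_csv(SCRATCH / "analysis_set.csv",
                           dtype={"stage": "string", "carried_fields": "string"})
    analysis["stage"] = analysis["stage"].astype(object)

    obs = tabulate_stage_by_year(analysis, "observed")
    locf = tabulate_stage_by_year(analysis, "locf_completers")
    save(obs, "03_stage_by_year_observed.csv")
    save(locf, "03_stage_by_year_locf_completers.csv")
    save(table_percent(locf, rounded=False), "03_stage_by_year_locf_pct.csv")
    save(tabulate_hy_by_year(analysis, "locf_completers"), "03_hy_by_year_locf.csv")

    flows = transition_flows(analysis)
    save(flows, "03_transition_flows.csv", index=False)
    with open(RESULTS / "03_sankey.json", "w", encoding="utf-8") as fh:
        json.dump(sankey_export(flows), fh, indent=2)

    pct = table_percent(locf)
    print(f"completers (stageable year-5 visit): {int(locf[5].sum())}")
    for stage in ("2B", "3", "4"):
        print(f"stage {stage}: {pct.loc[stage, 0]:.0f}% at baseline -> "
              f"{pct.loc[stage, 5]:.0f}% at year 5")
    off = flows[flows.stage_from != flows.stage_to]["n"].sum()
    print(f"{off} off-diagonal year-to-year transitions among completers")


if __name__ == "__main__":
    main()
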