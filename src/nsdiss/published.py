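"""Published summary tables of the PPMI NSD cohort, as fixture inputs.

The real participant-level PPMI data are access-restricted, but the
published cohort summaries — the baseline stage distribution (N=576) and
the track-combination counts among first-time progressors to stages 3-5 —
are public numbers.  This module encodes those counts and provides builders
that turn them into synthetic participant-level inputs, so the pipeline's
tabulation arithmetic can be exercised end-to-end against known printed
percentages.  The reconstructed visits are synthetic: they reproduce the
published *marginals*, not any real participant.
"""

from __future__ import annotations

import pandas as pd

from .anchors import AnchorConfig, default_anchor_config
from .stages import DOMAINS, STAGE_TO_BAND
from .tracks import ProgressionEvent

#: baseline NSD-ISS stage distribution of the published cohort (N=576)
BASELINE_STAGE_COUNTS: dict[str, int] = {
    "0": 1, "1A": 10, "1B": 2, "2A": 24, "2B": 137,
    "3": 324, "4": 73, "5": 4, "6": 1,
}

#: mutually exclusive track combinations among first progressors, by
#: destination stage (stage 3: N=110; stage 4: N=255; stage 5: N=28)
TRACK_COMBINATION_COUNTS: dict[str, dict[frozenset, int]] = {
    "3": {
        frozenset({"cognitive"}): 5,
        frozenset({"motor"}): 100,
        frozenset({"cognitive", "motor"}): 5,
    },
    "4": {
        frozenset({"cognitive"}): 27,
        frozenset({"motor"}): 106,
        frozenset({"other_nonmotor"}): 73,
        frozenset({"cognitive", "motor"}): 5,
        frozenset({"motor", "other_nonmotor"}): 36,
        frozenset({"cognitive", "other_nonmotor"}): 3,
        frozenset({"cognitive", "motor", "other_nonmotor"}): 5,
    },
    "5": {
        frozenset({"cognitive"}): 8,
        frozenset({"motor"}): 10,
        frozenset({"other_nonmotor"}): 3,
        frozenset({"cognitive", "motor"}): 2,
        frozenset({"motor", "other_nonmotor"}): 4,
        frozenset({"cognitive", "other_nonmotor"}): 0,
        frozenset({"cognitive", "motor", "other_nonmotor"}): 1,
    },
}


def _visit_for_stage(stage: str, pid: str, config: AnchorConfig) -> dict:
    """A synthetic baseline visit that the engine stages as ``stage``.

    Impairment stages are anchored on the motor domain; the score sits
    exactly on the band's lower threshold (boundary belongs to the band).
    """
    row = {
        "participant_id": pid, "cohort": "PD", "visit_year": 0.0,
        "s_status": "positive",
        "d_status": "negative" if stage in ("0", "1A", "2A") else "positive",
        "genetic_class": "snca_fully_penetrant" if stage == "0" else "none",
        "hy_stage": 0.0, "on_medication": False, "med_start_year": float("nan"),
    }
    for d in DOMAINS:
        row[config.domains[d].score_field] = 0.0
        row[config.domains[d].sign_field] = 0.0
    if stage in ("2A", "2B"):
        row[config.domains["motor"].sign_field] = 1.0
    band = STAGE_TO_BAND.get(stage)
    if band is not None:
        motor = config.domains["motor"]
        row[motor.score_field] = float(motor.bands[band])
        row[motor.sign_field] = 1.0
    return row


def baseline_visits_from_counts(counts: dict[str, int] | None = None,
                                config: AnchorConfig | None = None) -> pd.DataFrame:
    """Baseline visit table whose engine-assigned stages follow ``counts``."""
    counts = counts or BASELINE_STAGE_COUNTS
    config = config or default_anchor_config()
    rows, i = [], 0
    for stage, n in counts.items():
        for _ in range(n):
            rows.append(_visit_for_stage(stage, f"PUB{i:05d}", config))
            i += 1
    return pd.DataFrame(rows)


def progression_events_from_counts(
        combo_counts: dict[str, dict[frozenset, int]] | None = None
) -> list[ProgressionEvent]:
    """Synthetic first-progression events realizing the published combination
    counts, with destination-visit bands set to the destination stage's band
    for exactly the combination's domains."""
    combo_counts = combo_counts or TRACK_COMBINATION_COUNTS
    events, i = [], 0
    for stage, combos in combo_counts.items():
        band = STAGE_TO_BAND[stage]
        for combo, n in combos.items():
            bands = {d: (band if d in combo else "none") for d in DOMAINS}
            for _ in range(n):
                events.append(ProgressionEvent(
                    participant_id=f"EVT{i:05d}", time_years=1.0,
                    from_stage="2B", to_stage=stage, domain_bands=dict(bands)))
                i += 1
    return events
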