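"""Attribution of stage progression to functional domains ("tracks").

For participants whose first stage increase lands on stages 3-5, the
domains whose severity band supports the destination stage are the tracks
that "drove" the progression.  A domain contributes iff its band level at
the destination visit is at least the band anchoring the destination stage
(slight for 3, mild for 4, moderate for 5); because the stage is defined by
the maximal band, this is exactly the set of domains at that maximum.

The tabulation reports, per destination stage: N progressors, per-domain
"met criteria" counts (irrespective of other domains), and the seven
mutually exclusive domain combinations, which partition N.  When the anchor
config defines stage 3 without the other-nonmotor domain (no "slight" band
threshold), the stage-3 other-nonmotor cells are reported as missing (N/A)
rather than zero — the domain cannot, by definition, anchor that stage.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .anchors import AnchorConfig, default_anchor_config
from .stages import BAND_TO_STAGE, DOMAINS, STAGE_TO_BAND, band_rank
from .staging import evaluate_domains
from .trajectories import Trajectory, detect_first_stage_increase

#: the seven mutually exclusive combinations, in conventional table order
COMBINATIONS: tuple[frozenset, ...] = (
    frozenset({"cognitive"}),
    frozenset({"motor"}),
    frozenset({"other_nonmotor"}),
    frozenset({"cognitive", "motor"}),
    frozenset({"motor", "other_nonmotor"}),
    frozenset({"cognitive", "other_nonmotor"}),
    frozenset({"cognitive", "motor", "other_nonmotor"}),
)


def combination_label(combo: frozenset) -> str:
    if len(combo) == 1:
        return f"{next(iter(combo))}_only"
    return "+".join(d for d in DOMAINS if d in combo)


@dataclass(frozen=True)
class ProgressionEvent:
    """A first stage increase with the destination visit's domain bands."""

    participant_id: str
    time_years: float
    from_stage: str
    to_stage: str
    domain_bands: dict[str, str]


@dataclass
class TrackTable:
    """Track tabulation by destination stage (counts; NA = not applicable)."""

    counts: pd.DataFrame  # rows: domains + combinations + N; columns: stages
    n_by_stage: dict[str, int]

    def percent(self, rounded: bool = True) -> pd.DataFrame:
        n = pd.Series(self.n_by_stage)
        pct = 100.0 * self.counts.drop(index="N") / n
        return pct.round(0) if rounded else pct


def contributing_domains(event: ProgressionEvent) -> frozenset:
    """Domains whose band supports the destination stage."""
    need = band_rank(STAGE_TO_BAND[event.to_stage])
    return frozenset(d for d in DOMAINS
                     if band_rank(event.domain_bands.get(d, "none")) >= need)


def collect_progression_events(staged: pd.DataFrame,
                               trajectories: list[Trajectory],
                               config: AnchorConfig | None = None
                               ) -> list[ProgressionEvent]:
    """First-stage-increase events with destination-visit domain bands."""
    config = config or default_anchor_config()
    by_key = staged.set_index(["participant_id", "visit_year"])
    events = []
    for traj in trajectories:
        inc = detect_first_stage_increase(traj)
        if inc is None:
            continue
        row = by_key.loc[(traj.participant_id, inc.time_years)]
        bands = {name: st.severity_band
                 for name, st in evaluate_domains(row.to_dict(), config).items()}
        events.append(ProgressionEvent(
            participant_id=traj.participant_id, time_years=inc.time_years,
            from_stage=inc.from_stage, to_stage=inc.to_stage, domain_bands=bands))
    return events


def attribute_tracks(events: list[ProgressionEvent],
                     config: AnchorConfig | None = None,
                     stages: tuple[str, ...] = ("3", "4", "5")) -> TrackTable:
    """Tabulate contributing tracks by destination stage.

    Events to stages above the requested range (6) are ignored; an event
    below stage 3 is a caller error — there is no functional band to
    attribute.
    """
    config = config or default_anchor_config()
    for ev in events:
        if ev.to_stage not in BAND_TO_STAGE.values():
            raise ValueError(
                f"event destination below stage 3: {ev.participant_id} -> {ev.to_stage}")
    rows = ["N", *DOMAINS, *[combination_label(c) for c in COMBINATIONS]]
    counts = pd.DataFrame(0, index=rows, columns=list(stages), dtype="Int64")
    for ev in events:
        if ev.to_stage not in stages:
            continue
        combo = contributing_domains(ev)
        counts.loc["N", ev.to_stage] += 1
        for d in combo:
            counts.loc[d, ev.to_stage] += 1
        counts.loc[combination_label(combo), ev.to_stage] += 1
    # definitional N/A: a domain that cannot anchor a stage's band
    for stage in stages:
        need = STAGE_TO_BAND[stage]
        for d in DOMAINS:
            if config.domains[d].bands.get(need) is None:
                counts.loc[d, stage] = pd.NA
                for combo in COMBINATIONS:
                    if d in combo:
                        counts.loc[combination_label(combo), stage] = pd.NA
    n_by_stage = {s: int(counts.loc["N", s]) for s in stages}
    return TrackTable(counts=counts, n_by_stage=n_by_stage)


def attribute_tracks_within(events: list[ProgressionEvent],
                            horizon_years: float = 3.0,
                            config: AnchorConfig | None = None,
                            stages: tuple[str, ...] = ("3", "4", "5")) -> TrackTable:
    """Track tabulation restricted to events within the horizon (closed
    boundary: an event at exactly the horizon is included)."""
    if horizon_years < 0:
        raise ValueError("horizon_years must be >= 0")
    within = [ev for ev in events if ev.time_years <= horizon_years]
    return attribute_tracks(within, config=config, stages=stages)
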