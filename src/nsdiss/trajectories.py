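"""Cohort-level longitudinal outputs built from per-visit stage assignments.

Given a staged visit table (output of :func:`nsdiss.staging.stage_cohort`),
this module produces the longitudinal analysis surface:

* the analysis set after the study's exclusion rules (no follow-up,
  baseline below 2A, stage-2A baseline without a follow-up dopaminergic
  assessment), with a per-participant exclusion log — every participant
  lands in exactly one of analysis set or log;
* stage-by-year frequency tables, either over all observed stageable
  visits or for year-5 completers with last-stage-carried-forward (LOCF)
  filling of interim gaps;
* year-to-year stage transition flows (Sankey-ready) for completers;
* the same tabulation for Hoehn & Yahr stage as a clinical comparator;
* per-participant trajectories annotated with the first stage increase
  (the earliest visit whose stage rank strictly exceeds the baseline rank
  — returning to baseline after a reversion does not count).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .stages import STAGES, stage_rank


@dataclass(frozen=True)
class StageIncrease:
    time_years: float
    from_stage: str
    to_stage: str


@dataclass
class Trajectory:
    """Ordered staged visits of one participant, with event annotations."""

    participant_id: str
    times: tuple[float, ...]
    stages: tuple[str, ...]
    med_start_year: float = float("nan")
    on_med_at_baseline: bool = False

    def __post_init__(self) -> None:
        if len(self.times) == 0:
            raise ValueError("empty trajectory")
        if any(b <= a for a, b in zip(self.times, self.times[1:])):
            raise ValueError("visit times must be strictly increasing")

    @property
    def baseline_stage(self) -> str:
        return self.stages[0]

    @property
    def last_followup(self) -> float:
        return self.times[-1]


def detect_first_stage_increase(traj: Trajectory) -> StageIncrease | None:
    """Earliest visit whose stage rank strictly exceeds the baseline rank.

    Reversions below baseline and later returns *to* baseline are not
    increases; stage skips (e.g. 2B directly to 4) are kept as-is.  Returns
    None when the participant never exceeds baseline (right-censored at the
    last follow-up).
    """
    base = stage_rank(traj.baseline_stage)
    for t, s in zip(traj.times[1:], traj.stages[1:]):
        if stage_rank(s) > base:
            return StageIncrease(time_years=t, from_stage=traj.baseline_stage, to_stage=s)
    return None


# ---------------------------------------------------------------------------
# staged-table helpers


def _year_bin(times: pd.Series) -> pd.Series:
    """Nominal annual visit bin: nearest integer year (+-6-month window)."""
    return times.round().astype(int)


def _staged_only(staged: pd.DataFrame) -> pd.DataFrame:
    return staged[staged["stage"].notna()]


def build_trajectories(staged: pd.DataFrame) -> list[Trajectory]:
    """One :class:`Trajectory` per participant from stageable visits."""
    out = []
    for pid, grp in _staged_only(staged).groupby("participant_id", sort=True):
        grp = grp.sort_values("visit_year")
        med = grp["med_start_year"].iloc[0] if "med_start_year" in grp.columns else np.nan
        on_base = bool(grp["on_medication"].iloc[0]) if "on_medication" in grp.columns \
            and grp["visit_year"].iloc[0] == 0 else False
        out.append(Trajectory(
            participant_id=pid,
            times=tuple(grp["visit_year"]),
            stages=tuple(grp["stage"]),
            med_start_year=float(med) if med == med else float("nan"),
            on_med_at_baseline=on_base,
        ))
    return out


def apply_longitudinal_exclusions(staged: pd.DataFrame
                                  ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Apply the longitudinal analysis-set rules; log every exclusion.

    Rules, in order per participant:

    1. baseline visit unstageable (S−, S missing, or missing fields with
       nothing to carry) → ``not_nsd`` / ``unstageable_baseline``;
    2. no stageable follow-up visit → ``no_follow_up``;
    3. baseline stage 0/1A/1B → ``baseline_stage_below_2A``;
    4. baseline stage 2A with no follow-up visit at which the dopaminergic
       status was actually observed (not carried forward) →
       ``stage_2A_no_followup_dat``.

    Returns the retained staged rows and a log frame
    ``(participant_id, reason)`` covering every excluded participant.
    """
    reasons: dict[str, str] = {}
    keep: list[str] = []
    for pid, grp in staged.groupby("participant_id", sort=True):
        grp = grp.sort_values("visit_year")
        base = grp.iloc[0]
        if grp["visit_year"].iloc[0] != 0 or pd.isna(base["stage"]):
            r = base.get("unstageable_reason", "")
            reasons[pid] = "not_nsd" if r in ("s_negative", "s_missing") \
                else "unstageable_baseline"
            continue
        follow = grp[(grp["visit_year"] > 0) & grp["stage"].notna()]
        if len(follow) == 0:
            reasons[pid] = "no_follow_up"
            continue
        if stage_rank(base["stage"]) < stage_rank("2A"):
            reasons[pid] = "baseline_stage_below_2A"
            continue
        if base["stage"] == "2A":
            carried = follow["carried_fields"].fillna("").str.contains("d_status")
            observed_dat = follow["d_status"].notna() & ~carried
            if not observed_dat.any():
                reasons[pid] = "stage_2A_no_followup_dat"
                continue
        keep.append(pid)
    analysis = staged[staged["participant_id"].isin(keep)].copy()
    log = pd.DataFrame(
        [{"participant_id": p, "reason": r} for p, r in sorted(reasons.items())],
        columns=["participant_id", "reason"])
    return analysis, log


def _stage_year_frame(staged: pd.DataFrame, value_col: str) -> pd.DataFrame:
    """participants x years wide frame of the chosen per-visit value."""
    df = _staged_only(staged).copy() if value_col == "stage" \
        else staged[staged[value_col].notna()].copy()
    df["year"] = _year_bin(df["visit_year"])
    wide = (df.sort_values("visit_year")
              .drop_duplicates(["participant_id", "year"], keep="last")
              .pivot(index="participant_id", columns="year", values=value_col))
    return wide


def completer_ids(staged: pd.DataFrame, horizon_years: int = 5,
                  value_col: str = "stage") -> pd.Index:
    """Participants with an attended, stageable visit at the horizon year."""
    wide = _stage_year_frame(staged, value_col)
    if horizon_years not in wide.columns:
        return pd.Index([], name="participant_id")
    return wide.index[wide[horizon_years].notna()]


def tabulate_stage_by_year(staged: pd.DataFrame, mode: str = "observed",
                           horizon_years: int = 5,
                           value_col: str = "stage") -> pd.DataFrame:
    """Stage x year frequency table (counts), years 0..horizon.

    ``observed`` counts every attended, stageable visit.  ``locf_completers``
    restricts to participants stageable at the horizon visit and fills
    interim gaps with the last stage carried forward; LOCF never invents a
    label absent from the participant's observed history.
    """
    if mode not in ("observed", "locf_completers"):
        raise ValueError(f"unknown mode: {mode!r}")
    wide = _stage_year_frame(staged, value_col)
    years = list(range(0, horizon_years + 1))
    wide = wide.reindex(columns=years)
    if mode == "locf_completers":
        wide = wide[wide[horizon_years].notna()]
        wide = wide.ffill(axis=1)
    labels = STAGES if value_col == "stage" else sorted(
        pd.unique(wide.stack().dropna()))
    table = pd.DataFrame(
        {y: wide[y].value_counts().reindex(labels, fill_value=0) for y in years})
    table.index.name = value_col
    table.columns.name = "year"
    return table


def tabulate_hy_by_year(staged: pd.DataFrame, mode: str = "observed",
                        horizon_years: int = 5) -> pd.DataFrame:
    """Hoehn & Yahr stage x year table, same contract as the NSD table."""
    return tabulate_stage_by_year(staged, mode=mode, horizon_years=horizon_years,
                                  value_col="hy_stage")


def table_percent(counts: pd.DataFrame, rounded: bool = True) -> pd.DataFrame:
    """Within-year percentages of a frequency table (nearest integer when
    ``rounded``, matching the usual table style; raw otherwise)."""
    pct = 100.0 * counts / counts.sum(axis=0)
    return pct.round(0) if rounded else pct


def transition_flows(staged: pd.DataFrame,
                     baseline_stages: tuple[str, ...] = ("2B", "3", "4"),
                     horizon_years: int = 5) -> pd.DataFrame:
    """Year-to-year stage transition counts for LOCF-completed completers.

    Participants enter if they are stageable at the horizon visit and their
    baseline stage is in ``baseline_stages``.  Returns a long frame
    ``(year_from, stage_from, stage_to, n)``; for every year pair the total
    flow equals the number of included participants (conservation).
    """
    wide = _stage_year_frame(staged, "stage")
    years = list(range(0, horizon_years + 1))
    wide = wide.reindex(columns=years)
    wide = wide[wide[horizon_years].notna()].ffill(axis=1)
    wide = wide[wide[0].isin(baseline_stages)]
    if len(wide) == 0:
        return pd.DataFrame(columns=["year_from", "stage_from", "stage_to", "n"])
    rows = []
    for t in years[:-1]:
        counts = (wide.groupby([wide[t], wide[t + 1]]).size())
        for (s_from, s_to), n in counts.items():
            rows.append({"year_from": t, "stage_from": s_from,
                         "stage_to": s_to, "n": int(n)})
    return pd.DataFrame(rows).sort_values(
        ["year_from", "stage_from", "stage_to"]).reset_index(drop=True)


def sankey_export(flows: pd.DataFrame) -> dict:
    """Node/link document consumable by standard Sankey renderers."""
    if len(flows) == 0:
        return {"nodes": [], "links": []}
    years = sorted(set(flows["year_from"]) | {flows["year_from"].max() + 1})
    nodes, index = [], {}
    for y in years:
        for s in STAGES:
            present = ((flows["year_from"] == y) & (flows["stage_from"] == s)).any() or \
                      ((flows["year_from"] == y - 1) & (flows["stage_to"] == s)).any()
            if present:
                index[(y, s)] = len(nodes)
                nodes.append({"id": len(nodes), "year": int(y), "stage": s})
    links = [
        {"source": index[(int(r.year_from), r.stage_from)],
         "target": index[(int(r.year_from) + 1, r.stage_to)],
         "value": int(r.n)}
        for r in flows.itertuples()
    ]
    return {"nodes": nodes, "links": links}
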