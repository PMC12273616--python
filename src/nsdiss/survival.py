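"""Product-limit (Kaplan-Meier) analysis of stage progression and medication.

Two endpoints, both stratified by baseline stage and right-censored at the
last follow-up visit:

* time from enrollment to the first stage increase (strata 2B/3/4);
* time from enrollment to initiation of dopaminergic medication, defined as
  the first *visit* attended on medication (not the start date itself), for
  strata 2A-4 and excluding participants already medicated at baseline.

Estimation is the standard product-limit estimator with events preceding
censorings at tied times; the median confidence interval is obtained by
inverting the log-log (exponential Greenwood) confidence band, with an
undefined bound reported as NaN ("not reached") when the band never crosses
0.5.  Event times sit on the annual visit grid, so all estimates are
interval-censoring approximations at visit resolution.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter
from lifelines.utils import median_survival_times

from .trajectories import Trajectory, detect_first_stage_increase

#: columns of a survival dataset
SURVIVAL_COLUMNS = ["participant_id", "time_years", "event", "stratum"]


@dataclass
class KMCurve:
    """Product-limit estimate with at-risk bookkeeping and median CI."""

    timeline: np.ndarray          # distinct observed times, ascending
    survival: np.ndarray          # S(t) at each timeline point
    ci_lower: np.ndarray
    ci_upper: np.ndarray
    at_risk: np.ndarray
    n_events: np.ndarray
    n_censored: np.ndarray
    median: float                 # NaN / inf -> "not reached"
    median_ci: tuple[float, float]
    label: str = ""
    n: int = 0

    def survival_at(self, t: float) -> float:
        """Step-function value of S at time t (1 before the first event)."""
        idx = np.searchsorted(self.timeline, t, side="right") - 1
        return 1.0 if idx < 0 else float(self.survival[idx])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "time_years": self.timeline,
            "n_risk": self.at_risk,
            "n_event": self.n_events,
            "n_censored": self.n_censored,
            "survival": self.survival,
            "ci_lower": self.ci_lower,
            "ci_upper": self.ci_upper,
        })


def km_estimate(durations, events, label: str = "", alpha: float = 0.05) -> KMCurve:
    """Kaplan-Meier product-limit estimate of one stratum.

    ``durations``/``events`` are aligned arrays (event indicator 1 = stage
    increase / medication visit, 0 = right-censored).  Ties are resolved
    events-before-censorings, the product-limit convention.
    """
    durations = np.asarray(durations, dtype=float)
    events = np.asarray(events, dtype=bool)
    if len(durations) == 0:
        raise ValueError("empty stratum")
    if np.all(durations == 0) and not events.any():
        raise ValueError("all times zero with no events: nothing to estimate")

    kmf = KaplanMeierFitter(alpha=alpha)
    kmf.fit(durations, events, label=label or None)
    med = float(kmf.median_survival_time_)
    med_ci_frame = median_survival_times(kmf.confidence_interval_)
    lo, hi = (float(med_ci_frame.iloc[0, 0]), float(med_ci_frame.iloc[0, 1]))

    table = kmf.event_table.iloc[1:] if kmf.event_table.index[0] == 0 and \
        kmf.event_table.iloc[0][["observed", "censored"]].sum() == 0 else kmf.event_table
    timeline = table.index.to_numpy(dtype=float)
    sf = kmf.survival_function_
    ci = kmf.confidence_interval_
    surv = np.array([float(sf.loc[t].iloc[0]) for t in timeline])
    ci_lo = np.array([float(ci.loc[t].iloc[0]) for t in timeline])
    ci_hi = np.array([float(ci.loc[t].iloc[1]) for t in timeline])
    return KMCurve(
        timeline=timeline, survival=surv, ci_lower=ci_lo, ci_upper=ci_hi,
        at_risk=table["at_risk"].to_numpy(dtype=int),
        n_events=table["observed"].to_numpy(dtype=int),
        n_censored=table["censored"].to_numpy(dtype=int),
        median=med, median_ci=(lo, hi), label=label, n=int(len(durations)),
    )


def km_median_ci(curve: KMCurve, level: float = 0.95
                 ) -> tuple[float, float, float]:
    """(median, lower, upper) of a fitted curve; NaN/inf = not reached.

    The curve must have been fitted at the matching confidence level (the
    default pipeline fits at 95%).
    """
    if len(curve.timeline) == 0:
        raise ValueError("empty curve")
    if abs(level - 0.95) > 1e-12:
        raise ValueError(
            "curve carries the CI it was fitted with; refit km_estimate with "
            f"alpha={1 - level:g} instead")
    return curve.median, curve.median_ci[0], curve.median_ci[1]


# ---------------------------------------------------------------------------
# dataset construction


def build_stage_increase_dataset(trajectories: list[Trajectory],
                                 strata: tuple[str, ...] = ("2B", "3", "4")
                                 ) -> pd.DataFrame:
    """One survival row per participant with baseline stage in ``strata``.

    Event time is the first stage increase (annual grid); participants who
    never exceed baseline are censored at the last follow-up visit.
    """
    rows = []
    for traj in trajectories:
        if traj.baseline_stage not in strata:
            continue
        inc = detect_first_stage_increase(traj)
        rows.append({
            "participant_id": traj.participant_id,
            "time_years": inc.time_years if inc else traj.last_followup,
            "event": inc is not None,
            "stratum": traj.baseline_stage,
        })
    return pd.DataFrame(rows, columns=SURVIVAL_COLUMNS)


def build_med_initiation_dataset(trajectories: list[Trajectory],
                                 strata: tuple[str, ...] = ("2A", "2B", "3", "4")
                                 ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Time to the first on-medication visit; baseline-medicated are excluded.

    Returns ``(dataset, exclusion_log)``.  The event is the first *attended*
    visit at or after the medication start time; a start with no subsequent
    attended visit is censored at the last follow-up.
    """
    rows, excluded = [], []
    for traj in trajectories:
        if traj.baseline_stage not in strata:
            continue
        if traj.on_med_at_baseline or (
                not math.isnan(traj.med_start_year) and traj.med_start_year <= 0):
            excluded.append({"participant_id": traj.participant_id,
                             "reason": "on_medication_at_baseline"})
            continue
        time, event = traj.last_followup, False
        if not math.isnan(traj.med_start_year):
            after = [t for t in traj.times if t >= traj.med_start_year]
            if after:
                time, event = after[0], True
        rows.append({"participant_id": traj.participant_id, "time_years": time,
                     "event": event, "stratum": traj.baseline_stage})
    return (pd.DataFrame(rows, columns=SURVIVAL_COLUMNS),
            pd.DataFrame(excluded, columns=["participant_id", "reason"]))


def km_by_stratum(dataset: pd.DataFrame, alpha: float = 0.05) -> dict[str, KMCurve]:
    """Fit one KM curve per baseline-stage stratum of a survival dataset."""
    return {
        stratum: km_estimate(grp["time_years"], grp["event"], label=str(stratum),
                             alpha=alpha)
        for stratum, grp in dataset.groupby("stratum", sort=True)
    }
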