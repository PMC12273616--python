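"""Synthetic PPMI-like longitudinal cohorts with known ground truth.

The generator emulates the structure of an annual-visit observational PD /
prodromal cohort so that every downstream analysis (staging, tabulation,
survival, track attribution, medication impact) can be exercised and
validated without restricted real data:

* a latent NSD-ISS stage path per participant — discrete annual steps with
  geometric sojourn times parameterized by their median, non-decreasing in
  stage rank (disease never regresses; only *assigned* stage can revert,
  through the medication effect on scores);
* baseline stages concentrated in 2B/3/4, as in an early-PD cohort;
* visit scores drawn uniformly over the latent stage's anchor band in the
  active :class:`~nsdiss.anchors.AnchorConfig` (integer-rounded), plus
  bounded integer noise clipped to the band — visit-level fluctuation never
  flips a severity band on its own;
* medication initiation as a stage-dependent annual hazard, with a
  continuous start time inside the preceding visit interval; while on
  medication each domain score is reduced by a fixed per-domain amount
  (floored at 0), which is what makes stage reversion mechanistically
  producible;
* independent annual dropout (optionally stage-weighted) and
  field-level missingness at follow-up visits.

Everything is deterministic given the seed, and the random-number layout is
fixed per participant so that runs with different progression parameters
share common random numbers (monotone comparisons stay monotone).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field as dc_field

import numpy as np
import pandas as pd

from .anchors import AnchorConfig, ConfigurationError, default_anchor_config
from .stages import DOMAINS, SEVERITY_BANDS, STAGE_TO_BAND, band_rank, stage_rank

#: latent progression ladder (1B converts D first, so signs onset lands at 2B)
NEXT_STAGE: dict[str, str | None] = {
    "0": "1A", "1A": "1B", "1B": "2B", "2A": "2B",
    "2B": "3", "3": "4", "4": "5", "5": "6", "6": None,
}

#: stages at which the dopaminergic-deficit biomarker is abnormal
D_POSITIVE_STAGES = frozenset({"1B", "2B", "3", "4", "5", "6"})

_HY_BASE = {"0": 0, "1A": 0, "1B": 0, "2A": 0, "2B": 1, "3": 2, "4": 2, "5": 4, "6": 5}

#: baseline mix: the published PPMI NSD baseline distribution over stages 0-4,
#: renormalized (stages 5/6 are not simulated at baseline)
DEFAULT_BASELINE_MIX = {
    "0": 0.002, "1A": 0.018, "1B": 0.003, "2A": 0.042,
    "2B": 0.240, "3": 0.567, "4": 0.128,
}

DEFAULT_SOJOURN_MEDIANS = {
    "0": 10.0, "1A": 6.0, "1B": 4.0, "2A": 3.0,
    "2B": 2.0, "3": 5.0, "4": 8.0, "5": 10.0,
}

DEFAULT_MED_HAZARD = {
    "0": 0.0, "1A": 0.0, "1B": 0.0, "2A": 0.05,
    "2B": 0.28, "3": 0.55, "4": 0.60, "5": 0.60, "6": 0.60,
}

DEFAULT_MED_EFFECT = {"cognitive": 0.0, "motor": 4.0, "other_nonmotor": 1.0}


@dataclass
class SimulationParams:
    """Study conditions for one synthetic cohort."""

    n_participants: int = 576
    baseline_stage_mix: dict[str, float] = dc_field(
        default_factory=lambda: dict(DEFAULT_BASELINE_MIX))
    sojourn_median_years: dict[str, float] = dc_field(
        default_factory=lambda: dict(DEFAULT_SOJOURN_MEDIANS))
    med_initiation_hazard: dict[str, float] = dc_field(
        default_factory=lambda: dict(DEFAULT_MED_HAZARD))
    med_effect: dict[str, float] = dc_field(
        default_factory=lambda: dict(DEFAULT_MED_EFFECT))
    annual_dropout_prob: float = 0.05
    dropout_stage_multiplier: dict[str, float] = dc_field(default_factory=dict)
    missing_field_prob: float = 0.05
    score_noise: int = 1  # scores jitter by +-score_noise (0 = band-exact)
    primary_track_probs: dict[str, float] = dc_field(
        default_factory=lambda: {"motor": 0.85, "cognitive": 0.10, "other_nonmotor": 0.05})
    secondary_track_prob: float = 0.15
    n_years: int = 5
    seed: int = 0

    def validate(self) -> None:
        if self.n_participants < 1:
            raise ConfigurationError("n_participants must be >= 1")
        if self.n_years < 1:
            raise ConfigurationError("n_years must be >= 1")
        total = sum(self.baseline_stage_mix.values())
        if abs(total - 1.0) > 1e-9:
            raise ConfigurationError(
                f"baseline_stage_mix must sum to 1, got {total}")
        for label, p in self.baseline_stage_mix.items():
            stage_rank(label)  # raises on unknown label
            if not 0.0 <= p <= 1.0:
                raise ConfigurationError(f"baseline_stage_mix[{label}] out of [0,1]")
        for label, m in self.sojourn_median_years.items():
            if not m > 0:
                raise ConfigurationError(f"sojourn_median_years[{label}] must be > 0")
        for name, probs in (("med_initiation_hazard", self.med_initiation_hazard),
                            ("primary_track_probs", self.primary_track_probs)):
            for key, p in probs.items():
                if not 0.0 <= p <= 1.0:
                    raise ConfigurationError(f"{name}[{key}] out of [0,1]")
        for name, p in (("annual_dropout_prob", self.annual_dropout_prob),
                        ("missing_field_prob", self.missing_field_prob),
                        ("secondary_track_prob", self.secondary_track_prob)):
            if not 0.0 <= p <= 1.0:
                raise ConfigurationError(f"{name} out of [0,1]")
        if abs(sum(self.primary_track_probs.values()) - 1.0) > 1e-9:
            raise ConfigurationError("primary_track_probs must sum to 1")
        if self.score_noise < 0:
            raise ConfigurationError("score_noise must be >= 0")


@dataclass
class GroundTruth:
    """Latent state underlying a simulated cohort.

    ``stage_path`` has one row per participant-year (including years after
    dropout, so sojourn properties can be checked on the uncensored path);
    ``participants`` has one row per participant with the baseline stage,
    medication start year (NaN = never), dropout year (NaN = completed) and
    the domain chosen as the participant's primary impairment track.
    """

    stage_path: pd.DataFrame
    participants: pd.DataFrame


def annual_progression_prob(median_years: float) -> float:
    """Geometric-sojourn annual step probability with the given median.

    A geometric sojourn with per-year probability p has median m when
    p = 1 - 0.5**(1/m); an infinite median means no progression.
    """
    if math.isinf(median_years):
        return 0.0
    return 1.0 - 0.5 ** (1.0 / median_years)


def _band_score_range(dom_anchors, band: str) -> tuple[int, int]:
    """Integer score grid [lo, hi] spanned by a band.

    The top band and the "none" band are half-bounded; the top band uses a
    width-10 window above its threshold, "none" spans [0, lowest threshold).
    """
    if band == "none":
        lo, hi = 0.0, min(v for v in dom_anchors.bands.values() if v is not None)
    else:
        lo = dom_anchors.bands[band]
        width = dom_anchors.band_width(band)
        hi = lo + (10.0 if math.isinf(width) else width)
    return math.ceil(lo), math.ceil(hi) - 1


def _draw_band_score(dom_anchors, band: str, u: float, u_noise: float,
                     noise: int) -> int:
    """Integer score uniform over the band, plus band-bounded jitter.

    The jitter models visit-to-visit score fluctuation but is clipped to the
    band's score range: simulated measurement noise never flips the severity
    band, so the assigned stage tracks the latent stage exactly (medication
    is the only mechanism that moves scores across a boundary).
    """
    lo_i, hi_i = _band_score_range(dom_anchors, band)
    score = int(lo_i + math.floor(u * (hi_i - lo_i + 1)))
    if noise > 0:
        score += int(math.floor(u_noise * (2 * noise + 1))) - noise
    return max(lo_i, min(hi_i, score))


def _reachable_band(dom_anchors, band: str) -> str | None:
    """The band itself if the domain can anchor it, else None."""
    return band if dom_anchors.bands.get(band) is not None else None


def simulate_cohort(params: SimulationParams,
                    config: AnchorConfig | None = None
                    ) -> tuple[pd.DataFrame, GroundTruth]:
    """Generate a visit-level table and its ground truth.

    Returns ``(visits, truth)`` where ``visits`` follows the canonical
    schema consumed by :func:`nsdiss.staging.stage_cohort` and ``truth``
    carries the latent paths.  Field-level missingness is injected when
    ``params.missing_field_prob > 0`` (baseline is never blanked).
    """
    params.validate()
    config = config or default_anchor_config()

    mix_labels = sorted(params.baseline_stage_mix, key=stage_rank)
    mix_probs = np.array([params.baseline_stage_mix[s] for s in mix_labels])
    mix_cum = np.cumsum(mix_probs)
    step_prob = {s: annual_progression_prob(m)
                 for s, m in params.sojourn_median_years.items()}
    track_labels = list(DOMAINS)
    track_cum = np.cumsum([params.primary_track_probs.get(d, 0.0) for d in track_labels])

    rng = np.random.default_rng(params.seed)
    visit_rows: list[dict] = []
    path_rows: list[dict] = []
    part_rows: list[dict] = []

    for i in range(params.n_participants):
        pid = f"SYN{i:05d}"
        # fixed per-participant draw layout => common random numbers across
        # parameter settings
        u_base = rng.uniform()
        u_primary = rng.uniform()
        u_secondary = rng.uniform(size=len(track_labels))
        u_prog = rng.uniform(size=params.n_years)
        u_med = rng.uniform(size=params.n_years)
        u_med_frac = rng.uniform()
        u_drop = rng.uniform(size=params.n_years)
        u_scores = rng.uniform(size=(params.n_years + 1, len(track_labels)))
        u_noise = rng.uniform(size=(params.n_years + 1, len(track_labels)))
        u_hy = rng.uniform(size=params.n_years + 1)

        baseline = mix_labels[int(np.searchsorted(mix_cum, u_base, side="right"))]
        primary = track_labels[int(np.searchsorted(track_cum, u_primary, side="right"))]
        secondary = {d: u_secondary[j] < params.secondary_track_prob
                     for j, d in enumerate(track_labels)}
        genetic = "snca_fully_penetrant" if baseline == "0" else "none"

        # latent path
        path = [baseline]
        for t in range(1, params.n_years + 1):
            cur = path[-1]
            nxt = NEXT_STAGE[cur]
            p = step_prob.get(cur, 0.0)
            path.append(nxt if (nxt is not None and u_prog[t - 1] < p) else cur)

        # medication initiation on the annual hazard of the current stage
        med_start = math.nan
        for t in range(1, params.n_years + 1):
            hz = params.med_initiation_hazard.get(path[t - 1], 0.0)
            if u_med[t - 1] < hz:
                med_start = (t - 1) + u_med_frac  # inside the interval (t-1, t)
                break

        # dropout: participant misses visit t and all later ones
        drop_year = math.nan
        for t in range(1, params.n_years + 1):
            mult = params.dropout_stage_multiplier.get(path[t], 1.0)
            if u_drop[t - 1] < min(1.0, params.annual_dropout_prob * mult):
                drop_year = t
                break
        last_visit = params.n_years if math.isnan(drop_year) else int(drop_year) - 1

        for t in range(0, last_visit + 1):
            stage = path[t]
            band = STAGE_TO_BAND.get(stage)  # None for stages <= 2B
            on_med = (not math.isnan(med_start)) and med_start <= t
            row = {
                "participant_id": pid,
                "cohort": "PD" if stage_rank(baseline) >= 4 else "Prodromal",
                "visit_year": float(t),
                "s_status": "positive",
                "d_status": "positive" if stage in D_POSITIVE_STAGES else "negative",
                "genetic_class": genetic,
                "on_medication": bool(on_med),
                "med_start_year": med_start,
            }
            anchored: set[str] = set()
            if band is not None:
                anchored = {d for d in track_labels
                            if (d == primary or secondary[d])
                            and _reachable_band(config.domains[d], band)}
                if not anchored:
                    # primary track cannot anchor this stage (e.g. other-nonmotor
                    # at stage 3): fall back to motor so the latent stage is real
                    anchored = {"motor"}
            for j, dom in enumerate(track_labels):
                dom_band = band if dom in anchored else "none"
                score = float(_draw_band_score(config.domains[dom], dom_band,
                                               u_scores[t, j], u_noise[t, j],
                                               params.score_noise))
                if on_med:
                    score -= params.med_effect.get(dom, 0.0)
                row[config.domains[dom].score_field] = float(max(0.0, score))
                sign = dom_band != "none" or (
                    stage in ("2A", "2B") and (dom == "other_nonmotor"
                                               if stage == "2A" else dom == "motor"))
                row[config.domains[dom].sign_field] = 1.0 if sign else 0.0
            hy = _HY_BASE[stage] + (1 if stage in ("2B", "3", "4") and u_hy[t] < 0.3 else 0)
            row["hy_stage"] = float(hy)
            visit_rows.append(row)

        for t in range(0, params.n_years + 1):
            path_rows.append({"participant_id": pid, "visit_year": float(t),
                              "latent_stage": path[t]})
        part_rows.append({
            "participant_id": pid, "baseline_stage": baseline,
            "primary_track": primary, "med_start_year": med_start,
            "dropout_year": drop_year,
        })

    visits = pd.DataFrame(visit_rows)
    truth = GroundTruth(stage_path=pd.DataFrame(path_rows),
                        participants=pd.DataFrame(part_rows))
    if params.missing_field_prob > 0:
        visits, _ = inject_missingness(visits, params.missing_field_prob,
                                       seed=params.seed + 1, config=config)
    return visits, truth


def inject_missingness(cohort: pd.DataFrame, missing_field_prob: float,
                       seed: int, config: AnchorConfig | None = None
                       ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Blank stageable fields at follow-up visits, independently per field.

    Baseline visits are never blanked (the baseline stage must remain
    determinable).  Returns the blanked cohort and a log with one row per
    blanked ``(participant_id, visit_year, field)``; the blank cell itself
    (NaN) is the missingness marker consumed by carry-forward.
    """
    if not 0.0 <= missing_field_prob < 1.0:
        raise ConfigurationError("missing_field_prob must be in [0, 1)")
    config = config or default_anchor_config()
    fields = [*config.score_fields, *config.sign_fields, "d_status", "hy_stage"]
    fields = [f for f in fields if f in cohort.columns]
    df = cohort.copy()
    if missing_field_prob == 0.0:
        return df, pd.DataFrame(columns=["participant_id", "visit_year", "field"])

    rng = np.random.default_rng(seed)
    eligible = (df["visit_year"] > 0).to_numpy()
    log_rows = []
    for f in fields:
        blank = eligible & (rng.uniform(size=len(df)) < missing_field_prob)
        for idx in np.flatnonzero(blank):
            log_rows.append({"participant_id": df["participant_id"].iat[idx],
                             "visit_year": df["visit_year"].iat[idx], "field": f})
        df.loc[blank, f] = np.nan
    return df, pd.DataFrame(log_rows, columns=["participant_id", "visit_year", "field"])
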