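"""Rule-based NSD-ISS stage assignment for visit-level data.

A visit is staged from three ingredients:

* biomarker state — S (CSF alpha-synuclein seed amplification, positive /
  negative) and D (dopaminergic deficit on DAT imaging, read as binary),
  plus the genetic variant class;
* subtle clinical signs per domain (booleans);
* functional severity bands per domain, derived from scores through an
  :class:`~nsdiss.anchors.AnchorConfig`.

Staging applies only to S+ individuals: NSD is biologically defined by the
alpha-synuclein biomarker, so an S− or S-missing visit is not "stage
something", it is outside the framework (``UnstageableError``).

The rules, in order:

1. fully penetrant SNCA variant, no signs, no dopaminergic deficit → stage 0;
2. no signs, no impairment: D− → 1A, D+ → 1B;
3. signs present, no impairment: D− → 2A, D+ → 2B;
4. any functional band above none requires D+; the stage is 3/4/5/6 for a
   maximal band of slight/mild/moderate/severe, and the contributing tracks
   are the domains whose band equals that maximum.

Functional impairment with D− is not a defined NSD-ISS state; such visits
are assigned stage 2A and flagged (``impairment_without_dopaminergic_deficit``)
so that messy real data pass through audibly rather than crashing.

Missing stage-determining fields at a follow-up visit are filled by
carrying forward the nearest earlier observed value (:func:`carry_forward`),
mirroring annual-visit practice; every filled field is recorded so the
imputation can be audited or disabled.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .anchors import AnchorConfig
from .stages import BAND_TO_STAGE, DOMAINS, band_rank, stage_rank

#: non-anchor fields that are also carried forward across missing visits
EXTRA_CARRY_FIELDS = ("hy_stage",)


class UnstageableError(ValueError):
    """A visit cannot be staged (S−/S missing, D missing, or missing fields)."""

    def __init__(self, reason: str, missing_fields: list[str] | None = None):
        self.reason = reason
        self.missing_fields = list(missing_fields or [])
        msg = reason if not self.missing_fields else f"{reason}: {self.missing_fields}"
        super().__init__(msg)


@dataclass(frozen=True)
class BiomarkerState:
    s_status: str | None  # "positive" / "negative" / None
    d_status: str | None
    genetic_class: str = "none"  # none / snca_fully_penetrant / other_variant


@dataclass(frozen=True)
class DomainStatus:
    domain: str
    signs_present: bool
    severity_band: str = "none"

    def __post_init__(self) -> None:
        if band_rank(self.severity_band) > 0 and not self.signs_present:
            raise ValueError(f"{self.domain}: severity above none implies signs present")


@dataclass(frozen=True)
class StageAssignment:
    stage: str
    tracks: frozenset[str] = frozenset()
    carried_fields: tuple[str, ...] = ()
    warnings: tuple[str, ...] = ()

    @property
    def rank(self) -> int:
        return stage_rank(self.stage)


def _missing(value) -> bool:
    return value is None or (isinstance(value, float) and np.isnan(value)) or value is pd.NA


def evaluate_domains(visit, config: AnchorConfig) -> dict[str, DomainStatus]:
    """Derive one :class:`DomainStatus` per functional domain from a visit.

    ``visit`` is any mapping (a dict or a DataFrame row) exposing the score
    and sign fields named by the config.  The severity band is the highest
    band whose threshold the score meets.  A missing sign flag is tolerated
    when the band already implies signs; any other missing input raises
    :class:`UnstageableError` listing every missing field at once.
    """
    missing: list[str] = []
    out: dict[str, DomainStatus] = {}
    for name in DOMAINS:
        dom = config.domains[name]
        score = visit.get(dom.score_field) if hasattr(visit, "get") else visit[dom.score_field]
        sign = visit.get(dom.sign_field) if hasattr(visit, "get") else visit[dom.sign_field]
        if _missing(score):
            missing.append(dom.score_field)
            continue
        band = dom.band_for_score(float(score))
        if band == "none" and _missing(sign):
            missing.append(dom.sign_field)
            continue
        signs = bool(sign) if not _missing(sign) else False
        out[name] = DomainStatus(name, signs_present=signs or band != "none",
                                 severity_band=band)
    if missing:
        raise UnstageableError("missing_fields", missing)
    return out


def assign_stage(bio: BiomarkerState,
                 domains: dict[str, DomainStatus],
                 config: AnchorConfig | None = None) -> StageAssignment:
    """Apply the NSD-ISS rulebook to one visit's biomarker and domain states.

    The anchor config has already been consumed while building the
    ``DomainStatus`` values; it is accepted here only so callers can thread
    a single rulebook through the whole engine.
    """
    if bio.s_status != "positive":
        reason = "s_negative" if bio.s_status == "negative" else "s_missing"
        raise UnstageableError(reason)
    if _missing(bio.d_status) or bio.d_status not in ("positive", "negative"):
        raise UnstageableError("d_missing")
    d_pos = bio.d_status == "positive"

    statuses = [domains[name] for name in DOMAINS]
    max_band = max((s.severity_band for s in statuses), key=band_rank)
    any_signs = any(s.signs_present for s in statuses)

    if (bio.genetic_class == "snca_fully_penetrant" and not any_signs
            and not d_pos and max_band == "none"):
        return StageAssignment("0")
    if max_band == "none":
        if not any_signs:
            return StageAssignment("1B" if d_pos else "1A")
        return StageAssignment("2B" if d_pos else "2A")
    if not d_pos:
        # impairment without dopaminergic deficit: undefined state, park at
        # 2A (grouped "2A or lower" downstream) and flag for audit
        return StageAssignment("2A", warnings=("impairment_without_dopaminergic_deficit",))
    tracks = frozenset(s.domain for s in statuses if s.severity_band == max_band)
    return StageAssignment(BAND_TO_STAGE[max_band], tracks=tracks)


def stage_visit(visit, config: AnchorConfig) -> StageAssignment:
    """Stage a single visit mapping; convenience wrapper."""
    bio = BiomarkerState(
        s_status=None if _missing(visit.get("s_status")) else visit.get("s_status"),
        d_status=None if _missing(visit.get("d_status")) else visit.get("d_status"),
        genetic_class=(visit.get("genetic_class") if not _missing(visit.get("genetic_class"))
                       else "none"),
    )
    return assign_stage(bio, evaluate_domains(visit, config), config)


# ---------------------------------------------------------------------------
# carry-forward over a participant's visit sequence


def carry_forward(visits: pd.DataFrame, config: AnchorConfig,
                  extra_fields: tuple[str, ...] = EXTRA_CARRY_FIELDS) -> pd.DataFrame:
    """Fill missing stage-determining fields from the nearest earlier visit.

    Operates on the whole visit table (one or many participants).  Within
    each participant, visits are processed in time order and every missing
    field named by the config (plus ``extra_fields`` where present) is
    filled from the most recent visit at which it was observed.  Filled
    fields are recorded per row in a new ``carried_fields`` column (a
    ``|``-joined string, empty when nothing was carried).  Fields with no
    earlier observation stay missing, so a never-observed field still renders
    the visit unstageable — carry-forward never fabricates data.

    Idempotent: a second application is a no-op.
    """
    if len(visits) == 0:
        raise ValueError("empty visit sequence")
    fields = [f for f in (*config.required_fields, *extra_fields) if f in visits.columns]
    df = visits.sort_values(["participant_id", "visit_year"], kind="stable").copy()
    was_na = df[fields].isna()
    df[fields] = df.groupby("participant_id", sort=False)[fields].ffill()
    carried = was_na & df[fields].notna()
    df["carried_fields"] = [
        "|".join(np.array(fields)[row]) for row in carried.to_numpy()
    ]
    return df


def stage_cohort(visits: pd.DataFrame, config: AnchorConfig | None = None,
                 carry: bool = True) -> pd.DataFrame:
    """Stage every visit in a cohort table.

    Returns a copy of the (optionally carry-forward-completed) table with
    columns ``stage`` (label or NA), ``stage_rank`` (float, NaN when
    unstageable), ``tracks`` (``|``-joined domains), ``carried_fields``,
    ``warnings`` and ``unstageable_reason``.
    """
    if config is None:
        from .anchors import default_anchor_config
        config = default_anchor_config()
    df = carry_forward(visits, config) if carry else visits.sort_values(
        ["participant_id", "visit_year"], kind="stable").copy()
    if "carried_fields" not in df.columns:
        df["carried_fields"] = ""

    stages, ranks, tracks, warns, reasons = [], [], [], [], []
    for row in df.to_dict("records"):
        try:
            asg = stage_visit(row, config)
            stages.append(asg.stage)
            ranks.append(float(asg.rank))
            tracks.append("|".join(sorted(asg.tracks)))
            warns.append("|".join(asg.warnings))
            reasons.append("")
        except UnstageableError as exc:
            stages.append(pd.NA)
            ranks.append(np.nan)
            tracks.append("")
            warns.append("")
            reasons.append(exc.reason)
    df["stage"] = stages
    df["stage_rank"] = ranks
    df["tracks"] = tracks
    df["warnings"] = warns
    df["unstageable_reason"] = reasons
    return df
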