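"""Staging engine: domain evaluation, rule application, carry-forward."""


import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from nsdiss import (
    BiomarkerState,
    DomainStatus,
    UnstageableError,
    assign_stage,
    band_rank,
    carry_forward,
    evaluate_domains,
    stage_cohort,
    stage_rank,
)
from nsdiss.stages import DOMAINS, SEVERITY_BANDS, STAGES

from conftest import make_visit, visits_frame


# ---------------------------------------------------------------------------
# stage order


def test_stage_rank_total_order():
    ranks = [stage_rank(s) for s in STAGES]
    assert ranks == list(range(9))
    assert stage_rank("2B") == 4
    assert stage_rank("6") == 8
    assert stage_rank("3") - stage_rank("2B") == 1
    with pytest.raises(ValueError):
        stage_rank("7")


# ---------------------------------------------------------------------------
# domain evaluation


def test_all_zero_scores_give_no_signs_no_band(config):
    statuses = evaluate_domains(make_visit(), config)
    assert all(not s.signs_present and s.severity_band == "none"
               for s in statuses.values())


@pytest.mark.parametrize("domain", DOMAINS)
def test_band_boundaries_belong_to_upper_band(config, domain):
    """Scores around each threshold land per the half-open [lo, hi) rule,
    checked against an interval-walk oracle over the threshold grid."""
    anchors = config.domains[domain]
    thresholds = [(band, anchors.bands[band]) for band in SEVERITY_BANDS[1:]
                  if anchors.bands.get(band) is not None]

    def oracle(score):  # highest threshold <= score
        best = "none"
        for band, lo in thresholds:
            if score >= lo:
                best = band
        return best

    probe = sorted({v + d for _, v in thresholds for d in (-1, -0.5, 0, 0.5, 1)}
                   | {0, 1e6})
    for score in probe:
        if score < 0:
            continue
        assert anchors.band_for_score(score) == oracle(score), score


def test_single_domain_above_none(config):
    visit = make_visit(cognitive=12.0, cognitive_signs=1.0)  # moderate
    statuses = evaluate_domains(visit, config)
    above = [d for d, s in statuses.items() if s.severity_band != "none"]
    assert above == ["cognitive"]
    assert statuses["cognitive"].severity_band == "moderate"


def test_missing_fields_listed_at_once(config):
    visit = make_visit()
    visit["motor_score"] = np.nan
    visit["cognitive_score"] = np.nan
    with pytest.raises(UnstageableError) as err:
        evaluate_domains(visit, config)
    assert set(err.value.missing_fields) == {"motor_score", "cognitive_score"}


def test_domain_status_requires_signs_with_band():
    with pytest.raises(ValueError):
        DomainStatus("motor", signs_present=False, severity_band="slight")


# ---------------------------------------------------------------------------
# stage assignment


def _domains(cog="none", mot="none", non="none", signs=False):
    return {
        "cognitive": DomainStatus("cognitive", signs or cog != "none", cog),
        "motor": DomainStatus("motor", signs or mot != "none", mot),
        "other_nonmotor": DomainStatus("other_nonmotor", signs or non != "none", non),
    }


def test_asymptomatic_with_dat_deficit_is_1b(config):
    asg = assign_stage(BiomarkerState("positive", "positive"), _domains(), config)
    assert asg.stage == "1B" and asg.tracks == frozenset()


def test_slight_motor_impairment_is_stage3_motor_track(config):
    asg = assign_stage(BiomarkerState("positive", "positive"),
                       _domains(mot="slight"), config)
    assert asg.stage == "3" and asg.tracks == frozenset({"motor"})


def test_s_negative_is_not_stageable(config):
    with pytest.raises(UnstageableError):
        assign_stage(BiomarkerState("negative", "positive"), _domains(), config)
    with pytest.raises(UnstageableError):
        assign_stage(BiomarkerState(None, "positive"), _domains(), config)


def test_d_missing_is_not_stageable(config):
    with pytest.raises(UnstageableError):
        assign_stage(BiomarkerState("positive", None), _domains(), config)


def test_max_band_sets_stage_and_ties_share_tracks(config):
    asg = assign_stage(BiomarkerState("positive", "positive"),
                       _domains(cog="mild", mot="mild", non="slight"), config)
    assert asg.stage == "4"
    assert asg.tracks == frozenset({"cognitive", "motor"})


def test_snca_carrier_asymptomatic_is_stage0_else_general_rules(config):
    bio = BiomarkerState("positive", "negative", "snca_fully_penetrant")
    assert assign_stage(bio, _domains(), config).stage == "0"
    # with signs the carrier is staged by the general rules
    assert assign_stage(bio, _domains(signs=True), config).stage == "2A"
    bio_d = BiomarkerState("positive", "positive", "snca_fully_penetrant")
    assert assign_stage(bio_d, _domains(), config).stage == "1B"


def test_impairment_without_dat_flags_and_parks_at_2a(config):
    asg = assign_stage(BiomarkerState("positive", "negative"),
                       _domains(mot="mild"), config)
    assert asg.stage == "2A"
    assert "impairment_without_dopaminergic_deficit" in asg.warnings


@given(
    bands=st.tuples(*[st.sampled_from(SEVERITY_BANDS)] * 3),
    bump=st.integers(0, 2),
    d_pos=st.booleans(),
    signs=st.booleans(),
)
@settings(max_examples=300, derandomize=True, deadline=None)
def test_raising_a_band_never_lowers_stage(config, bands, bump, d_pos, signs):
    """Monotonicity: increasing any one domain's severity band cannot
    decrease the assigned stage rank."""
    bio = BiomarkerState("positive", "positive" if d_pos else "negative")
    lo = assign_stage(bio, _domains(*bands, signs=signs), config)
    raised = list(bands)
    idx = bump % 3
    raised[idx] = SEVERITY_BANDS[min(band_rank(raised[idx]) + 1, 4)]
    hi = assign_stage(bio, _domains(*raised, signs=signs), config)
    assert stage_rank(hi.stage) >= stage_rank(lo.stage)


@given(bands=st.tuples(*[st.sampled_from(SEVERITY_BANDS)] * 3),
       d_pos=st.booleans(), signs=st.booleans())
@settings(max_examples=300, derandomize=True, deadline=None)
def test_track_soundness(config, bands, d_pos, signs):
    """Every reported track has the stage-defining band; stages <= 2B have
    no tracks."""
    bio = BiomarkerState("positive", "positive" if d_pos else "negative")
    domains = _domains(*bands, signs=signs)
    asg = assign_stage(bio, domains, config)
    if stage_rank(asg.stage) <= stage_rank("2B"):
        assert asg.tracks == frozenset()
    else:
        max_band = max(bands, key=band_rank)
        assert asg.tracks == frozenset(
            d for d, b in zip(DOMAINS, bands) if b == max_band)
        assert asg.tracks


# ---------------------------------------------------------------------------
# carry-forward


def test_complete_data_carries_nothing(config):
    df = visits_frame([make_visit(year=y) for y in (0, 1, 2)])
    out = carry_forward(df, config)
    assert (out["carried_fields"] == "").all()


def test_gap_filled_from_nearest_earlier_visit_and_flagged(config):
    rows = [make_visit(year=y, motor=5.0, motor_signs=1.0) for y in (0, 1, 2)]
    rows[1]["motor_score"] = np.nan
    rows[2]["motor_score"] = np.nan
    out = carry_forward(visits_frame(rows), config).sort_values("visit_year")
    assert out["motor_score"].tolist() == [5.0, 5.0, 5.0]
    assert out["carried_fields"].tolist() == ["", "motor_score", "motor_score"]


def test_never_observed_field_stays_missing(config):
    rows = [make_visit(year=y) for y in (0, 1)]
    for r in rows:
        r["motor_score"] = np.nan
    staged = stage_cohort(visits_frame(rows), config)
    assert staged["stage"].isna().all()
    assert (staged["unstageable_reason"] == "missing_fields").all()


def test_carry_forward_is_idempotent(config, default_cohort):
    visits, _ = default_cohort
    once = carry_forward(visits, config)
    twice = carry_forward(once.drop(columns="carried_fields"), config)
    pd.testing.assert_frame_equal(
        once.drop(columns="carried_fields").reset_index(drop=True),
        twice.drop(columns="carried_fields").reset_index(drop=True))
    assert (twice["carried_fields"] == "").all()


def test_carry_forward_rejects_empty(config):
    with pytest.raises(ValueError):
        carry_forward(pd.DataFrame(columns=["participant_id", "visit_year"]), config)
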