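"""Longitudinal outputs: exclusions, tabulation, flows, first increase."""

import numpy as np
import pandas as pd
import pytest

from nsdiss import (
    Trajectory,
    apply_longitudinal_exclusions,
    detect_first_stage_increase,
    sankey_export,
    stage_cohort,
    tabulate_hy_by_year,
    tabulate_stage_by_year,
    transition_flows,
)

from conftest import make_visit, visits_frame


def traj(stages, times=None, **kw):
    times = times if times is not None else tuple(float(t) for t in range(len(stages)))
    return Trajectory("P", tuple(times), tuple(stages), **kw)


# ---------------------------------------------------------------------------
# first stage increase


def test_first_increase_at_first_rank_exceeding_baseline():
    inc = detect_first_stage_increase(traj(["2B", "2B", "3", "4"]))
    assert (inc.time_years, inc.from_stage, inc.to_stage) == (2.0, "2B", "3")


def test_reversion_then_return_to_baseline_is_not_an_increase():
    assert detect_first_stage_increase(traj(["3", "2B", "3", "3"])) is None
    inc = detect_first_stage_increase(traj(["3", "2B", "3", "4"]))
    assert (inc.time_years, inc.to_stage) == (3.0, "4")


def test_stage_skip_recorded_as_is():
    inc = detect_first_stage_increase(traj(["2B", "4"]))
    assert inc.to_stage == "4" and inc.time_years == 1.0


def test_trajectory_rejects_nonincreasing_times():
    with pytest.raises(ValueError):
        Trajectory("P", (0.0, 1.0, 1.0), ("3", "3", "3"))
    with pytest.raises(ValueError):
        Trajectory("P", (), ())


# ---------------------------------------------------------------------------
# exclusions


def _cohort_rows():
    rows = []
    # retained: baseline 2B, 5 annual visits
    for y in range(6):
        rows.append(make_visit("KEEP", y, motor_signs=1.0))
    # baseline only
    rows.append(make_visit("NOFU", 0, motor_signs=1.0))
    # baseline stage 1A (S+, D-, asymptomatic)
    for y in range(3):
        rows.append(make_visit("LOW", y, d="negative"))
    # baseline 2A without any follow-up DAT assessment
    for y in range(3):
        r = make_visit("NODAT", y, d="negative", nonmotor_signs=1.0)
        if y > 0:
            r["d_status"] = np.nan
        rows.append(r)
    # S-negative participant
    for y in range(2):
        rows.append(make_visit("SNEG", y, s="negative"))
    return rows


def test_exclusion_rules_and_reason_codes(config):
    staged = stage_cohort(visits_frame(_cohort_rows()), config)
    analysis, log = apply_longitudinal_exclusions(staged)
    assert set(analysis["participant_id"]) == {"KEEP"}
    reasons = dict(zip(log["participant_id"], log["reason"]))
    assert reasons == {"NOFU": "no_follow_up", "LOW": "baseline_stage_below_2A",
                       "NODAT": "stage_2A_no_followup_dat", "SNEG": "not_nsd"}


def test_every_participant_in_analysis_set_or_log(default_staged):
    analysis, log = apply_longitudinal_exclusions(default_staged)
    pids = set(default_staged["participant_id"])
    assert set(analysis["participant_id"]) | set(log["participant_id"]) == pids
    assert not (set(analysis["participant_id"]) & set(log["participant_id"]))


# ---------------------------------------------------------------------------
# tabulation


def _static_cohort(config, n_years=5):
    rows = []
    for pid, stage_kw in (("A", dict(motor_signs=1.0)),            # 2B
                          ("B", dict(motor=5.0, motor_signs=1.0)),  # 3
                          ("C", dict(motor=15.0, motor_signs=1.0))):  # 4
        for y in range(n_years + 1):
            rows.append(make_visit(pid, y, **stage_kw))
    return stage_cohort(visits_frame(rows), config)


def test_static_cohort_tabulates_identically_every_year(config):
    table = tabulate_stage_by_year(_static_cohort(config), "observed")
    for y in range(1, 6):
        assert (table[y] == table[0]).all()
    assert table.loc["2B", 0] == 1 and table.loc["3", 0] == 1 and table.loc["4", 0] == 1


def test_locf_fills_interim_gap_with_last_stage(config):
    rows = [make_visit("P", y, motor=5.0, motor_signs=1.0) for y in (0, 1, 2, 4, 5)]
    staged = stage_cohort(visits_frame(rows), config)
    table = tabulate_stage_by_year(staged, "locf_completers")
    assert table.loc["3", 3] == 1  # missing year 3 carried as stage 3


def test_locf_restricted_to_year5_completers(config):
    rows = [make_visit("DONE", y, motor_signs=1.0) for y in range(6)]
    rows += [make_visit("DROP", y, motor_signs=1.0) for y in range(3)]
    staged = stage_cohort(visits_frame(rows), config)
    locf = tabulate_stage_by_year(staged, "locf_completers")
    assert locf.sum(axis=0).tolist() == [1] * 6
    observed = tabulate_stage_by_year(staged, "observed")
    assert observed.sum(axis=0).tolist() == [2, 2, 2, 1, 1, 1]


def test_modes_agree_on_complete_data(config):
    staged = _static_cohort(config)
    obs = tabulate_stage_by_year(staged, "observed")
    locf = tabulate_stage_by_year(staged, "locf_completers")
    pd.testing.assert_frame_equal(obs, locf)


def test_unknown_mode_rejected(config):
    with pytest.raises(ValueError):
        tabulate_stage_by_year(_static_cohort(config), "median")


def test_locf_never_invents_a_stage_label(default_staged):
    wide_obs = (default_staged[default_staged["stage"].notna()]
                .pivot(index="participant_id", columns="visit_year", values="stage"))
    locf = tabulate_stage_by_year(default_staged, "locf_completers")
    for stage in locf.index[locf.sum(axis=1) > 0]:
        assert (wide_obs == stage).any().any()


def test_hy_tabulation_same_contract(config):
    staged = _static_cohort(config)
    table = tabulate_hy_by_year(staged, "observed")
    assert table.sum(axis=0).tolist() == [3] * 6
    assert (table.loc[0.0] == 3).all()  # all constructed visits have HY 0


# ---------------------------------------------------------------------------
# transition flows


def test_static_flows_all_on_diagonal(config):
    flows = transition_flows(_static_cohort(config))
    assert (flows["stage_from"] == flows["stage_to"]).all()
    conservation = flows.groupby("year_from")["n"].sum()
    assert (conservation == 3).all()


def test_single_transition_appears_once_off_diagonal(config):
    rows = []
    for y in range(6):
        motor = 5.0 if y >= 2 else 0.0  # 2B -> 3 at year 2
        rows.append(make_visit("P", y, motor=motor, motor_signs=1.0))
    flows = transition_flows(stage_cohort(visits_frame(rows), config))
    off = flows[flows["stage_from"] != flows["stage_to"]]
    assert len(off) == 1
    assert off.iloc[0][["year_from", "stage_from", "stage_to", "n"]].tolist() == \
        [1, "2B", "3", 1]


def test_flow_conservation_on_simulated_cohort(default_staged):
    analysis, _ = apply_longitudinal_exclusions(default_staged)
    flows = transition_flows(analysis)
    totals = flows.groupby("year_from")["n"].sum()
    assert totals.nunique() == 1  # same completers count at every step


def test_absent_filter_stage_gives_empty_flows(config):
    flows = transition_flows(_static_cohort(config), baseline_stages=("6",))
    assert len(flows) == 0
    assert sankey_export(flows) == {"nodes": [], "links": []}


def test_sankey_links_match_flow_counts(config):
    flows = transition_flows(_static_cohort(config))
    doc = sankey_export(flows)
    assert sum(l["value"] for l in doc["links"]) == flows["n"].sum()
    ids = {n["id"] for n in doc["nodes"]}
    assert all(l["source"] in ids and l["target"] in ids for l in doc["links"])
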