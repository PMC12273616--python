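import math

import pandas as pd
import pytest

from nsdiss import SimulationParams, default_anchor_config, simulate_cohort, stage_cohort

INF = math.inf

#: sojourn map with no progression anywhere
FROZEN_SOJOURNS = {s: INF for s in ("0", "1A", "1B", "2A", "2B", "3", "4", "5")}

#: medication hazards switched off
NO_MEDS = {s: 0.0 for s in ("0", "1A", "1B", "2A", "2B", "3", "4", "5", "6")}


@pytest.fixture(scope="session")
def config():
    return default_anchor_config()


@pytest.fixture(scope="session")
def default_cohort(config):
    """A mid-sized cohort under the default study conditions."""
    params = SimulationParams(n_participants=300, seed=11)
    visits, truth = simulate_cohort(params, config)
    return visits, truth


@pytest.fixture(scope="session")
def default_staged(default_cohort, config):
    visits, _ = default_cohort
    return stage_cohort(visits, config)


def make_visit(pid="P1", year=0.0, s="positive", d="positive", genetic="none",
               motor=0.0, cognitive=0.0, nonmotor=0.0,
               motor_signs=0.0, cognitive_signs=0.0, nonmotor_signs=0.0,
               hy=0.0, on_med=False, med_start=float("nan")):
    """One canonical visit row as a dict."""
    return {
        "participant_id": pid, "cohort": "PD", "visit_year": float(year),
        "s_status": s, "d_status": d, "genetic_class": genetic,
        "motor_score": motor, "cognitive_score": cognitive,
        "nonmotor_score": nonmotor, "motor_signs": motor_signs,
        "cognitive_signs": cognitive_signs, "nonmotor_signs": nonmotor_signs,
        "hy_stage": hy, "on_medication": on_med, "med_start_year": med_start,
    }


def visits_frame(rows):
    return pd.DataFrame(rows)
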