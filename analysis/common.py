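"""Shared paths and loaders for the numbered analysis scripts."""

from pathlib import Path

import pandas as pd

from nsdiss import default_anchor_config, read_visits, stage_cohort

ROOT = Path(__file__).resolve().parent.parent
SCRATCH = ROOT / "scratch" / "cohort"
RESULTS = ROOT / "results"

#: study conditions of the main synthetic analysis
COHORT_SEED = 20
COHORT_N = 576


def load_cohort():
    visits_path = SCRATCH / "visits.csv"
    if not visits_path.exists():
        raise SystemExit("run analysis/01_simulate_cohort.py first")
    return read_visits(visits_path)


def load_staged():
    config = default_anchor_config()
    return stage_cohort(load_cohort(), config), config


def save(df: pd.DataFrame, name: str, index: bool = True) -> Path:
    RESULTS.mkdir(parents=True, exist_ok=True)
    path = RESULTS / name
    df.to_csv(path, index=index)
    return path
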