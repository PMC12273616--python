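"""Canonical delimited formats, schema validation, and run manifests.

The pipeline's interchange format is a UTF-8 CSV with one row per
participant-visit.  Mandatory columns: ``participant_id``, ``visit_year``
(decimal years from enrollment), ``s_status``, ``d_status``.  Scores,
sign flags, genetic class, Hoehn & Yahr stage and medication state are
carried in the columns named by the active anchor config.  Blank cells are
missing data and are preserved as missing — never zero-filled.

Every pipeline run writes a :class:`RunManifest` (JSON) recording input
hashes, the anchor-config hash, seeds and record counts, so any output
table can be traced to exactly one configuration.
"""

from __future__ import annotations

import hashlib
import json
import warnings
from dataclasses import dataclass, field
from datetime import datetime, timezone
from pathlib import Path

import pandas as pd

MANDATORY_COLUMNS = ("participant_id", "visit_year", "s_status", "d_status")

KNOWN_COLUMNS = (
    *MANDATORY_COLUMNS, "cohort", "genetic_class",
    "cognitive_score", "motor_score", "nonmotor_score",
    "cognitive_signs", "motor_signs", "nonmotor_signs",
    "hy_stage", "on_medication", "med_start_year",
)

_STRING_COLUMNS = ("participant_id", "cohort", "s_status", "d_status", "genetic_class")


class SchemaError(ValueError):
    """The visit table violates the canonical schema."""


def read_visits(path: str | Path) -> pd.DataFrame:
    """Read and validate a visit-level CSV.

    Unknown columns are kept but warned about; missing mandatory columns and
    duplicate ``(participant_id, visit_year)`` keys are hard errors naming
    the offender.  Blank cells stay missing (NaN), never 0.
    """
    df = pd.read_csv(path, dtype={c: "string" for c in _STRING_COLUMNS})
    missing = [c for c in MANDATORY_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"missing mandatory columns: {missing}")
    unknown = [c for c in df.columns if c not in KNOWN_COLUMNS]
    if unknown:
        warnings.warn(f"unknown columns kept as-is: {unknown}", stacklevel=2)
    df["visit_year"] = pd.to_numeric(df["visit_year"], errors="raise")
    for col in _STRING_COLUMNS:
        if col in df.columns:
            df[col] = df[col].astype(object).where(df[col].notna(), None)
    dup = df.duplicated(["participant_id", "visit_year"], keep=False)
    if dup.any():
        keys = df.loc[dup, ["participant_id", "visit_year"]].drop_duplicates()
        raise SchemaError(
            "duplicate participant-visit keys: "
            + ", ".join(f"({r.participant_id}, {r.visit_year})"
                        for r in keys.itertuples()))
    if "on_medication" in df.columns:
        df["on_medication"] = df["on_medication"].astype("boolean").astype(object)
    return df


def write_visits(df: pd.DataFrame, path: str | Path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, index=False)


def file_sha256(path: str | Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()[:16]


@dataclass
class RunManifest:
    """Provenance record tying a run's outputs to its inputs and config."""

    command: str
    config_hash: str
    seed: int | None = None
    inputs: dict[str, str] = field(default_factory=dict)   # path -> hash
    record_counts: dict[str, int] = field(default_factory=dict)
    software_version: str = ""
    timestamp: str = ""

    def __post_init__(self) -> None:
        if not self.software_version:
            from . import __version__
            self.software_version = __version__
        if not self.timestamp:
            self.timestamp = datetime.now(timezone.utc).isoformat(timespec="seconds")

    def add_input(self, path: str | Path) -> None:
        self.inputs[str(path)] = file_sha256(path)

    def to_dict(self) -> dict:
        return {
            "command": self.command,
            "config_hash": self.config_hash,
            "seed": self.seed,
            "inputs": dict(self.inputs),
            "record_counts": dict(self.record_counts),
            "software_version": self.software_version,
            "timestamp": self.timestamp,
        }

    def write(self, path: str | Path) -> None:
        Path(path).parent.mkdir(parents=True, exist_ok=True)
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(self.to_dict(), fh, indent=2, sort_keys=True)
            fh.write("\n")
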