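"""Staging anchors: the configurable rulebook mapping scores to severity bands.

The staging engine itself is threshold-agnostic; everything that decides how
a visit's functional scores translate into severity bands (and hence stages
3-6) lives in an :class:`AnchorConfig`, loaded from a YAML file.  Each
functional domain declares

* ``score_field`` — the visit-table column holding the domain's functional
  score (higher = worse; motor and other-nonmotor from MDS-UPDRS Part I/II
  component sums, cognitive from MoCA/MDS-UPDRS-derived deficit scores),
* ``sign_field`` — a boolean column flagging subtle clinical signs/symptoms
  in the domain (used for the stage-2 "signs without impairment" split),
* ``bands`` — lower thresholds for the slight/mild/moderate/severe bands.

Bands are half-open intervals ``[lo, hi)``: a score exactly at a threshold
belongs to the higher band.  A band whose threshold is ``null`` is
unreachable for that domain; the shipped default leaves the other-nonmotor
"slight" band unreachable, encoding that stage 3 is defined by the cognitive
and motor domains only.

The default configuration bundled with the package
(``data/anchors_synthetic_v1.yaml``) is a synthetic reconstruction for
simulation and testing — substitute the operational anchor thresholds for
use on real cohort data.
"""

from __future__ import annotations

import hashlib
import math
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import yaml

from .stages import DOMAINS, SEVERITY_BANDS, band_rank


class ConfigurationError(ValueError):
    """Raised when an anchor configuration or simulation parameter is invalid."""


@dataclass(frozen=True)
class DomainAnchors:
    """Sign criterion and severity-band thresholds for one functional domain."""

    score_field: str
    sign_field: str
    #: band name -> inclusive lower threshold; None = band unreachable
    bands: dict[str, float | None]

    def band_for_score(self, score: float) -> str:
        """Highest severity band whose threshold the score meets.

        Bands are half-open ``[lo, hi)``; a score on a boundary falls in the
        upper band.  Scores below every reachable threshold map to "none".
        """
        if score is None or (isinstance(score, float) and math.isnan(score)):
            raise ValueError("cannot band a missing score")
        best = "none"
        for band in SEVERITY_BANDS[1:]:
            lo = self.bands.get(band)
            if lo is not None and score >= lo:
                best = band
        return best

    @property
    def min_band(self) -> str | None:
        """Lowest reachable band above none, or None if no band is reachable."""
        for band in SEVERITY_BANDS[1:]:
            if self.bands.get(band) is not None:
                return band
        return None

    def band_width(self, band: str) -> float:
        """Width of a reachable band (distance to the next reachable threshold).

        The top reachable band is unbounded; ``inf`` is returned.
        """
        lo = self.bands.get(band)
        if lo is None:
            raise ValueError(f"band {band!r} is unreachable in this domain")
        for upper in SEVERITY_BANDS[band_rank(band) + 1:]:
            hi = self.bands.get(upper)
            if hi is not None:
                return hi - lo
        return math.inf


@dataclass(frozen=True)
class AnchorConfig:
    """Complete staging rulebook: one :class:`DomainAnchors` per domain."""

    version: str
    domains: dict[str, DomainAnchors] = field(default_factory=dict)

    def __post_init__(self) -> None:
        missing = set(DOMAINS) - set(self.domains)
        if missing:
            raise ConfigurationError(f"anchor config missing domains: {sorted(missing)}")
        for name, dom in self.domains.items():
            unknown = set(dom.bands) - set(SEVERITY_BANDS[1:])
            if unknown:
                raise ConfigurationError(f"{name}: unknown bands {sorted(unknown)}")
            present = [(band, dom.bands[band]) for band in SEVERITY_BANDS[1:]
                       if dom.bands.get(band) is not None]
            if not present:
                raise ConfigurationError(f"{name}: no reachable severity band")
            values = [v for _, v in present]
            if any(nxt <= prev for prev, nxt in zip(values, values[1:])):
                raise ConfigurationError(
                    f"{name}: band thresholds must be strictly increasing, got {values}")
            # only a leading prefix of bands may be unreachable (no holes)
            reachable = [dom.bands.get(band) is not None for band in SEVERITY_BANDS[1:]]
            first = reachable.index(True)
            if not all(reachable[first:]):
                raise ConfigurationError(f"{name}: unreachable band above a reachable one")

    # -- serialization ----------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "version": self.version,
            "domains": {
                name: {
                    "score_field": dom.score_field,
                    "sign_field": dom.sign_field,
                    "bands": {b: dom.bands.get(b) for b in SEVERITY_BANDS[1:]},
                }
                for name, dom in sorted(self.domains.items())
            },
        }

    @classmethod
    def from_dict(cls, raw: dict) -> "AnchorConfig":
        try:
            domains = {
                name: DomainAnchors(
                    score_field=spec["score_field"],
                    sign_field=spec["sign_field"],
                    bands=dict(spec["bands"]),
                )
                for name, spec in raw["domains"].items()
            }
            return cls(version=str(raw["version"]), domains=domains)
        except KeyError as exc:
            raise ConfigurationError(f"anchor config missing key: {exc}") from exc

    @classmethod
    def from_yaml(cls, path: str | Path) -> "AnchorConfig":
        with open(path, encoding="utf-8") as fh:
            return cls.from_dict(yaml.safe_load(fh))

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)

    @property
    def config_hash(self) -> str:
        """SHA-256 of the canonical serialized form; echoed into all outputs."""
        canon = yaml.safe_dump(self.to_dict(), sort_keys=True)
        return hashlib.sha256(canon.encode("utf-8")).hexdigest()[:16]

    @property
    def score_fields(self) -> list[str]:
        return [self.domains[d].score_field for d in DOMAINS]

    @property
    def sign_fields(self) -> list[str]:
        return [self.domains[d].sign_field for d in DOMAINS]

    #: fields a visit must have (after carry-forward) to be stageable
    @property
    def required_fields(self) -> list[str]:
        return ["s_status", "d_status", *self.score_fields, *self.sign_fields]


def default_anchor_config() -> AnchorConfig:
    """The bundled synthetic-reconstruction anchor config."""
    ref = resources.files("nsdiss").joinpath("data/anchors_synthetic_v1.yaml")
    with ref.open("r", encoding="utf-8") as fh:
        return AnchorConfig.from_dict(yaml.safe_load(fh))
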