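"""NSD-ISS stage labels and their total order.

The integrated staging system for neuronal alpha-synuclein disease (NSD)
defines seven stages, with stages 1 and 2 split by dopaminergic status:

    0 < 1A < 1B < 2A < 2B < 3 < 4 < 5 < 6

Stage 0 is reserved for asymptomatic carriers of fully penetrant SNCA
variants; 1A/1B are asymptomatic biomarker stages (without/with dopaminergic
deficit); 2A/2B add subtle clinical signs without functional impairment; and
stages 3-6 are anchored on increasing severity of functional impairment
(slight, mild, moderate, severe) in at least one clinical domain.
"""

from __future__ import annotations

STAGES: tuple[str, ...] = ("0", "1A", "1B", "2A", "2B", "3", "4", "5", "6")

_RANK: dict[str, int] = {s: i for i, s in enumerate(STAGES)}

#: severity bands in increasing order; bands slight..severe anchor stages 3..6
SEVERITY_BANDS: tuple[str, ...] = ("none", "slight", "mild", "moderate", "severe")

_BAND_RANK: dict[str, int] = {b: i for i, b in enumerate(SEVERITY_BANDS)}

#: functional-impairment stage anchored by each band above "none"
BAND_TO_STAGE: dict[str, str] = {"slight": "3", "mild": "4", "moderate": "5", "severe": "6"}

STAGE_TO_BAND: dict[str, str] = {v: k for k, v in BAND_TO_STAGE.items()}

#: the three NSD-ISS functional domains ("tracks")
DOMAINS: tuple[str, ...] = ("cognitive", "motor", "other_nonmotor")


def stage_rank(stage: str) -> int:
    """Integer ordinal of a stage label: 0,1A,1B,2A,2B,3,4,5,6 -> 0..8.

    The total order backs every notion of "stage increase" and "reversion"
    used downstream.

    Raises
    ------
    ValueError
        If ``stage`` is not one of the nine NSD-ISS labels.
    """
    try:
        return _RANK[str(stage)]
    except KeyError:
        raise ValueError(f"unknown NSD-ISS stage label: {stage!r}") from None


def band_rank(band: str) -> int:
    """Ordinal of a severity band: none,slight,mild,moderate,severe -> 0..4."""
    try:
        return _BAND_RANK[band]
    except KeyError:
        raise ValueError(f"unknown severity band: {band!r}") from None
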