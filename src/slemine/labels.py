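"""Shared label enumerations for classes and determinations."""

from __future__ import annotations

import enum


class SleClass(str, enum.Enum):
    """Tripartite classification outcome."""

    SLE_NEG = "SLE_neg"
    UCTD = "UCTD"
    SLE_POS = "SLE_pos"


class Group(str, enum.Enum):
    """Record-window position relative to clinical SLE classification:
    histories ending at classification (pre_SC) vs beginning after a
    prior classification (post_SC)."""

    PRE_SC = "pre_SC"
    POST_SC = "post_SC"


class Determination(str, enum.Enum):
    """Extraction/consensus outcome for one criterion."""

    POSITIVE = "positive"
    NEGATIVE = "negative"
    NOT_REPORTED = "not_reported"


class ClinDet(str, enum.Enum):
    """Clinical (ground-truth) determination for one criterion;
    ``unspecified`` marks criteria never clinically adjudicated."""

    POS = "pos"
    NEG = "neg"
    UNSPECIFIED = "unspecified"
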