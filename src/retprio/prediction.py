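"""In-silico deleteriousness consensus across four prediction tools.

Each variant carries one slot per tool — PROVEAN, SIFT, PolyPhen-2 and
MutationTaster — holding either a numeric score or a categorical label as
emitted by the annotation pipeline.  Slots resolve deterministically to
damaging / tolerated / unknown given configured per-tool thresholds, and a
variant is retained when at least three of the four tools call it damaging.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from typing import Optional, Union

TOOLS = ("provean", "sift", "polyphen2", "mutationtaster")

ToolValue = Union[float, str, None]


class Call(enum.Enum):
    DAMAGING = "damaging"
    TOLERATED = "tolerated"
    UNKNOWN = "unknown"


class ConfigError(ValueError):
    pass


@dataclass
class PredictionThresholds:
    """Per-tool cutoffs, following each tool's published convention.

    provean: damaging when score <= provean_max (default -2.5).
    sift: damaging when score <= sift_max (default 0.05).
    polyphen2: damaging when score >= polyphen2_min (default 0.446,
        the HumVar "possibly damaging" boundary).
    mutationtaster: label-based; labels in ``mutationtaster_damaging``
        are damaging ("disease_causing" and its automatic variant, plus the
        single-letter codes A/D the tool also emits).
    """

    provean_max: float = -2.5
    sift_max: float = 0.05
    polyphen2_min: float = 0.446
    mutationtaster_damaging: frozenset[str] = frozenset(
        {"disease_causing", "disease_causing_automatic", "A", "D"}
    )
    mutationtaster_tolerated: frozenset[str] = frozenset(
        {"polymorphism", "polymorphism_automatic", "N", "P"}
    )


# label tables for tools whose annotations sometimes arrive categorical
_SIFT_LABELS = {"deleterious": Call.DAMAGING, "damaging": Call.DAMAGING,
                "tolerated": Call.TOLERATED}
_POLYPHEN_LABELS = {
    "probably_damaging": Call.DAMAGING,
    "possibly_damaging": Call.DAMAGING,
    "benign": Call.TOLERATED,
}
_PROVEAN_LABELS = {"deleterious": Call.DAMAGING, "damaging": Call.DAMAGING,
                   "neutral": Call.TOLERATED}


def _try_float(value: ToolValue) -> Optional[float]:
    if isinstance(value, (int, float)):
        return float(value)
    try:
        return float(str(value))
    except (TypeError, ValueError):
        return None


def resolve_call(
    tool: str, value: ToolValue, thresholds: Optional[PredictionThresholds] = None
) -> Call:
    """Resolve one tool's raw score-or-label to damaging/tolerated/unknown.

    Numeric values are compared against the tool's configured cutoff with
    the tool's direction; string values go through a label table.  An
    absent or unrecognized value resolves to unknown.
    """
    if tool not in TOOLS:
        raise ConfigError(f"unknown prediction tool {tool!r}; expected one of {TOOLS}")
    th = thresholds or PredictionThresholds()
    if value is None or (isinstance(value, str) and not value.strip()):
        return Call.UNKNOWN

    score = _try_float(value)
    if tool == "provean":
        if score is not None:
            return Call.DAMAGING if score <= th.provean_max else Call.TOLERATED
        return _PROVEAN_LABELS.get(str(value).strip().lower(), Call.UNKNOWN)
    if tool == "sift":
        if score is not None:
            return Call.DAMAGING if score <= th.sift_max else Call.TOLERATED
        return _SIFT_LABELS.get(str(value).strip().lower(), Call.UNKNOWN)
    if tool == "polyphen2":
        if score is not None:
            return Call.DAMAGING if score >= th.polyphen2_min else Call.TOLERATED
        return _POLYPHEN_LABELS.get(str(value).strip().lower(), Call.UNKNOWN)
    # mutationtaster: label-only tool
    label = str(value).strip()
    if label in th.mutationtaster_damaging or label.lower() in th.mutationtaster_damaging:
        return Call.DAMAGING
    if label in th.mutationtaster_tolerated or label.lower() in th.mutationtaster_tolerated:
        return Call.TOLERATED
    return Call.UNKNOWN


@dataclass
class PredictionSet:
    """Raw score-or-label per tool, resolvable to calls."""

    provean: ToolValue = None
    sift: ToolValue = None
    polyphen2: ToolValue = None
    mutationtaster: ToolValue = None

    def resolve(
        self, thresholds: Optional[PredictionThresholds] = None
    ) -> dict[str, Call]:
        return {
            tool: resolve_call(tool, getattr(self, tool), thresholds)
            for tool in TOOLS
        }


def damaging_consensus(
    predictions: PredictionSet,
    thresholds: Optional[PredictionThresholds] = None,
    min_damaging: int = 3,
    strict: bool = False,
) -> bool:
    """True iff at least ``min_damaging`` of the four tools call damaging.

    Unknown counts as not-damaging.  With ``strict=True`` any unresolved
    slot fails the variant outright (all four calls must be resolvable).
    """
    calls = predictions.resolve(thresholds)
    if strict and any(c is Call.UNKNOWN for c in calls.values()):
        return False
    return sum(1 for c in calls.values() if c is Call.DAMAGING) >= min_damaging


def consensus_from_calls(calls: list[Call], min_damaging: int = 3) -> bool:
    """Consensus on already-resolved calls (used by the exhaustive checks)."""
    return sum(1 for c in calls if c is Call.DAMAGING) >= min_damaging
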