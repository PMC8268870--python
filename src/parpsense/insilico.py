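"""Normalization of PROVEAN and DANN evidence into B/D/U calls.

Variant records may carry either a categorical call copied from an
annotation front-end or a raw tool score.  A categorical call always wins;
a raw score is thresholded at the tool's customary operating point; with
neither, the call is Unknown (this is the normal outcome for variants the
tools cannot score, e.g. start-loss or frameshift changes).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

__all__ = [
    "PROVEAN_CUTOFF",
    "DANN_CUTOFF",
    "InsilicoCall",
    "call_provean",
    "call_dann",
]

#: PROVEAN deleterious cutoff (score <= cutoff -> D), the tool's published default.
PROVEAN_CUTOFF = -2.5
#: DANN deleterious cutoff (score >= cutoff -> D), a widely used operating point.
DANN_CUTOFF = 0.96

_VALID = {"B", "D", "U"}


@dataclass
class InsilicoCall:
    tool: str  # "provean" | "dann"
    call: str  # "B" | "D" | "U"
    source: str  # "categorical_input" | "score_threshold" | "unscorable"


def _categorical(tool: str, categorical: Optional[str]) -> Optional[InsilicoCall]:
    if categorical is None:
        return None
    # annotation exports occasionally contain stray symbols (e.g. "N");
    # anything outside the B/D/U vocabulary is treated as Unknown
    call = categorical if categorical in _VALID else "U"
    return InsilicoCall(tool, call, "categorical_input")


def call_provean(
    score: Optional[float] = None,
    categorical: Optional[str] = None,
    cutoff: float = PROVEAN_CUTOFF,
) -> InsilicoCall:
    """Resolve PROVEAN evidence; more negative scores are more damaging."""
    resolved = _categorical("provean", categorical)
    if resolved is not None:
        return resolved
    if score is not None:
        return InsilicoCall("provean", "D" if score <= cutoff else "B", "score_threshold")
    return InsilicoCall("provean", "U", "unscorable")


def call_dann(
    score: Optional[float] = None,
    categorical: Optional[str] = None,
    cutoff: float = DANN_CUTOFF,
) -> InsilicoCall:
    """Resolve DANN evidence; scores live in [0, 1], higher is more damaging."""
    resolved = _categorical("dann", categorical)
    if resolved is not None:
        return resolved
    if score is not None:
        if not 0.0 <= score <= 1.0:
            raise ValueError(f"DANN score must lie in [0, 1], got {score!r}")
        return InsilicoCall("dann", "D" if score >= cutoff else "B", "score_threshold")
    return InsilicoCall("dann", "U", "unscorable")
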