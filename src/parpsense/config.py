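"""Run-wide tunables with their clinical defaults."""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

from .insilico import DANN_CUTOFF, PROVEAN_CUTOFF
from .second_hit import DEFAULT_THRESHOLD

__all__ = ["RunConfig", "DEFAULT_CONFIG"]


@dataclass(frozen=True)
class RunConfig:
    """Parameters of the sensitivity-prediction pipeline.

    second_hit_threshold
        Green/red boundary on the VAF/purity score (default 0.7).
    provean_cutoff / dann_cutoff
        Score operating points used only when no categorical call is given.
    ps_cutoff
        ECOG Performance Status at or above which a VUS patient is called
        Resistant regardless of variant evidence (default 3: PS 3-4
        patients derive no benefit).
    benefit_days
        Progression-free-survival threshold separating clinical benefit
        from non-benefit (default 120 days, strict: benefit means > 120).
    gate_known_pathogenic
        Extend the PS gate to patients routed by a known pathogenic
        variant; off by default (the gate belongs to the VUS algorithm).
    """

    second_hit_threshold: float = DEFAULT_THRESHOLD
    provean_cutoff: float = PROVEAN_CUTOFF
    dann_cutoff: float = DANN_CUTOFF
    ps_cutoff: int = 3
    benefit_days: int = 120
    gate_known_pathogenic: bool = False
    seed: Optional[int] = None

    def __post_init__(self) -> None:
        if self.benefit_days <= 0:
            raise ValueError("benefit_days must be positive")
        if self.second_hit_threshold <= 0:
            raise ValueError("second_hit_threshold must be positive")


DEFAULT_CONFIG = RunConfig()
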