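"""Loss-of-wild-type-allele ("second hit") scoring from VAF and tumor purity.

Homologous-recombination genes are tumor suppressors: both alleles must be
inactivated for repair to fail.  When the wild-type allele is lost in tumor
cells, the variant allele frequency observed by sequencing rises above the
heterozygous expectation of half the tumor cell content.  The score defined
here is

    score = VAF / purity

so that a heterozygous somatic variant with both alleles retained scores
exactly 0.5 regardless of purity, while any loss of the remaining wild-type
copy pushes the score upward (a germline heterozygote with wild-type loss
reaches VAF = 1/(2-p), i.e. score 1/((2-p)*p) > 1 at realistic purities).
Scores at or above the decision threshold (default 0.7) fall in the "green"
zone — putative loss of the wild-type allele, hence potential benefit from
PARP inhibition — and scores below it in the "red" zone.

The formula is a reconstruction: published per-variant scores and the
worked heterozygous example pin down the ratio form and the position of the
green/red boundary, but the original computation was not printed.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np

__all__ = [
    "DEFAULT_THRESHOLD",
    "SecondHitResult",
    "SecondHitTable",
    "expected_het_vaf",
    "second_hit_score",
    "second_hit_call",
    "render_second_hit_table",
]

#: Green/red decision boundary on the VAF/purity scale.  The published
#: per-variant scores leave a gap between 0.66 (largest red) and 0.72
#: (smallest green); 0.7 sits inside it, with ties resolved as green.
DEFAULT_THRESHOLD = 0.7


def _as_fraction(value: float, name: str) -> float:
    # accept pathologist percentages (e.g. 60 for 60%) defensively
    if value > 1.0:
        import warnings

        warnings.warn(f"{name}={value} > 1; interpreting as a percentage", stacklevel=3)
        return value / 100.0
    return value


def expected_het_vaf(purity: float) -> float:
    """Expected VAF of a heterozygous somatic variant with no allele loss.

    With diploid tumor and normal cells, a variant present on one of the
    two alleles of every tumor cell contributes purity/2 of all alleles.

    >>> expected_het_vaf(0.60)
    0.3
    """
    purity = _as_fraction(purity, "purity")
    if not 0.0 < purity <= 1.0:
        raise ValueError(f"purity must lie in (0, 1], got {purity!r}")
    return purity / 2.0


def second_hit_score(vaf: float, purity: float) -> float:
    """Fraction of tumor-cell alleles inferred to carry the variant.

    Returns ``vaf / purity``; 0.5 is the heterozygous-no-loss expectation,
    values near or above ~1 indicate loss of the wild-type allele.
    """
    purity = _as_fraction(purity, "purity")
    if not 0.0 < purity <= 1.0:
        raise ValueError(f"purity must lie in (0, 1], got {purity!r}")
    if not 0.0 <= vaf <= 1.0:
        raise ValueError(f"vaf must lie in [0, 1], got {vaf!r}")
    return vaf / purity


def second_hit_call(
    score: Optional[float], threshold: float = DEFAULT_THRESHOLD
) -> str:
    """Categorical loss-of-wild-type-allele call from a score.

    ``None`` (no VAF or purity available) yields ``"U"``; otherwise scores
    at or above the threshold are ``"D"`` (green zone) and below ``"B"``
    (red zone).
    """
    if threshold <= 0:
        raise ValueError(f"threshold must be positive, got {threshold!r}")
    if score is None:
        return "U"
    if score < 0:
        raise ValueError(f"score must be nonnegative, got {score!r}")
    return "D" if score >= threshold else "B"


@dataclass
class SecondHitResult:
    """A resolved second-hit assessment for one variant."""

    score: Optional[float]
    call: str

    @property
    def zone(self) -> Optional[str]:
        if self.score is None:
            return None
        return "green" if self.call == "D" else "red"


def assess(
    vaf: Optional[float],
    purity: Optional[float],
    precomputed_score: Optional[float] = None,
    precomputed_call: Optional[str] = None,
    threshold: float = DEFAULT_THRESHOLD,
) -> SecondHitResult:
    """Resolve second-hit evidence, preferring raw VAF/purity over
    precomputed values and a precomputed score over a bare call."""
    if vaf is not None and purity is not None:
        score = second_hit_score(vaf, purity)
        return SecondHitResult(score, second_hit_call(score, threshold))
    if precomputed_score is not None:
        return SecondHitResult(precomputed_score, second_hit_call(precomputed_score, threshold))
    if precomputed_call is not None:
        call = precomputed_call if precomputed_call in ("B", "D") else "U"
        return SecondHitResult(None, call)
    return SecondHitResult(None, "U")


@dataclass
class SecondHitTable:
    """Score grid over (purity, VAF) with green/red zone per cell.

    ``scores[i, j]`` is the score at ``purity_grid[i]``, ``vaf_grid[j]``.
    Cells with score > 2 are implausible under any diploid model (the VAF
    exceeds what even homozygous pure-tumor alleles could produce) and are
    flagged in ``implausible``.
    """

    purity_grid: np.ndarray
    vaf_grid: np.ndarray
    scores: np.ndarray
    green: np.ndarray
    implausible: np.ndarray
    threshold: float

    def to_frame(self):
        """Render as a DataFrame (rows = purity, columns = VAF) of
        ``"score|zone"`` strings, the machine-readable decision table."""
        import pandas as pd

        cells = np.empty(self.scores.shape, dtype=object)
        for i in range(self.scores.shape[0]):
            for j in range(self.scores.shape[1]):
                zone = "green" if self.green[i, j] else "red"
                if self.implausible[i, j]:
                    zone += "!"
                cells[i, j] = f"{self.scores[i, j]:.2f}|{zone}"
        return pd.DataFrame(
            cells,
            index=[f"{p:.0%}" for p in self.purity_grid],
            columns=[f"{v:.0%}" for v in self.vaf_grid],
        )


def render_second_hit_table(
    purity_step: float = 5,
    vaf_step: float = 5,
    threshold: float = DEFAULT_THRESHOLD,
) -> SecondHitTable:
    """Build the loss-of-heterozygosity decision grid.

    Steps are in percent and must divide 100.  Purity runs from one step to
    100% (a purity of zero is undefined), VAF from 0 to 100%.
    """
    for name, step in (("purity_step", purity_step), ("vaf_step", vaf_step)):
        if step <= 0:
            raise ValueError(f"{name} must be positive, got {step!r}")
        if 100 % step:
            raise ValueError(f"{name} must divide 100, got {step!r}")
    purity_grid = np.arange(purity_step, 100 + purity_step / 2, purity_step) / 100.0
    vaf_grid = np.arange(0, 100 + vaf_step / 2, vaf_step) / 100.0
    scores = vaf_grid[np.newaxis, :] / purity_grid[:, np.newaxis]
    return SecondHitTable(
        purity_grid=purity_grid,
        vaf_grid=vaf_grid,
        scores=scores,
        green=scores >= threshold,
        implausible=scores > 2.0,
        threshold=threshold,
    )
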