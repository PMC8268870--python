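"""Domain types for PARP-inhibitor sensitivity prediction cohorts.

A cohort is a list of treatment episodes (:class:`PatientCase`), each
carrying the homologous-recombination gene variants observed in the
patient's tumor (:class:`VariantRecord`).  Quantitative evidence (variant
allele frequency, pathologist tumor purity, in-silico scores) and
qualitative evidence (curated variant class, categorical tool calls) live
side by side on the variant record; downstream modules resolve them into
Benign / Deleterious / Unknown calls.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

__all__ = [
    "KNOWN_CLASSES",
    "CANCER_SITES",
    "TREATMENTS",
    "PLATINUM_RESPONSES",
    "CALLS",
    "VariantRecord",
    "PatientCase",
    "Cohort",
    "patient_variant_class",
]

KNOWN_CLASSES = ("benign", "probably_benign", "unknown", "pathogenic")
CANCER_SITES = ("ovary", "breast", "digestive_tract", "endometrium", "skin", "other")
TREATMENTS = ("olaparib", "niraparib", "none")
PLATINUM_RESPONSES = ("CR", "PR", "SD", "PD", "none", "missing")
#: Categorical evidence calls: Benign, Deleterious, Unknown.
CALLS = ("B", "D", "U")


class ValidationError(ValueError):
    """A record violates a domain invariant."""


def _check_fraction(name: str, value: Optional[float], lo_open: bool = False) -> None:
    if value is None:
        return
    if lo_open:
        ok = 0.0 < value <= 1.0
    else:
        ok = 0.0 <= value <= 1.0
    if not ok:
        raise ValidationError(f"{name} must lie in {'(0,1]' if lo_open else '[0,1]'}, got {value!r}")


@dataclass
class VariantRecord:
    """One observed variant with its evidence.

    HGVS strings are carried verbatim and never validated or normalized:
    clinical reports routinely contain idiosyncratic spellings and the
    classification algorithm never parses them.

    Parameters
    ----------
    gene : str
        HGNC gene symbol (e.g. ``"BRCA1"``).
    cdna, protein : str
        HGVS c. / p. descriptions as reported.
    known_class : str
        Curated pathogenicity class: ``benign``, ``probably_benign``,
        ``unknown`` (a VUS) or ``pathogenic``.
    vaf : float, optional
        Variant allele frequency in [0, 1].
    tumor_purity : float, optional
        Pathologist-estimated tumor cell content in (0, 1].
    provean_score : float, optional
        PROVEAN score; more negative means more damaging.
    provean_call, dann_call, second_hit_call : {"B", "D", "U"}, optional
        Categorical calls, when precomputed.
    dann_score : float, optional
        DANN deleteriousness score in [0, 1].
    second_hit_score : float, optional
        Precomputed loss-of-wild-type-allele score (VAF / purity scale).
    """

    gene: str
    cdna: str = ""
    protein: str = ""
    known_class: str = "unknown"
    vaf: Optional[float] = None
    tumor_purity: Optional[float] = None
    provean_score: Optional[float] = None
    provean_call: Optional[str] = None
    dann_score: Optional[float] = None
    dann_call: Optional[str] = None
    second_hit_score: Optional[float] = None
    second_hit_call: Optional[str] = None

    def __post_init__(self) -> None:
        if self.known_class not in KNOWN_CLASSES:
            raise ValidationError(
                f"known_class must be one of {KNOWN_CLASSES}, got {self.known_class!r}"
            )
        _check_fraction("vaf", self.vaf)
        _check_fraction("dann_score", self.dann_score)
        _check_fraction("tumor_purity", self.tumor_purity, lo_open=True)
        if self.second_hit_score is not None and self.second_hit_score < 0:
            raise ValidationError(f"second_hit_score must be nonnegative, got {self.second_hit_score!r}")
        # Call columns normally hold B/D/U, but stray symbols from
        # annotation exports are kept verbatim; resolution treats anything
        # outside the vocabulary as Unknown.
        for name in ("provean_call", "dann_call", "second_hit_call"):
            value = getattr(self, name)
            if value is not None and (not isinstance(value, str) or not value.strip()):
                raise ValidationError(f"{name} must be a non-empty string or None, got {value!r}")

    @property
    def is_vus(self) -> bool:
        return self.known_class == "unknown"


@dataclass
class PatientCase:
    """One treatment episode with its clinical endpoint and variants.

    ``pfs_event`` is True when progression or death was observed and False
    when the progression-free-survival time is right-censored (treatment
    ongoing, or stopped for toxicity rather than progression).
    ``performance_status`` is the ECOG 0-4 scale; it may be missing for
    cases where it was never recorded.
    """

    patient_id: str
    cancer_site: str = "other"
    histology: str = ""
    performance_status: Optional[int] = None
    treatment: str = "none"
    platinum_response: str = "missing"
    pfs_days: int = 1
    pfs_event: bool = True
    variants: list[VariantRecord] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.cancer_site not in CANCER_SITES:
            raise ValidationError(
                f"cancer_site must be one of {CANCER_SITES}, got {self.cancer_site!r}"
            )
        if self.treatment not in TREATMENTS:
            raise ValidationError(f"treatment must be one of {TREATMENTS}, got {self.treatment!r}")
        if self.platinum_response not in PLATINUM_RESPONSES:
            raise ValidationError(
                f"platinum_response must be one of {PLATINUM_RESPONSES}, "
                f"got {self.platinum_response!r}"
            )
        if self.performance_status is not None and not 0 <= self.performance_status <= 4:
            raise ValidationError(
                f"performance_status must be in 0..4, got {self.performance_status!r}"
            )
        if self.pfs_days < 1:
            raise ValidationError(f"pfs_days must be >= 1, got {self.pfs_days!r}")

    @property
    def vus(self) -> list[VariantRecord]:
        """The variants of unknown significance carried by this case."""
        return [v for v in self.variants if v.is_vus]


@dataclass
class Cohort:
    """An ordered collection of patient cases."""

    cases: list[PatientCase] = field(default_factory=list)
    label: str = ""

    def __len__(self) -> int:
        return len(self.cases)

    def __iter__(self):
        return iter(self.cases)

    def subset(self, predicate, label: str = "") -> "Cohort":
        return Cohort([c for c in self.cases if predicate(c)], label or self.label)


_CLASS_PRECEDENCE = {"pathogenic": 2, "unknown": 1, "benign": 0, "probably_benign": 0}


def patient_variant_class(case: PatientCase) -> str:
    """Patient-level variant class under pathogenic > unknown > benign precedence.

    ``probably_benign`` collapses into ``benign``.  A patient carrying both a
    VUS and a pathogenic variant is counted as a pathogenic-variant patient.

    Raises
    ------
    ValueError
        If the case has no variants (the class is undefined).
    """
    if not case.variants:
        raise ValueError(f"patient {case.patient_id!r} has no variants; class undefined")
    best = max(case.variants, key=lambda v: _CLASS_PRECEDENCE[v.known_class])
    rank = _CLASS_PRECEDENCE[best.known_class]
    return {2: "pathogenic", 1: "unknown", 0: "benign"}[rank]
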