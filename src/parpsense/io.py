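"""Readers and writers for cohort tables.

The on-disk cohort format is a pair of UTF-8 tab-separated files with
header rows:

* a *patients* file: ``patient_id, site, histology, ps, treatment,
  platinum_response, pfs_days, pfs_event``
* a *variants* file: ``patient_id, gene, cdna, protein, known_class, vaf,
  purity, provean_score, provean_call, dann_score, dann_call,
  second_hit_score, second_hit_call``

Empty cells are missing values.  HGVS strings are carried verbatim.
Variant allele frequencies may alternatively be pulled from a VCF file
(``dialect="vcf+tsv"``) whose sample names are patient ids, using the
per-sample ``AF`` field or, failing that, allele depths ``AD``.
"""

from __future__ import annotations

import os
from typing import Optional

import pandas as pd

from .models import Cohort, PatientCase, ValidationError, VariantRecord

__all__ = ["SchemaError", "read_cohort", "write_cohort", "read_vcf_variants"]

PATIENT_COLUMNS = [
    "patient_id",
    "site",
    "histology",
    "ps",
    "treatment",
    "platinum_response",
    "pfs_days",
    "pfs_event",
]
VARIANT_COLUMNS = [
    "patient_id",
    "gene",
    "cdna",
    "protein",
    "known_class",
    "vaf",
    "purity",
    "provean_score",
    "provean_call",
    "dann_score",
    "dann_call",
    "second_hit_score",
    "second_hit_call",
]

_TRUE = {"true", "1", "yes"}
_FALSE = {"false", "0", "no"}


class SchemaError(ValueError):
    """The file header does not match the documented schema."""


def _read_table(path: str, required: list[str]) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing mandatory column(s) {missing}")
    return df


def _opt_str(value: str) -> Optional[str]:
    value = value.strip()
    return value or None


def _opt_float(value: str, path: str, row: int, col: str) -> Optional[float]:
    value = value.strip()
    if not value:
        return None
    try:
        return float(value)
    except ValueError:
        raise ValidationError(f"{path} row {row}: unparseable {col} {value!r}") from None


def _opt_int(value: str, path: str, row: int, col: str) -> Optional[int]:
    value = value.strip()
    if not value:
        return None
    try:
        return int(value)
    except ValueError:
        raise ValidationError(f"{path} row {row}: unparseable {col} {value!r}") from None


def _bool(value: str, path: str, row: int) -> bool:
    v = value.strip().lower()
    if v in _TRUE:
        return True
    if v in _FALSE:
        return False
    raise ValidationError(f"{path} row {row}: unparseable pfs_event {value!r}")


def read_cohort(
    patients_path: str,
    variants_path: Optional[str] = None,
    dialect: str = "tsv",
    vcf_path: Optional[str] = None,
    label: str = "",
) -> Cohort:
    """Read a validated cohort from disk.

    ``variants_path`` defaults to the patients path with ``patients``
    replaced by ``variants`` when such a file exists.  With
    ``dialect="vcf+tsv"``, per-variant VAFs are overlaid from ``vcf_path``.
    Rows violating domain invariants raise :class:`ValidationError`
    naming the file and row.
    """
    if dialect not in ("tsv", "vcf+tsv"):
        raise ValueError(f"unknown dialect {dialect!r}")
    if variants_path is None:
        guess = patients_path.replace("patients", "variants")
        if guess != patients_path and os.path.exists(guess):
            variants_path = guess

    variants_by_patient: dict[str, list[VariantRecord]] = {}
    if variants_path is not None:
        vdf = _read_table(variants_path, VARIANT_COLUMNS)
        for i, row in enumerate(vdf.itertuples(index=False), start=2):
            try:
                rec = VariantRecord(
                    gene=row.gene.strip(),
                    cdna=row.cdna,
                    protein=row.protein,
                    known_class=row.known_class.strip(),
                    vaf=_opt_float(row.vaf, variants_path, i, "vaf"),
                    tumor_purity=_opt_float(row.purity, variants_path, i, "purity"),
                    provean_score=_opt_float(row.provean_score, variants_path, i, "provean_score"),
                    provean_call=_opt_str(row.provean_call),
                    dann_score=_opt_float(row.dann_score, variants_path, i, "dann_score"),
                    dann_call=_opt_str(row.dann_call),
                    second_hit_score=_opt_float(
                        row.second_hit_score, variants_path, i, "second_hit_score"
                    ),
                    second_hit_call=_opt_str(row.second_hit_call),
                )
            except ValidationError as exc:
                raise ValidationError(f"{variants_path} row {i}: {exc}") from None
            variants_by_patient.setdefault(row.patient_id.strip(), []).append(rec)

    if dialect == "vcf+tsv":
        if vcf_path is None:
            raise ValueError("dialect 'vcf+tsv' requires vcf_path")
        for pid, recs in read_vcf_variants(vcf_path).items():
            existing = variants_by_patient.setdefault(pid, [])
            by_key = {(v.gene, v.cdna): v for v in existing}
            for rec in recs:
                match = by_key.get((rec.gene, rec.cdna))
                if match is not None:
                    match.vaf = rec.vaf
                else:
                    existing.append(rec)

    pdf = _read_table(patients_path, PATIENT_COLUMNS)
    cases: list[PatientCase] = []
    for i, row in enumerate(pdf.itertuples(index=False), start=2):
        pid = row.patient_id.strip()
        try:
            cases.append(
                PatientCase(
                    patient_id=pid,
                    cancer_site=row.site.strip() or "other",
                    histology=row.histology,
                    performance_status=_opt_int(row.ps, patients_path, i, "ps"),
                    treatment=row.treatment.strip() or "none",
                    platinum_response=row.platinum_response.strip() or "missing",
                    pfs_days=_opt_int(row.pfs_days, patients_path, i, "pfs_days") or 0,
                    pfs_event=_bool(row.pfs_event, patients_path, i),
                    variants=variants_by_patient.get(pid, []),
                )
            )
        except ValidationError as exc:
            raise ValidationError(f"{patients_path} row {i}: {exc}") from None
    return Cohort(cases=cases, label=label or os.path.basename(patients_path))


def _fmt(value) -> str:
    if value is None:
        return ""
    if isinstance(value, bool):
        return "true" if value else "false"
    if isinstance(value, float):
        return f"{value:g}"
    return str(value)


def write_cohort(cohort: Cohort, patients_path: str, variants_path: str) -> None:
    """Write a cohort back to the two-file TSV schema."""
    prows = [
        {
            "patient_id": c.patient_id,
            "site": c.cancer_site,
            "histology": c.histology,
            "ps": _fmt(c.performance_status),
            "treatment": c.treatment,
            "platinum_response": c.platinum_response,
            "pfs_days": c.pfs_days,
            "pfs_event": _fmt(c.pfs_event),
        }
        for c in cohort
    ]
    vrows = [
        {
            "patient_id": c.patient_id,
            "gene": v.gene,
            "cdna": v.cdna,
            "protein": v.protein,
            "known_class": v.known_class,
            "vaf": _fmt(v.vaf),
            "purity": _fmt(v.tumor_purity),
            "provean_score": _fmt(v.provean_score),
            "provean_call": _fmt(v.provean_call),
            "dann_score": _fmt(v.dann_score),
            "dann_call": _fmt(v.dann_call),
            "second_hit_score": _fmt(v.second_hit_score),
            "second_hit_call": _fmt(v.second_hit_call),
        }
        for c in cohort
        for v in c.variants
    ]
    pd.DataFrame(prows, columns=PATIENT_COLUMNS).to_csv(patients_path, sep="\t", index=False)
    pd.DataFrame(vrows, columns=VARIANT_COLUMNS).to_csv(variants_path, sep="\t", index=False)


def read_vcf_variants(vcf_path: str) -> dict[str, list[VariantRecord]]:
    """Extract per-sample variant records with VAFs from a VCF 4.x file.

    The VAF comes from the per-sample ``AF`` FORMAT field when present,
    otherwise from allele depths ``AD`` as alt/(ref+alt).  The gene symbol
    is taken from an INFO ``GENE`` key when present, else the record ID,
    else ``"."``.  Samples with no called alternate allele are skipped.
    """
    import pysam

    out: dict[str, list[VariantRecord]] = {}
    with pysam.VariantFile(vcf_path) as vcf:
        for rec in vcf:
            gene = rec.info.get("GENE", rec.id or ".")
            if isinstance(gene, tuple):
                gene = gene[0]
            cdna = f"{rec.chrom}:{rec.pos}{rec.ref}>{(rec.alts or ('?',))[0]}"
            for sample_name, sample in rec.samples.items():
                gt = sample.get("GT")
                if gt is None or not any(a for a in gt if a):
                    continue
                vaf = None
                af = sample.get("AF")
                if af is not None:
                    vaf = af[0] if isinstance(af, tuple) else af
                else:
                    ad = sample.get("AD")
                    if ad is not None and len(ad) >= 2 and None not in ad[:2]:
                        total = ad[0] + ad[1]
                        vaf = ad[1] / total if total else None
                out.setdefault(sample_name, []).append(
                    VariantRecord(gene=str(gene), cdna=cdna, known_class="unknown", vaf=vaf)
                )
    return out
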