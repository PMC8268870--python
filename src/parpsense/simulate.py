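"""Seeded synthetic-cohort generator.

Emulates the statistical structure the classifier assumes so that every
pipeline stage is testable without patient data: each simulated patient
carries one homologous-recombination variant of a known true class, a
pathologist purity estimate, a variant allele frequency generated from an
explicit allele-count model with binomial read-depth noise, in-silico
calls that are correct for the true class up to a configurable flip rate,
and an exponential progression-free-survival time whose median depends on
the true class and Performance Status.

The allele-count forward model (diploid tumor and normal cells, purity p):

=====================  ==========================  =================
state                  variant-allele fraction      VAF/purity score
=====================  ==========================  =================
somatic het, no loss   p/2                          0.5
somatic het, WT loss   p/(2-p)                      1/(2-p)
germline het, no loss  1/2                          1/(2p)
germline het, WT loss  1/(2-p)                      1/((2-p)p)
=====================  ==========================  =================

Loss of the wild-type allele removes one of the two alleles of every
tumor cell, shrinking the denominator to 2-p alleles per cell on average.
Defaults simulate somatic variants; germline zygosity is available via
``germline_prob`` but note that an unlost germline heterozygote already
scores 1/(2p), which crosses the 0.7 green threshold at purities below
~0.71 — the known confounder of purity-ratio LOH inference.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .classifier import classify_consensus
from .config import DEFAULT_CONFIG, RunConfig
from .models import Cohort, PatientCase, VariantRecord
from .survival import logrank_test

__all__ = ["SimConfig", "true_vaf", "simulate_cohort", "recovery_experiment"]

TRUE_CLASSES = ("benign", "vus_benign", "vus_deleterious", "pathogenic")

_GENES = ("BRCA1", "BRCA2", "PALB2", "ATM", "RAD51C", "BRIP1", "RAD51D", "RAD50")


@dataclass(frozen=True)
class SimConfig:
    """Generator parameters.

    The defaults mirror the olaparib study cohort: ~100x panel coverage,
    FFPE purities of 60-90%, roughly 10% benign / 30% VUS (half of which
    are truly deleterious) / 60% pathogenic carriers, Performance Status
    mostly 0-2 with a PS>=3 tail, and class-separated exponential PFS
    with medians 81 days (benign behavior) and 190 days (deleterious
    behavior), censored ~10% of the time.
    """

    n_patients: int = 60
    class_mix: dict = field(
        default_factory=lambda: {
            "benign": 0.10,
            "vus_benign": 0.15,
            "vus_deleterious": 0.15,
            "pathogenic": 0.60,
        }
    )
    purity_range: tuple[float, float] = (0.6, 0.9)
    read_depth: int = 100
    loss_prob_given_deleterious: float = 0.8
    germline_prob: float = 0.0
    insilico_flip_rate: float = 0.1
    ps_distribution: tuple[float, ...] = (0.10, 0.55, 0.15, 0.20, 0.0)
    pfs_median_by_true_class: dict = field(
        default_factory=lambda: {
            "benign": 81.0,
            "vus_benign": 81.0,
            "vus_deleterious": 190.0,
            "pathogenic": 190.0,
        }
    )
    censor_prob: float = 0.1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_patients < 0:
            raise ValueError("n_patients must be >= 0")
        if self.read_depth < 1:
            raise ValueError("read_depth must be >= 1")
        for name, probs in (
            ("class_mix", list(self.class_mix.values())),
            ("ps_distribution", list(self.ps_distribution)),
        ):
            if any(p < 0 for p in probs) or abs(sum(probs) - 1.0) > 1e-9:
                raise ValueError(f"{name} must be nonnegative and sum to 1")
        if set(self.class_mix) != set(TRUE_CLASSES):
            raise ValueError(f"class_mix must cover exactly {TRUE_CLASSES}")
        lo, hi = self.purity_range
        if not 0.0 < lo <= hi <= 1.0:
            raise ValueError("purity_range must lie within (0, 1]")


def true_vaf(purity: float, germline: bool, loss: bool) -> float:
    """Expected variant allele fraction under the allele-count model."""
    if loss:
        return 1.0 / (2.0 - purity) if germline else purity / (2.0 - purity)
    return 0.5 if germline else purity / 2.0


def _flip(rng: np.random.Generator, call: str, rate: float) -> str:
    if rng.random() < rate:
        return "B" if call == "D" else "D"
    return call


def simulate_cohort(cfg: SimConfig) -> tuple[Cohort, pd.DataFrame]:
    """Generate a cohort and its ground-truth table.

    Identical configs (including the seed) give identical outputs.
    """
    rng = np.random.default_rng(cfg.seed)
    classes = list(cfg.class_mix)
    probs = np.array([cfg.class_mix[c] for c in classes])
    cases: list[PatientCase] = []
    truth_rows: list[dict] = []
    for i in range(cfg.n_patients):
        true_class = classes[rng.choice(len(classes), p=probs)]
        purity = float(rng.uniform(*cfg.purity_range))
        germline = bool(rng.random() < cfg.germline_prob)
        deleterious = true_class in ("vus_deleterious", "pathogenic")
        loss = bool(deleterious and rng.random() < cfg.loss_prob_given_deleterious)
        tv = true_vaf(purity, germline, loss)
        obs_vaf = float(rng.binomial(cfg.read_depth, tv) / cfg.read_depth)
        correct = "D" if deleterious else "B"
        provean = _flip(rng, correct, cfg.insilico_flip_rate)
        dann = _flip(rng, correct, cfg.insilico_flip_rate)
        ps = int(rng.choice(5, p=np.asarray(cfg.ps_distribution)))
        median = cfg.pfs_median_by_true_class[true_class]
        if ps >= 3:
            median = min(median, 60.0)  # poor-PS patients progress early
        t = rng.exponential(median / np.log(2.0))
        event = bool(rng.random() >= cfg.censor_prob)
        if not event:
            t = t * rng.uniform(0.2, 1.0)  # censored partway through follow-up
        pfs = max(1, int(round(t)))
        known = {
            "benign": "benign",
            "vus_benign": "unknown",
            "vus_deleterious": "unknown",
            "pathogenic": "pathogenic",
        }[true_class]
        gene = _GENES[rng.integers(len(_GENES))]
        variant = VariantRecord(
            gene=gene,
            cdna=f"c.{100 + i}A > G",
            protein=f"p.Sim{i}",
            known_class=known,
            vaf=obs_vaf,
            tumor_purity=purity,
            provean_call=provean,
            dann_call=dann,
        )
        cases.append(
            PatientCase(
                patient_id=f"sim_{i:03d}",
                cancer_site="ovary",
                performance_status=ps,
                treatment="olaparib",
                platinum_response="missing",
                pfs_days=pfs,
                pfs_event=event,
                variants=[variant],
            )
        )
        truth_rows.append(
            {
                "patient_id": f"sim_{i:03d}",
                "true_class": true_class,
                "germline": germline,
                "loss": loss,
                "purity": purity,
                "true_vaf": tv,
                "observed_vaf": obs_vaf,
                "ps": ps,
                "pfs_days": pfs,
                "pfs_event": event,
            }
        )
    truth = pd.DataFrame(
        truth_rows,
        columns=[
            "patient_id",
            "true_class",
            "germline",
            "loss",
            "purity",
            "true_vaf",
            "observed_vaf",
            "ps",
            "pfs_days",
            "pfs_event",
        ],
    )
    return Cohort(cases, label=f"simulated(seed={cfg.seed})"), truth


def recovery_experiment(
    cfg: SimConfig, config: RunConfig = DEFAULT_CONFIG
) -> dict:
    """Run the full pipeline on a simulated cohort and score it.

    Sensitivity is the fraction of truly deleterious VUS patients labelled
    Sensitive, specificity the fraction of truly benign VUS patients
    labelled Resistant (Uncertain counts as a miss for both).  Also
    reports the log-rank p-value between predicted S and R groups.
    """
    cohort, truth = simulate_cohort(cfg)
    if len(cohort) == 0:
        return {"n": 0, "n_vus": 0, "sensitivity": None, "specificity": None, "logrank_p": None}
    truth_by_id = truth.set_index("patient_id")
    labels: dict[str, str] = {}
    for case in cohort:
        if case.vus:
            labels[case.patient_id] = classify_consensus(case, config).final_label
    tp = fn = tn = fp = 0
    for pid, label in labels.items():
        cls = truth_by_id.loc[pid, "true_class"]
        if cls == "vus_deleterious":
            tp += label == "S"
            fn += label != "S"
        elif cls == "vus_benign":
            tn += label == "R"
            fp += label != "R"
    sensitivity = tp / (tp + fn) if tp + fn else None
    specificity = tn / (tn + fp) if tn + fp else None
    s_ids = [pid for pid, lab in labels.items() if lab == "S"]
    r_ids = [pid for pid, lab in labels.items() if lab == "R"]
    logrank_p = None
    if s_ids and r_ids:
        by_id = {c.patient_id: c for c in cohort}
        grp = lambda ids: (
            [by_id[i].pfs_days for i in ids],
            [by_id[i].pfs_event for i in ids],
        )
        logrank_p = logrank_test(grp(s_ids), grp(r_ids)).p_value
    return {
        "n": len(cohort),
        "n_vus": len(labels),
        "sensitivity": sensitivity,
        "specificity": specificity,
        "logrank_p": logrank_p,
    }
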