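"""The VUS sensitivity-prediction algorithm.

Two evidence models are run in parallel, one pairing the second-hit
(loss-of-wild-type-allele) call with PROVEAN and one pairing it with DANN.
Within a model a VUS is *deleterious* as soon as either line of evidence
says D — the rationale being that either a lost wild-type allele or a
damaging protein change suffices for homologous-recombination failure —
and *benign* only when both lines resolve to B.  A patient is predicted
Sensitive (S) under a model when any of their VUS is deleterious, unless
their Performance Status is at or above the gate (default PS 3), which
forces Resistant (R): poor-PS patients progress before a PARP inhibitor
can act, whatever the tumor genotype.  The final prediction is the
consensus of the two models; disagreement yields Uncertain (U).

Patients whose tumors carry a known pathogenic or only benign variants do
not need the algorithm; :func:`decision_tree` routes them directly.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from . import second_hit as sh
from .config import DEFAULT_CONFIG, RunConfig
from .insilico import call_dann, call_provean
from .models import PatientCase, VariantRecord, patient_variant_class

__all__ = [
    "MODELS",
    "ClassificationResult",
    "resolve_second_hit",
    "resolve_insilico",
    "classify_variant",
    "classify_patient",
    "classify_consensus",
    "decision_tree",
]

#: The two evidence models: second hit combined with one in-silico tool.
MODELS = ("provean_based", "dann_based")


def resolve_second_hit(v: VariantRecord, config: RunConfig = DEFAULT_CONFIG) -> sh.SecondHitResult:
    return sh.assess(
        v.vaf,
        v.tumor_purity,
        precomputed_score=v.second_hit_score,
        precomputed_call=v.second_hit_call,
        threshold=config.second_hit_threshold,
    )


def resolve_insilico(v: VariantRecord, model: str, config: RunConfig = DEFAULT_CONFIG) -> str:
    if model == "provean_based":
        return call_provean(v.provean_score, v.provean_call, config.provean_cutoff).call
    if model == "dann_based":
        return call_dann(v.dann_score, v.dann_call, config.dann_cutoff).call
    raise ValueError(f"unknown evidence model {model!r}; expected one of {MODELS}")


def classify_variant(
    v: VariantRecord, model: str, config: RunConfig = DEFAULT_CONFIG
) -> str:
    """Per-model verdict for one VUS: deleterious / benign / unknown.

    Deleterious as soon as the second-hit call or the model's in-silico
    call is D; benign only when both are B; otherwise unknown.  Unknown
    evidence therefore never argues for sensitivity.
    """
    hit = resolve_second_hit(v, config).call
    tool = resolve_insilico(v, model, config)
    if "D" in (hit, tool):
        return "deleterious"
    if hit == "B" and tool == "B":
        return "benign"
    return "unknown"


def _ps_gated(case: PatientCase, config: RunConfig) -> bool:
    return (
        case.performance_status is not None
        and case.performance_status >= config.ps_cutoff
    )


def classify_patient(
    case: PatientCase, model: str, config: RunConfig = DEFAULT_CONFIG
) -> str:
    """Patient-level S/R label under one evidence model.

    Requires at least one VUS.  Performance Status at or above the gate
    forces R; otherwise the patient is S when any VUS is deleterious.
    """
    vus = case.vus
    if not vus:
        raise ValueError(
            f"patient {case.patient_id!r} carries no VUS; "
            "route known classes through decision_tree instead"
        )
    if _ps_gated(case, config):
        return "R"
    if any(classify_variant(v, model, config) == "deleterious" for v in vus):
        return "S"
    return "R"


@dataclass
class ClassificationResult:
    """Outcome of the dual-model consensus for one patient."""

    patient_id: str
    per_variant: dict[str, list[str]]  # model -> verdict per VUS, in order
    per_model_label: dict[str, str]  # model -> "S" | "R"
    final_label: str  # "S" | "R" | "U"
    ps_gated: bool
    rationale: list[str] = field(default_factory=list)


def classify_consensus(
    case: PatientCase, config: RunConfig = DEFAULT_CONFIG
) -> ClassificationResult:
    """Run both evidence models and take their consensus.

    Agreement gives that label; disagreement gives Uncertain ("U"),
    which covers both an "S or R" split and genuinely unresolvable
    evidence.
    """
    vus = case.vus
    rationale: list[str] = []
    gated = _ps_gated(case, config)
    per_variant: dict[str, list[str]] = {}
    per_model: dict[str, str] = {}
    for model in MODELS:
        verdicts = [classify_variant(v, model, config) for v in vus]
        per_variant[model] = verdicts
        per_model[model] = classify_patient(case, model, config)
        for v, verdict in zip(vus, verdicts):
            hit = resolve_second_hit(v, config)
            tool = resolve_insilico(v, model, config)
            score = "n/a" if hit.score is None else f"{hit.score:.2f}"
            rationale.append(
                f"[{model}] {v.gene} {v.protein or v.cdna}: "
                f"second_hit={hit.call} (score {score}), in_silico={tool} -> {verdict}"
            )
    if gated:
        rationale.append(
            f"PS {case.performance_status} >= {config.ps_cutoff}: gated to Resistant"
        )
    labels = set(per_model.values())
    final = labels.pop() if len(labels) == 1 else "U"
    rationale.append(
        f"models {per_model['provean_based']}/{per_model['dann_based']} -> final {final}"
    )
    return ClassificationResult(
        patient_id=case.patient_id,
        per_variant=per_variant,
        per_model_label=per_model,
        final_label=final,
        ps_gated=gated,
        rationale=rationale,
    )


def decision_tree(case: PatientCase, config: RunConfig = DEFAULT_CONFIG) -> str:
    """Treatment-decision routing for any patient.

    Known pathogenic variant -> ``treat_parpi_sensitive`` (PS-independent
    by default); no variants or only benign -> ``do_not_expect_hrd_response``;
    VUS present -> the consensus algorithm's label, mapped S -> sensitive,
    R -> no response expected, U -> uncertain.
    """
    if not case.variants:
        return "do_not_expect_hrd_response"
    cls = patient_variant_class(case)
    if cls == "pathogenic":
        if config.gate_known_pathogenic and _ps_gated(case, config):
            return "do_not_expect_hrd_response"
        return "treat_parpi_sensitive"
    if cls == "benign":
        return "do_not_expect_hrd_response"
    final = classify_consensus(case, config).final_label
    return {
        "S": "treat_parpi_sensitive",
        "R": "do_not_expect_hrd_response",
        "U": "treat_uncertain",
    }[final]
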