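"""The VUS classification algorithm: per-variant verdicts, the PS gate,
dual-model consensus, and the treatment-decision tree."""

import itertools

import pytest

from parpsense import (
    RunConfig,
    classify_consensus,
    classify_patient,
    classify_variant,
    decision_tree,
)
from parpsense.fixtures import TABLE3_FINAL_PREDICTION, TABLE5_FINAL_PREDICTION
from parpsense.models import PatientCase, VariantRecord


def vus(sh="U", dann="U", provean="U"):
    return VariantRecord(
        gene="BRCA1",
        known_class="unknown",
        second_hit_call=sh,
        dann_call=dann,
        provean_call=provean,
    )


def case(variants, ps=1, pid="p1", pfs=100):
    return PatientCase(
        patient_id=pid, performance_status=ps, pfs_days=pfs, variants=variants
    )


def by_id(cohort, pid):
    return next(c for c in cohort if c.patient_id == pid)


class TestClassifyVariant:
    def test_insilico_d_suffices(self, table3):
        v = by_id(table3, "Ovarian #2").variants[0]  # second hit B, PROVEAN D
        assert classify_variant(v, "provean_based") == "deleterious"

    def test_second_hit_d_suffices(self, table3):
        v = by_id(table3, "Ovarian #6").variants[0]  # second hit D, DANN B
        assert classify_variant(v, "dann_based") == "deleterious"

    def test_benign_needs_both_b(self, table3):
        v = by_id(table3, "Digestive tract #1").variants[0]  # B, B, B
        assert classify_variant(v, "provean_based") == "benign"
        assert classify_variant(v, "dann_based") == "benign"

    def test_unknown_when_no_d_and_some_u(self):
        assert classify_variant(vus(sh="B", dann="U"), "dann_based") == "unknown"

    @pytest.mark.parametrize("sh,tool", list(itertools.product("BDU", repeat=2)))
    def test_exhaustive_truth_table(self, sh, tool):
        expected = (
            "deleterious" if "D" in (sh, tool) else "benign" if sh == tool == "B" else "unknown"
        )
        assert classify_variant(vus(sh=sh, provean=tool), "provean_based") == expected


class TestClassifyPatient:
    def test_ps3_gates_to_resistant(self, table3):
        c = by_id(table3, "Digestive tract #2")  # strong evidence but PS 3
        assert classify_patient(c, "provean_based") == "R"
        assert classify_patient(c, "dann_based") == "R"

    def test_deleterious_with_good_ps_is_sensitive(self, table3):
        c = by_id(table3, "Skin #1")  # PS 1, RAD51C second hit D
        assert classify_patient(c, "provean_based") == "S"

    def test_all_benign_is_resistant(self, table3):
        c = by_id(table3, "Digestive tract #5")  # PS 0, all B
        assert classify_patient(c, "provean_based") == "R"

    def test_requires_a_vus(self):
        c = case([VariantRecord(gene="BRCA1", known_class="pathogenic")])
        with pytest.raises(ValueError, match="decision_tree"):
            classify_patient(c, "provean_based")

    def test_unknown_evidence_never_triggers_sensitive(self):
        assert classify_patient(case([vus()]), "provean_based") == "R"

    def test_brute_force_oracle_equivalence(self):
        """classify_patient matches an independently stated truth table
        over every evidence combination and Performance Status."""
        for sh, dann, provean, ps in itertools.product("BDU", "BDU", "BDU", range(5)):
            c = case([vus(sh, dann, provean)], ps=ps)
            for model, tool in (("provean_based", provean), ("dann_based", dann)):
                oracle = "R" if ps >= 3 else ("S" if "D" in (sh, tool) else "R")
                assert classify_patient(c, model) == oracle, (sh, dann, provean, ps, model)


class TestConsensus:
    def test_table3_full_reproduction(self, table3):
        got = {c.patient_id: classify_consensus(c).final_label for c in table3}
        assert got == TABLE3_FINAL_PREDICTION

    def test_table5_full_reproduction(self, table5):
        got = {c.patient_id: classify_consensus(c).final_label for c in table5}
        assert got == TABLE5_FINAL_PREDICTION

    def test_disagreement_is_uncertain(self, table3):
        res = classify_consensus(by_id(table3, "Ovarian #23"))
        assert res.per_model_label == {"provean_based": "S", "dann_based": "R"}
        assert res.final_label == "U"

    def test_any_vus_deleterious_aggregation(self, table3):
        # second variant is DANN D although the first is not
        assert classify_consensus(by_id(table3, "Breast #8")).final_label == "S"

    def test_rationale_mentions_gate(self, table3):
        res = classify_consensus(by_id(table3, "Digestive tract #7"))
        assert res.ps_gated and any("gated" in r for r in res.rationale)

    def test_permutation_invariance(self, table3):
        for c in table3:
            flipped = PatientCase(
                patient_id=c.patient_id,
                cancer_site=c.cancer_site,
                performance_status=c.performance_status,
                treatment=c.treatment,
                pfs_days=c.pfs_days,
                pfs_event=c.pfs_event,
                variants=list(reversed(c.variants)),
            )
            assert classify_consensus(flipped).final_label == classify_consensus(c).final_label

    def test_adding_deleterious_variant_never_flips_s_to_r(self):
        for sh, dann, provean in itertools.product("BDU", repeat=3):
            base = case([vus(sh, dann, provean)], ps=1)
            extended = case([vus(sh, dann, provean), vus(sh="D", dann="D", provean="D")], ps=1)
            before = classify_consensus(base)
            after = classify_consensus(extended)
            for model in ("provean_based", "dann_based"):
                if before.per_model_label[model] == "S":
                    assert after.per_model_label[model] == "S"
            assert after.final_label == "S"

    def test_ps_dominance(self):
        for sh, dann, provean in itertools.product("BDU", repeat=3):
            res = classify_consensus(case([vus(sh, dann, provean)], ps=3))
            assert res.final_label == "R" and res.ps_gated


class TestDecisionTree:
    def test_pathogenic_routes_to_sensitive(self, table2):
        assert decision_tree(by_id(table2, "Ovarian #1")) == "treat_parpi_sensitive"

    def test_benign_only_routes_to_no_response(self, table2):
        assert decision_tree(by_id(table2, "Ovarian #12")) == "do_not_expect_hrd_response"

    def test_uncertain_vus_propagates(self, table2):
        assert decision_tree(by_id(table2, "Ovarian #23")) == "treat_uncertain"

    def test_no_variants_means_no_hrd_response(self):
        assert decision_tree(case([], ps=1)) == "do_not_expect_hrd_response"

    def test_pathogenic_ignores_ps_by_default(self):
        c = case([VariantRecord(gene="BRCA1", known_class="pathogenic")], ps=3)
        assert decision_tree(c) == "treat_parpi_sensitive"
        gated = RunConfig(gate_known_pathogenic=True)
        assert decision_tree(c, gated) == "do_not_expect_hrd_response"

    def test_sensitive_and_resistant_vus_routing(self, table3):
        assert decision_tree(by_id(table3, "Skin #1")) == "treat_parpi_sensitive"
        assert decision_tree(by_id(table3, "Digestive tract #5")) == "do_not_expect_hrd_response"
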