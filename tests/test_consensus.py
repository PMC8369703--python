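"""Consensus-variant evaluation, cross-classification, and agreement."""

import dataclasses

import numpy as np
import pandas as pd
import pytest

from conftest import make_assessment
from oracles import VARIANT_ORACLES
from triagekit.consensus import (
    RescuerProfile,
    agreement_matrix,
    cross_classify,
    evaluate_consensus,
)
from triagekit.cohort import CohortSpecification, generate_cohort
from triagekit.errors import DomainError, MissingFieldError
from triagekit.model import Assessment, LSIAction, Tier, Training
from triagekit.synthesis import LSIPolicy, consensus_to_system
from triagekit.systems import (
    enumerate_assessment_space,
    evaluate,
    load_system,
    system_grids,
    system_to_yaml,
)


class TestEvaluateConsensus:
    def test_walker_green(self, majority):
        assert (
            evaluate_consensus(majority, Assessment(ambulatory="yes")).tier
            is Tier.P3_DELAYED_GREEN
        )

    def test_unremarkable_non_walker_yellow(self, majority):
        a = make_assessment(ambulatory="no", respiratory_rate=20)
        assert evaluate_consensus(majority, a).tier is Tier.P2_URGENT_YELLOW

    def test_bradypnea_red(self, majority):
        a = make_assessment(ambulatory="no", respiratory_rate=8)
        assert evaluate_consensus(majority, a).tier is Tier.P1_IMMEDIATE_RED

    def test_apneic_black_without_positioning_step(self, majority):
        a = Assessment(ambulatory="no", spontaneous_breathing="no")
        res = evaluate_consensus(majority, a)
        assert res.tier is Tier.PX_DEAD_BLACK
        assert res.lsis_recommended == []

    def test_cbrn_never_interrogates_pulse(self, cbrn):
        a = make_assessment(
            ambulatory="no", respiratory_rate=20, radial_pulse_palpable="unknown"
        )
        res = evaluate_consensus(cbrn, a)
        assert res.tier is Tier.P2_URGENT_YELLOW
        assert all(cid != "radial_pulse" for cid, _ in res.trace)

    def test_missing_field_error_names_criterion(self, majority):
        with pytest.raises(MissingFieldError, match="spontaneous_breathing"):
            evaluate_consensus(majority, Assessment(ambulatory="no"))

    @pytest.mark.parametrize(
        "rr,expected",
        [
            (10, Tier.P2_URGENT_YELLOW),
            (30, Tier.P2_URGENT_YELLOW),
            (9, Tier.P1_IMMEDIATE_RED),
            (31, Tier.P1_IMMEDIATE_RED),
        ],
    )
    def test_rr_band_endpoints_inclusive_normal(self, majority, rr, expected):
        a = make_assessment(ambulatory="no", respiratory_rate=rr)
        assert evaluate_consensus(majority, a).tier is expected


class TestLSIGating:
    def test_modified_recommends_hemorrhage_control(self, modified):
        a = make_assessment(ambulatory="no", major_external_hemorrhage="yes")
        res = evaluate_consensus(modified, a)
        assert res.tier is Tier.P1_IMMEDIATE_RED
        assert [l.kind.value for l in res.lsis_recommended] == ["hemorrhage_control"]
        assert ("lsi:hemorrhage_control", "performed") in res.trace

    def test_unpermitted_lsi_recorded_not_dropped(self, modified):
        # raise the training bar so a lay rescuer cannot perform the control
        policy = tuple(
            LSIPolicy(
                action=LSIAction(kind=p.action.kind, requires_training=Training.MEDICAL),
                enabled=p.enabled,
            )
            for p in modified.lsi_policy
        )
        strict = dataclasses.replace(modified, lsi_policy=policy)
        a = make_assessment(ambulatory="no", major_external_hemorrhage="yes")
        res = evaluate_consensus(strict, a, RescuerProfile(training=Training.LAYPERSON))
        assert res.lsis_recommended == []
        assert ("lsi:hemorrhage_control", "indicated, not performed") in res.trace
        # gating never alters the assigned tier
        assert res.tier is evaluate_consensus(modified, a).tier

    def test_equipment_gating(self):
        bare_hands = RescuerProfile(training=Training.ADVANCED, equipment=frozenset())
        assert not bare_hands.permits(LSIAction(kind="chest_decompression"))
        assert bare_hands.permits(LSIAction(kind="airway_positioning"))


@pytest.mark.parametrize("variant", ["majority", "modified", "cbrn"])
def test_consensus_matches_truth_table_oracle(variant, majority, modified, cbrn):
    spec = {"majority": majority, "modified": modified, "cbrn": cbrn}[variant]
    oracle = VARIANT_ORACLES[variant]
    compiled = consensus_to_system(spec)
    for a in enumerate_assessment_space(system_grids(compiled)):
        assert evaluate_consensus(spec, a).tier is oracle(a)


def test_consensus_serialized_rule_file_equals_direct_evaluation(majority, modified, cbrn):
    """The derived tool is just another system: compiling the specification
    to a rule file and running the generic engine reproduces every tier."""
    for spec in (majority, modified, cbrn):
        reloaded = load_system(system_to_yaml(consensus_to_system(spec)))
        for a in enumerate_assessment_space(system_grids(reloaded)):
            engine = evaluate(reloaded, a)
            direct = evaluate_consensus(spec, a)
            assert engine.tier is direct.tier
            assert {l.kind for l in engine.lsis_recommended} == {
                l.kind for l in direct.lsis_recommended
            }


class TestCrossClassify:
    def test_walker_green_everywhere_but_salt(self, systems, majority):
        walker = make_assessment(ambulatory="yes", minor_injuries_only="no")
        matrix = cross_classify(list(systems.values()) + [majority], [walker])
        row = matrix.iloc[0]
        for sid in matrix.columns:
            if sid == "SALT":
                assert row[sid] == Tier.P2_URGENT_YELLOW.value
            else:
                assert row[sid] == Tier.P3_DELAYED_GREEN.value

    def test_empty_cohort(self, systems):
        matrix = cross_classify(list(systems.values()), [])
        assert matrix.shape == (0, 7)

    def test_full_cohort_no_errors(self, systems, majority):
        cohort, _ = generate_cohort(CohortSpecification(n=50, seed=11))
        matrix = cross_classify(list(systems.values()) + [majority], cohort)
        assert matrix.shape == (50, 8)
        assert matrix.notna().all().all()

    def test_error_carries_casualty_index(self, systems):
        cohort = [make_assessment(), Assessment(ambulatory="no")]
        with pytest.raises(MissingFieldError) as err:
            cross_classify([systems["CFT"]], cohort)
        assert any("casualty index 1" in note for note in err.value.__notes__)


class TestAgreement:
    def test_identical_columns_agree_perfectly(self):
        col = [Tier.P3_DELAYED_GREEN.value, Tier.P1_IMMEDIATE_RED.value] * 3
        matrix = pd.DataFrame({"a": col, "b": col})
        out = agreement_matrix(matrix)
        assert out.raw.loc["a", "b"] == 1.0
        assert out.kappa.loc["a", "b"] == 1.0
        assert (np.diag(out.raw) == 1.0).all()

    def test_chance_level_agreement_gives_zero_kappa(self):
        g, r = Tier.P3_DELAYED_GREEN.value, Tier.P1_IMMEDIATE_RED.value
        matrix = pd.DataFrame({"a": [g, g, r, r], "b": [g, r, g, r]})
        assert agreement_matrix(matrix).kappa.loc["a", "b"] == pytest.approx(0.0)

    def test_three_tier_kappa_matches_hand_computation(self):
        g, y, r = (
            Tier.P3_DELAYED_GREEN.value,
            Tier.P2_URGENT_YELLOW.value,
            Tier.P1_IMMEDIATE_RED.value,
        )
        a = [g, g, g, y, y, r, r, r, r, r]
        b = [g, g, y, y, r, r, r, r, g, y]
        # brute-force kappa from the confusion matrix marginals
        observed = sum(x == z for x, z in zip(a, b)) / 10
        chance = sum((a.count(t) / 10) * (b.count(t) / 10) for t in (g, y, r))
        expected = (observed - chance) / (1 - chance)
        out = agreement_matrix(pd.DataFrame({"a": a, "b": b}))
        assert out.kappa.loc["a", "b"] == pytest.approx(expected)
        assert out.kappa.loc["b", "a"] == pytest.approx(expected)

    def test_gray_folds_onto_immediate(self):
        r, gray = Tier.P1_IMMEDIATE_RED.value, Tier.GRAY_EXPECTANT.value
        matrix = pd.DataFrame({"a": [r, r], "b": [gray, r]})
        out = agreement_matrix(matrix)
        assert out.raw.loc["a", "b"] == 1.0

    def test_single_system_rejected(self):
        with pytest.raises(DomainError):
            agreement_matrix(pd.DataFrame({"a": [Tier.P3_DELAYED_GREEN.value]}))

    def test_kappa_bounded(self, systems):
        cohort, _ = generate_cohort(CohortSpecification(n=120, seed=3))
        matrix = cross_classify(list(systems.values()), cohort)
        kappa = agreement_matrix(matrix).kappa
        assert ((kappa.values >= -1) & (kappa.values <= 1)).all()
        assert np.allclose(kappa.values, kappa.values.T)
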