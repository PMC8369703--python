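"""Rule-file loading, tree evaluation, and the enumeration utilities."""

import pytest
import yaml
from hypothesis import given

from conftest import complete_assessments, make_assessment
from oracles import SYSTEM_ORACLES
from triagekit.errors import ConfigurationError, SchemaError, StructuralError
from triagekit.model import Assessment, Ternary, Tier
from triagekit.systems import (
    SYSTEM_IDS,
    enumerate_assessment_space,
    evaluate,
    get_system,
    load_system,
    replay_trace,
    salt_global_sort,
    system_grids,
    system_to_yaml,
)

MINIMAL = {
    "id": "TOY",
    "name": "toy",
    "tiers": ["P3_DELAYED_GREEN", "P1_IMMEDIATE_RED"],
    "root": "walking",
    "nodes": [
        {
            "id": "walking",
            "predicate": {"name": "ask", "field": "ambulatory"},
            "on_yes": {"tier": "P3_DELAYED_GREEN"},
            "on_no": {"tier": "P1_IMMEDIATE_RED"},
        }
    ],
}


class TestLoading:
    def test_start_has_four_core_tiers(self, systems):
        assert set(systems["START_mSTART"].tiers) == {
            Tier.P3_DELAYED_GREEN,
            Tier.P2_URGENT_YELLOW,
            Tier.P1_IMMEDIATE_RED,
            Tier.PX_DEAD_BLACK,
        }

    def test_salt_has_five_tiers_including_gray(self, systems):
        assert len(systems["SALT"].tiers) == 5
        assert Tier.GRAY_EXPECTANT in systems["SALT"].tiers

    def test_exactly_seven_fixtures(self, systems):
        assert len(systems) == 7
        assert set(systems) == set(SYSTEM_IDS)

    def test_dangling_reference_rejected(self):
        bad = yaml.safe_load(yaml.safe_dump(MINIMAL))
        bad["nodes"][0]["on_no"] = {"node": "ghost"}
        with pytest.raises(StructuralError, match="ghost"):
            load_system(bad)

    def test_cycle_rejected(self):
        bad = yaml.safe_load(yaml.safe_dump(MINIMAL))
        bad["nodes"][0]["on_no"] = {"node": "loop"}
        bad["nodes"].append(
            {
                "id": "loop",
                "predicate": {"name": "ask", "field": "follows_commands"},
                "on_yes": {"node": "walking"},
                "on_no": {"tier": "P1_IMMEDIATE_RED"},
            }
        )
        with pytest.raises(StructuralError, match="cycle"):
            load_system(bad)

    def test_schema_violation_names_location(self):
        bad = yaml.safe_load(yaml.safe_dump(MINIMAL))
        bad["nodes"][0]["predicate"] = {"name": "astrology"}
        with pytest.raises(SchemaError, match="astrology"):
            load_system(bad)

    def test_branch_must_have_single_target(self):
        bad = yaml.safe_load(yaml.safe_dump(MINIMAL))
        bad["nodes"][0]["on_yes"] = {}
        with pytest.raises(SchemaError):
            load_system(bad)

    def test_yaml_round_trip(self, systems):
        for system in systems.values():
            again = load_system(system_to_yaml(system))
            assert again == system


class TestEvaluate:
    def test_start_walker_is_delayed(self, systems):
        res = evaluate(systems["START_mSTART"], Assessment(ambulatory="yes"))
        assert res.tier is Tier.P3_DELAYED_GREEN
        assert res.trace == [("walking", "yes")]

    def test_start_apneic_after_positioning_is_dead(self, systems):
        a = Assessment(
            ambulatory="no",
            spontaneous_breathing="no",
            breathing_after_airway_positioning="no",
            airway_positioning_attempts=2,
        )
        res = evaluate(systems["START_mSTART"], a)
        assert res.tier is Tier.PX_DEAD_BLACK
        assert any(l.kind.value == "airway_positioning" for l in res.lsis_recommended)

    def test_ts_tachypnea_is_immediate(self, systems):
        a = make_assessment(ambulatory="no", respiratory_rate=35)
        assert evaluate(systems["TS"], a).tier is Tier.P1_IMMEDIATE_RED

    def test_salt_unsurvivable_uncontrolled_bleed_is_expectant(self, systems):
        a = Assessment(
            can_wave="no",
            major_external_hemorrhage="yes",
            hemorrhage_controlled_after_intervention="no",
            spontaneous_breathing="yes",
            survivable_given_resources="no",
        )
        res = evaluate(systems["SALT"], a)
        assert res.tier is Tier.GRAY_EXPECTANT
        assert any(l.kind.value == "hemorrhage_control" for l in res.lsis_recommended)

    def test_deterministic_including_trace(self, systems):
        a = make_assessment(ambulatory="no", follows_commands="no")
        for system in systems.values():
            assert evaluate(system, a) == evaluate(system, a)

    @given(complete_assessments())
    def test_trace_replay_reproduces_tier(self, assessment):
        for sid in SYSTEM_IDS:
            system = get_system(sid)
            res = evaluate(system, assessment)
            assert res.trace, "trace must be non-empty for a complete assessment"
            assert replay_trace(system, res.trace) is res.tier

    @given(complete_assessments())
    def test_walker_always_delayed_outside_salt(self, assessment):
        """All systems except SALT tier a walking casualty GREEN directly."""
        walker = assessment.model_copy(update={"ambulatory": Ternary.YES})
        for sid in SYSTEM_IDS:
            if sid == "SALT":
                continue
            assert evaluate(get_system(sid), walker).tier is Tier.P3_DELAYED_GREEN

    def test_apneic_unresponsive_casualty_dead_in_every_system(self, systems):
        a = make_assessment(
            ambulatory="no",
            spontaneous_breathing="no",
            breathing_after_airway_positioning="no",
            airway_positioning_attempts=2,
            follows_commands="no",
            can_wave="no",
            purposeful_movement="no",
            respiratory_rate=0.0,
            heart_rate=0.0,
            radial_pulse_palpable="no",
            gcs=3,
        )
        for system in systems.values():
            assert evaluate(system, a).tier is Tier.PX_DEAD_BLACK

    def test_mstart_variant_prefers_radial_pulse_when_warm(self):
        a = make_assessment(
            ambulatory="no",
            cold_environment=False,
            capillary_refill_seconds=1.0,
            radial_pulse_palpable="no",
        )
        assert evaluate(get_system("START_mSTART"), a).tier is Tier.P2_URGENT_YELLOW
        mstart = get_system("START_mSTART", always_radial_pulse=True)
        assert evaluate(mstart, a).tier is Tier.P1_IMMEDIATE_RED

    def test_orange_flag_marks_secondary_eligibility_only(self):
        a = make_assessment(ambulatory="no")
        default = evaluate(get_system("FDNY_START"), a)
        assert default.flags == []
        flagged = evaluate(get_system("FDNY_START", enable_orange=True), a)
        assert flagged.tier is default.tier  # never re-tiered at primary triage
        assert "ORANGE_ELIGIBLE" in flagged.flags

    def test_safer_branch_imputation_avoids_under_triage(self, systems):
        a = Assessment(ambulatory="no")  # everything else unobserved
        res = evaluate(systems["START_mSTART"], a, impute_safer=True)
        assert res.tier is Tier.P1_IMMEDIATE_RED
        assert "IMPUTED" in res.flags


class TestEnumeration:
    def test_cartesian_count(self):
        grids = {
            "ambulatory": ["yes", "no"],
            "follows_commands": ["yes", "no"],
            "gcs": [3, 14, 15],
        }
        assert len(list(enumerate_assessment_space(grids))) == 12

    def test_single_point_grids(self):
        out = list(enumerate_assessment_space({"ambulatory": ["no"]}))
        assert len(out) == 1

    def test_empty_grid_rejected(self):
        with pytest.raises(ConfigurationError):
            enumerate_assessment_space({})
        with pytest.raises(ConfigurationError):
            list(enumerate_assessment_space({"ambulatory": []}))

    def test_unknown_field_rejected(self):
        with pytest.raises(ConfigurationError):
            list(enumerate_assessment_space({"blood_type": ["A"]}))

    def test_default_grids_exercise_every_predicate_both_ways(self, systems):
        """Brute force: every node of every system answers yes and no somewhere."""
        for system in systems.values():
            answers = {nid: set() for nid in system.node_map}
            for a in enumerate_assessment_space(system_grids(system)):
                for nid, ans in evaluate(system, a).trace:
                    answers[nid].add(ans)
            for nid, seen in answers.items():
                assert seen == {"yes", "no"}, f"{system.id}.{nid} only answered {seen}"


class TestGlobalSorting:
    def test_still_wave_walk_order(self):
        walk = make_assessment(ambulatory="yes")
        wave = make_assessment(ambulatory="no", can_wave="yes")
        still = make_assessment(ambulatory="no", can_wave="no", purposeful_movement="no")
        order = salt_global_sort([walk, wave, still])
        assert order == [2, 1, 0]

    def test_stable_within_group(self):
        still = make_assessment(ambulatory="no", can_wave="no", purposeful_movement="no")
        assert salt_global_sort([still, still, still]) == [0, 1, 2]


@pytest.mark.parametrize("system_id", SYSTEM_IDS)
def test_truth_table_equivalence(system_id, systems):
    """Tree evaluation equals the independent flat-conditional oracle."""
    system = systems[system_id]
    oracle = SYSTEM_ORACLES[system_id]
    n = 0
    for a in enumerate_assessment_space(system_grids(system)):
        assert evaluate(system, a).tier is oracle(a), a
        n += 1
    assert n > 0
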