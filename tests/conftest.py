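import hypothesis.strategies as st
import pytest
from hypothesis import settings

from triagekit.model import Assessment
from triagekit.synthesis import build_variant, derive_majority, tally_shipped
from triagekit.systems import load_all_systems

settings.register_profile("suite", deadline=None, derandomize=True, max_examples=60)
settings.load_profile("suite")


COMPLETE_DEFAULTS = dict(
    ambulatory="yes",
    spontaneous_breathing="yes",
    breathing_after_airway_positioning="no",
    airway_positioning_attempts=0,
    respiratory_rate=16.0,
    respiratory_distress="no",
    radial_pulse_palpable="yes",
    capillary_refill_seconds=1.0,
    heart_rate=80.0,
    follows_commands="yes",
    purposeful_movement="yes",
    gcs=15,
    major_external_hemorrhage="no",
    hemorrhage_controlled_after_intervention="no",
    obvious_death_signs="no",
    cold_environment=False,
    survivable_given_resources="yes",
    can_wave="yes",
    minor_injuries_only="yes",
)


def make_assessment(**overrides) -> Assessment:
    """A fully observed casualty, benign unless overridden."""
    record = dict(COMPLETE_DEFAULTS)
    record.update(overrides)
    return Assessment(**record)


@pytest.fixture(scope="session")
def systems():
    return load_all_systems()


@pytest.fixture(scope="session")
def tally():
    return tally_shipped()


@pytest.fixture(scope="session")
def majority(tally):
    return derive_majority(tally)


@pytest.fixture(scope="session")
def modified(majority):
    return build_variant(majority, "modified")


@pytest.fixture(scope="session")
def cbrn(majority):
    return build_variant(majority, "cbrn")


_tern = st.sampled_from(["yes", "no"])
_rr = st.sampled_from([0.0, 5.0, 9.0, 10.0, 11.0, 12.0, 16.0, 21.0, 22.0, 29.0, 30.0, 31.0, 40.0])
_hr = st.sampled_from([0.0, 60.0, 99.0, 100.0, 110.0, 120.0, 121.0, 140.0])
_cr = st.sampled_from([0.5, 1.0, 2.0, 2.1, 4.0])
_gcs = st.sampled_from([3, 8, 13, 14, 15])


@st.composite
def complete_assessments(draw):
    """Fully observed assessments spanning every shipped threshold."""
    spont = draw(_tern)
    after = "no" if spont == "yes" else draw(_tern)
    attempts = 0 if spont == "yes" else (2 if after == "no" else draw(st.integers(1, 2)))
    return Assessment(
        ambulatory=draw(_tern),
        spontaneous_breathing=spont,
        breathing_after_airway_positioning=after,
        airway_positioning_attempts=attempts,
        respiratory_rate=draw(_rr),
        respiratory_distress=draw(_tern),
        radial_pulse_palpable=draw(_tern),
        capillary_refill_seconds=draw(_cr),
        heart_rate=draw(_hr),
        follows_commands=draw(_tern),
        purposeful_movement=draw(_tern),
        gcs=draw(_gcs),
        major_external_hemorrhage=draw(_tern),
        hemorrhage_controlled_after_intervention=draw(_tern),
        obvious_death_signs=draw(_tern),
        cold_environment=draw(st.booleans()),
        survivable_given_resources=draw(_tern),
        can_wave=draw(_tern),
        minor_injuries_only=draw(_tern),
    )


@st.composite
def partial_assessments(draw):
    """Assessments where any finding may be unobserved."""
    tern3 = st.sampled_from(["yes", "no", "unknown"])
    spont = draw(tern3)
    after = draw(tern3)
    if spont != "no" and after == "yes":
        after = "unknown"
    return Assessment(
        ambulatory=draw(tern3),
        spontaneous_breathing=spont,
        breathing_after_airway_positioning=after,
        airway_positioning_attempts=0,
        respiratory_rate=draw(st.none() | _rr),
        respiratory_distress=draw(tern3),
        radial_pulse_palpable=draw(tern3),
        capillary_refill_seconds=draw(st.none() | _cr),
        heart_rate=draw(st.none() | _hr),
        follows_commands=draw(tern3),
        purposeful_movement=draw(tern3),
        gcs=draw(st.none() | _gcs),
        major_external_hemorrhage=draw(tern3),
        hemorrhage_controlled_after_intervention=draw(tern3),
        obvious_death_signs=draw(tern3),
        cold_environment=draw(st.booleans()),
        survivable_given_resources=draw(tern3),
        can_wave=draw(tern3),
        minor_injuries_only=draw(tern3),
    )
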