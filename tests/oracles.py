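"""Independent flat-conditional (truth-table) implementations of every
encoded system and consensus variant.

Deliberately written without trees, node ids, or any engine machinery so
they can serve as an independent oracle for the declarative rule files.
Inputs are complete assessments.
"""

from triagekit.model import Assessment, Tier, Ternary

YES, NO = Ternary.YES, Ternary.NO
GREEN = Tier.P3_DELAYED_GREEN
YELLOW = Tier.P2_URGENT_YELLOW
RED = Tier.P1_IMMEDIATE_RED
BLACK = Tier.PX_DEAD_BLACK
GRAY = Tier.GRAY_EXPECTANT


def oracle_start(a: Assessment, always_radial: bool = False) -> Tier:
    if a.ambulatory is YES:
        return GREEN
    if a.spontaneous_breathing is NO:
        return RED if a.breathing_after_airway_positioning is YES else BLACK
    if a.respiratory_rate > 30:
        return RED
    if always_radial or a.cold_environment:
        if a.radial_pulse_palpable is NO:
            return RED
    elif a.capillary_refill_seconds > 2:
        return RED
    if a.follows_commands is NO:
        return RED
    return YELLOW


def oracle_fdny(a: Assessment) -> Tier:
    if a.ambulatory is YES:
        return GREEN
    if a.obvious_death_signs is YES:
        return BLACK
    if a.spontaneous_breathing is NO:
        return RED if a.breathing_after_airway_positioning is YES else BLACK
    if a.respiratory_rate < 10 or a.respiratory_rate > 30:
        return RED
    if a.radial_pulse_palpable is NO:
        return RED
    if a.follows_commands is NO:
        return RED
    return YELLOW


def oracle_mptt(a: Assessment) -> Tier:
    if a.ambulatory is YES:
        return GREEN
    if a.spontaneous_breathing is NO:
        return BLACK
    if a.respiratory_rate < 12 or a.respiratory_rate > 21:
        return RED
    if a.heart_rate >= 100:
        return RED
    if a.gcs < 14:
        return RED
    return YELLOW


def oracle_asav(a: Assessment) -> Tier:
    if a.ambulatory is YES:
        return GREEN
    if a.spontaneous_breathing is NO:
        return BLACK
    if a.respiratory_distress is YES:
        return RED
    if (
        a.major_external_hemorrhage is YES
        and a.hemorrhage_controlled_after_intervention is NO
    ):
        return RED
    if a.radial_pulse_palpable is NO:
        return RED
    if a.follows_commands is NO:
        return RED
    return YELLOW


def oracle_salt(a: Assessment) -> Tier:
    if a.spontaneous_breathing is NO and a.breathing_after_airway_positioning is NO:
        return BLACK
    immediate = (
        (
            a.major_external_hemorrhage is YES
            and a.hemorrhage_controlled_after_intervention is NO
        )
        or (a.follows_commands is NO and a.purposeful_movement is NO)
        or a.radial_pulse_palpable is NO
        or a.respiratory_distress is YES
    )
    if immediate:
        return RED if a.survivable_given_resources is YES else GRAY
    return GREEN if a.minor_injuries_only is YES else YELLOW


def oracle_cft(a: Assessment) -> Tier:
    if a.ambulatory is YES:
        return GREEN
    if a.follows_commands is YES:
        return RED if a.radial_pulse_palpable is NO else YELLOW
    if a.spontaneous_breathing is YES:
        return RED
    return BLACK


def oracle_ts(a: Assessment) -> Tier:
    if a.ambulatory is YES:
        return GREEN
    if a.obvious_death_signs is YES:
        return BLACK
    if a.spontaneous_breathing is NO:
        return BLACK
    if a.respiratory_rate < 10 or a.respiratory_rate > 29:
        return RED
    if a.cold_environment:
        if a.heart_rate > 120:
            return RED
    elif a.capillary_refill_seconds > 2:
        return RED
    return YELLOW


def oracle_consensus_majority(a: Assessment) -> Tier:
    if a.ambulatory is YES:
        return GREEN
    if a.spontaneous_breathing is NO:
        return BLACK
    if a.respiratory_rate < 10 or a.respiratory_rate > 30:
        return RED
    if a.radial_pulse_palpable is NO:
        return RED
    if a.follows_commands is NO:
        return RED
    return YELLOW


def oracle_consensus_modified(a: Assessment) -> Tier:
    if a.ambulatory is YES:
        return GREEN
    if a.spontaneous_breathing is NO:
        return RED if a.breathing_after_airway_positioning is YES else BLACK
    if a.respiratory_distress is YES:
        return RED
    if a.major_external_hemorrhage is YES:
        return RED
    if a.radial_pulse_palpable is NO:
        return RED
    if a.follows_commands is NO:
        return RED
    return YELLOW


def oracle_consensus_cbrn(a: Assessment) -> Tier:
    if a.ambulatory is YES:
        return GREEN
    if a.spontaneous_breathing is NO:
        return RED if a.breathing_after_airway_positioning is YES else BLACK
    if a.respiratory_distress is YES:
        return RED
    if a.major_external_hemorrhage is YES:
        return RED
    if a.follows_commands is NO:
        return RED
    return YELLOW


SYSTEM_ORACLES = {
    "START_mSTART": oracle_start,
    "FDNY_START": oracle_fdny,
    "MPTT": oracle_mptt,
    "ASAV": oracle_asav,
    "SALT": oracle_salt,
    "CFT": oracle_cft,
    "TS": oracle_ts,
}

VARIANT_ORACLES = {
    "majority": oracle_consensus_majority,
    "modified": oracle_consensus_modified,
    "cbrn": oracle_consensus_cbrn,
}
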