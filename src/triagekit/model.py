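"""Shared vocabulary: triage tiers, casualty assessment records, results.

The assessment record holds every observable finding interrogated by at
least one of the encoded triage systems.  Ternary fields distinguish an
explicit negative from an observation that was never made (``unknown``),
which matters for partial field assessments.
"""

from __future__ import annotations

import enum
from typing import Optional

from pydantic import BaseModel, ConfigDict, Field, model_validator

from .errors import IdentifierError


class Tier(str, enum.Enum):
    """Triage priority tiers.

    The four core tiers (P3/P2/P1/PX) are common to all encoded systems.
    ORANGE_EXTENDED exists only in FDNY-START (secondary deterioration-risk
    assessment) and GRAY_EXPECTANT only in SALT (immediate casualties judged
    unsurvivable with current resources).
    """

    P3_DELAYED_GREEN = "P3_DELAYED_GREEN"
    P2_URGENT_YELLOW = "P2_URGENT_YELLOW"
    P1_IMMEDIATE_RED = "P1_IMMEDIATE_RED"
    PX_DEAD_BLACK = "PX_DEAD_BLACK"
    ORANGE_EXTENDED = "ORANGE_EXTENDED"
    GRAY_EXPECTANT = "GRAY_EXPECTANT"

    @property
    def severity_rank(self) -> Optional[int]:
        """Strict total order on the three treatable tiers (P3 < P2 < P1).

        PX and the extended tiers have no rank: over-/under-triage of a dead
        or expectant casualty is not a defined quantity, so misclassification
        involving them is reported in separate confusion-matrix cells instead.
        """
        return _SEVERITY_RANK.get(self)


_SEVERITY_RANK = {
    Tier.P3_DELAYED_GREEN: 1,
    Tier.P2_URGENT_YELLOW: 2,
    Tier.P1_IMMEDIATE_RED: 3,
}

CORE_TIERS = (
    Tier.P3_DELAYED_GREEN,
    Tier.P2_URGENT_YELLOW,
    Tier.P1_IMMEDIATE_RED,
    Tier.PX_DEAD_BLACK,
)


class Ternary(str, enum.Enum):
    """Three-valued answer to a bedside question: yes / no / unknown."""

    YES = "yes"
    NO = "no"
    UNKNOWN = "unknown"

    def __bool__(self) -> bool:  # guard against accidental truthiness
        raise TypeError("Ternary values must be compared explicitly")

    @classmethod
    def from_bool(cls, value: Optional[bool]) -> "Ternary":
        if value is None:
            return cls.UNKNOWN
        return cls.YES if value else cls.NO


YES, NO, UNKNOWN = Ternary.YES, Ternary.NO, Ternary.UNKNOWN


class Assessment(BaseModel):
    """One casualty's observable findings at primary triage.

    All ternary fields default to ``unknown`` and numeric vitals to missing,
    so a partially assessed casualty is representable; whether that is
    acceptable depends on which system tree is evaluated
    (see :func:`completeness_check`).
    """

    model_config = ConfigDict(validate_assignment=True, extra="forbid")

    ambulatory: Ternary = UNKNOWN
    spontaneous_breathing: Ternary = UNKNOWN
    breathing_after_airway_positioning: Ternary = UNKNOWN
    airway_positioning_attempts: int = Field(default=0, ge=0, le=2)
    respiratory_rate: Optional[float] = Field(default=None, ge=0)
    respiratory_distress: Ternary = UNKNOWN
    radial_pulse_palpable: Ternary = UNKNOWN
    capillary_refill_seconds: Optional[float] = Field(default=None, ge=0)
    heart_rate: Optional[float] = Field(default=None, ge=0)
    follows_commands: Ternary = UNKNOWN
    purposeful_movement: Ternary = UNKNOWN
    gcs: Optional[int] = Field(default=None, ge=3, le=15)
    major_external_hemorrhage: Ternary = UNKNOWN
    hemorrhage_controlled_after_intervention: Ternary = UNKNOWN
    obvious_death_signs: Ternary = UNKNOWN
    cold_environment: bool = False
    survivable_given_resources: Ternary = UNKNOWN
    can_wave: Ternary = UNKNOWN
    minor_injuries_only: Ternary = UNKNOWN

    @model_validator(mode="after")
    def _airway_consistency(self) -> "Assessment":
        if (
            self.breathing_after_airway_positioning is YES
            and self.spontaneous_breathing is not NO
        ):
            raise ValueError(
                "breathing_after_airway_positioning may be 'yes' only when "
                "spontaneous_breathing is 'no'"
            )
        if self.airway_positioning_attempts > 0 and self.spontaneous_breathing is not NO:
            raise ValueError(
                "airway_positioning_attempts > 0 requires spontaneous_breathing 'no'"
            )
        return self

    def to_record(self) -> dict:
        """Flat dict of primitives (round-trips through CSV/JSON)."""
        out = {}
        for name in FIELD_ORDER:
            value = getattr(self, name)
            out[name] = value.value if isinstance(value, Ternary) else value
        return out

    @classmethod
    def from_record(cls, record: dict) -> "Assessment":
        return cls(**record)


FIELD_ORDER = tuple(Assessment.model_fields)

TERNARY_FIELDS = tuple(
    name
    for name, f in Assessment.model_fields.items()
    if f.annotation is Ternary
)


class LSIKind(str, enum.Enum):
    """Lifesaving interventions appearing in the analyzed systems."""

    AIRWAY_POSITIONING = "airway_positioning"
    AIRWAY_OPENING = "airway_opening"
    HEMORRHAGE_CONTROL = "hemorrhage_control"
    CHEST_DECOMPRESSION = "chest_decompression"
    ANTIDOTE_AUTOINJECTOR = "antidote_autoinjector"


class Training(str, enum.Enum):
    LAYPERSON = "layperson"
    MEDICAL = "medical"
    ADVANCED = "advanced"


TRAINING_ORDER = {Training.LAYPERSON: 0, Training.MEDICAL: 1, Training.ADVANCED: 2}

# Minimum rescuer training per intervention.  Positioning an airway or
# applying pressure/tourniquet are feasible for lay rescuers; judging an
# opened airway or indicating antidotes needs medical training; field chest
# decompression is an advanced skill.
DEFAULT_LSI_TRAINING = {
    LSIKind.AIRWAY_POSITIONING: Training.LAYPERSON,
    LSIKind.HEMORRHAGE_CONTROL: Training.LAYPERSON,
    LSIKind.AIRWAY_OPENING: Training.MEDICAL,
    LSIKind.ANTIDOTE_AUTOINJECTOR: Training.MEDICAL,
    LSIKind.CHEST_DECOMPRESSION: Training.ADVANCED,
}


class LSIAction(BaseModel):
    model_config = ConfigDict(frozen=True)

    kind: LSIKind
    requires_training: Training = None  # type: ignore[assignment]

    @model_validator(mode="before")
    @classmethod
    def _default_training(cls, data):
        if isinstance(data, dict) and data.get("requires_training") is None:
            kind = LSIKind(data["kind"])
            data = {**data, "requires_training": DEFAULT_LSI_TRAINING[kind]}
        return data


class TriageResult(BaseModel):
    """Outcome of evaluating one casualty under one system.

    ``trace`` is the ordered list of (criterion id, answer) pairs actually
    interrogated; replaying it through the system's tree reproduces ``tier``.
    """

    tier: Tier
    trace: list[tuple[str, str]]
    lsis_recommended: list[LSIAction] = []
    flags: list[str] = []


def completeness_check(assessment: Assessment, system_id: str) -> list[str]:
    """Fields the named system's tree may interrogate that are unknown.

    Explores the tree following known answers and *both* branches of any
    node whose field is unknown; an empty result guarantees that evaluation
    of this assessment cannot hit a missing-field error.
    """
    from . import systems as _systems  # deferred: systems imports this module

    try:
        system = _systems.get_system(system_id)
    except KeyError:
        raise IdentifierError(f"unknown system id '{system_id}'") from None
    return _systems.missing_fields(system, assessment)
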