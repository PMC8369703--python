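"""Criteria meta-synthesis: canonical tally in sevenths, majority rule,
full-coverage respiratory-rate band, and assembly of the translational
consensus specification.

The rephrasing/merging of per-system predicates into canonical criteria was
a human content-analysis step; it ships as a reviewed data file
(``data/canonical_map.yaml``) rather than being inferred algorithmically.
"""

from __future__ import annotations

import functools
from dataclasses import dataclass, field, replace
from fractions import Fraction
from importlib import resources
from typing import Iterable, Optional, Sequence, Union

import pandas as pd
import yaml

from .errors import CoverageError, DomainError, UsageError
from .model import LSIAction, LSIKind, Tier
from .systems import TriageSystemDefinition, load_all_systems, load_system

TOTAL_SYSTEMS = 7
MAJORITY_THRESHOLD = Fraction(4, 7)


# ---------------------------------------------------------------------------
# Tally types


@dataclass(frozen=True)
class Modifier:
    """A sub-criterion with its own member set (e.g. 'after 1-2 attempts')."""

    id: str
    phrase: str
    member_systems: frozenset[str]

    @property
    def fraction(self) -> Fraction:
        return Fraction(len(self.member_systems), TOTAL_SYSTEMS)


@dataclass(frozen=True)
class CanonicalCriterion:
    """A merged criterion with tier assignment and contributing systems."""

    id: str
    tier: Tier
    phrase: str
    member_systems: frozenset[str]
    modifiers: tuple[Modifier, ...] = ()
    provisional: bool = False
    rr_bands: tuple["RRBand", ...] = ()

    @property
    def fraction(self) -> Fraction:
        return Fraction(len(self.member_systems), TOTAL_SYSTEMS)


@dataclass(frozen=True)
class RRBand:
    """Inclusive normal respiratory-rate band; abnormal outside it.

    ``normal_min`` may be absent (no lower limit, non-constraining).
    """

    normal_max: float
    normal_min: Optional[float] = None

    def __post_init__(self):
        if self.normal_min is not None and self.normal_min > self.normal_max:
            raise DomainError(
                f"normal_min {self.normal_min} exceeds normal_max {self.normal_max}"
            )

    def contains(self, rate: float) -> bool:
        if self.normal_min is not None and rate < self.normal_min:
            return False
        return rate <= self.normal_max


# ---------------------------------------------------------------------------
# Canonical map


@functools.lru_cache(maxsize=None)
def load_canonical_map() -> dict:
    text = (resources.files("triagekit") / "data" / "canonical_map.yaml").read_text()
    return yaml.safe_load(text)


def extract_rr_band(system: TriageSystemDefinition) -> Optional[RRBand]:
    """The system's respiratory-rate band, read from its rr predicate."""
    for node in system.nodes:
        if node.predicate.name == "rr_outside":
            params = node.predicate.params()
            return RRBand(
                normal_max=params["normal_max"], normal_min=params.get("normal_min")
            )
    return None


def tally_criteria(
    systems: Iterable[TriageSystemDefinition],
    canonical_map: Optional[dict] = None,
) -> list[CanonicalCriterion]:
    """Count each canonical criterion's member systems in sevenths.

    Every decision node of every provided system (core four tiers) must be
    covered by the map; an unmapped node raises :class:`CoverageError`
    naming the system and node.  ORANGE/GRAY tier criteria are not part of
    the map, matching their exclusion from the compilation.
    """
    canonical_map = canonical_map or load_canonical_map()
    provided = {s.id: s for s in systems}

    mapped: dict[str, set[str]] = {sid: set() for sid in provided}

    def note(member: dict) -> Optional[str]:
        sid, nid = member["system"], member["node"]
        if sid not in provided:
            return None
        if nid not in provided[sid].node_map:
            raise CoverageError(
                f"canonical map references missing node '{nid}' of system '{sid}'"
            )
        mapped[sid].add(nid)
        return sid

    out: list[CanonicalCriterion] = []
    for entry in canonical_map["criteria"]:
        members = frozenset(
            sid for m in entry["members"] if (sid := note(m)) is not None
        )
        modifiers = tuple(
            Modifier(
                id=mod["id"],
                phrase=mod["phrase"],
                member_systems=frozenset(
                    sid for m in mod["members"] if (sid := note(m)) is not None
                ),
            )
            for mod in entry.get("modifiers", ())
        )
        rr_bands: tuple[RRBand, ...] = ()
        if entry["id"] == "p1_rr":
            rr_bands = tuple(
                band
                for sid in sorted(members)
                if (band := extract_rr_band(provided[sid])) is not None
            )
        out.append(
            CanonicalCriterion(
                id=entry["id"],
                tier=Tier(entry["tier"]),
                phrase=entry["phrase"],
                member_systems=members,
                modifiers=modifiers,
                provisional=bool(entry.get("provisional", False)),
                rr_bands=rr_bands,
            )
        )

    for item in canonical_map.get("structural", ()):
        note(item)

    for sid, system in provided.items():
        unmapped = set(system.node_map) - mapped[sid]
        if unmapped:
            raise CoverageError(
                f"predicate not covered by canonical map: system '{sid}', "
                f"node(s) {sorted(unmapped)}"
            )
    return out


def tally_shipped() -> list[CanonicalCriterion]:
    """Tally over the seven shipped fixtures."""
    return tally_criteria(load_all_systems().values())


def tally_to_frame(tally: Sequence[CanonicalCriterion]) -> pd.DataFrame:
    """Tabular tally report (criterion, tier, phrase, systems, fraction)."""
    rows = []
    for c in tally:
        rows.append(
            {
                "criterion": c.id,
                "tier": c.tier.value,
                "phrase": c.phrase,
                "systems": ";".join(sorted(c.member_systems)),
                "fraction": f"{len(c.member_systems)}/{TOTAL_SYSTEMS}",
            }
        )
        for m in c.modifiers:
            rows.append(
                {
                    "criterion": f"{c.id}.{m.id}",
                    "tier": c.tier.value,
                    "phrase": m.phrase,
                    "systems": ";".join(sorted(m.member_systems)),
                    "fraction": f"{len(m.member_systems)}/{TOTAL_SYSTEMS}",
                }
            )
    return pd.DataFrame(rows, columns=["criterion", "tier", "phrase", "systems", "fraction"])


# ---------------------------------------------------------------------------
# Respiratory-rate full-coverage rule


def derive_rr_band(per_system_bands: Sequence[RRBand]) -> RRBand:
    """The one interval covering the whole spectrum of per-system limits.

    Lower bound: minimum of the finite lower normal bounds (absent bounds
    are non-constraining); upper bound: maximum of the upper bounds.
    Idempotent and order-independent.
    """
    bands = list(per_system_bands)
    if not bands:
        raise DomainError("derive_rr_band requires at least one band")
    mins = [b.normal_min for b in bands if b.normal_min is not None]
    return RRBand(
        normal_max=max(b.normal_max for b in bands),
        normal_min=min(mins) if mins else None,
    )


# ---------------------------------------------------------------------------
# Consensus specification

# Fixed presentation order: airway -> breathing -> circulation -> disability
# within each tier, following the published derivation-table row order.
_CRITERION_ORDER = (
    "p3_ambulatory",
    "p3_minor_injuries_only",
    "px_non_ambulatory",
    "px_not_breathing",
    "px_no_pulse",
    "px_obvious_death",
    "px_commands_unable",
    "p1_non_ambulatory",
    "p1_breathing_open_airway",
    "p1_respiratory_distress",
    "p1_rr",
    "p1_major_external_hemorrhage",  # variant-inserted, never tallied
    "p1_hemorrhage_persistent",
    "p1_radial_pulse_absent",
    "p1_hr",
    "p1_cap_refill",
    "p1_commands_unable",
    "p1_survivable",
    "p1_not_deadly_injured",
    "p2_non_ambulatory_rephrase",
    "p2_not_fulfilling_px_p1",
    "p2_more_than_minor",
)

VARIANTS = ("majority", "modified", "cbrn")

_ALL_LSI_KINDS = (
    LSIKind.AIRWAY_POSITIONING,
    LSIKind.AIRWAY_OPENING,
    LSIKind.HEMORRHAGE_CONTROL,
    LSIKind.CHEST_DECOMPRESSION,
    LSIKind.ANTIDOTE_AUTOINJECTOR,
)


@dataclass(frozen=True)
class LSIPolicy:
    action: LSIAction
    enabled: bool


@dataclass(frozen=True)
class ConsensusSpecification:
    """A derived translational triage algorithm variant.

    ``criteria`` holds, per tier, the ordered canonical criterion ids the
    variant interrogates; ``rr_band`` is the full-coverage normal band used
    by the majority variant's rate check.
    """

    threshold: Fraction
    variant: str
    criteria: dict[Tier, tuple[str, ...]]
    rr_band: Optional[RRBand]
    lsi_policy: tuple[LSIPolicy, ...]
    allow_airway_attempts: bool = False
    max_airway_attempts: int = 2

    def enabled_lsis(self) -> dict[LSIKind, LSIAction]:
        return {p.action.kind: p.action for p in self.lsi_policy if p.enabled}

    def p1_criteria(self) -> tuple[str, ...]:
        return self.criteria.get(Tier.P1_IMMEDIATE_RED, ())


def _ordered(ids: Iterable[str]) -> tuple[str, ...]:
    return tuple(sorted(ids, key=_CRITERION_ORDER.index))


def derive_majority(
    tally: Sequence[CanonicalCriterion],
    threshold: Union[Fraction, float, str] = MAJORITY_THRESHOLD,
) -> ConsensusSpecification:
    """Combine the criteria of majority (fraction >= threshold) per tier."""
    if isinstance(threshold, str):
        threshold = Fraction(threshold)
    threshold = Fraction(threshold).limit_denominator(10**6)
    if not 0 < threshold <= 1:
        raise DomainError(f"threshold {threshold} outside (0, 1]")

    selected = [c for c in tally if c.fraction >= threshold]
    criteria: dict[Tier, tuple[str, ...]] = {}
    for tier in Tier:
        ids = [c.id for c in selected if c.tier is tier]
        if ids:
            criteria[tier] = _ordered(ids)

    rr_criterion = next((c for c in tally if c.id == "p1_rr"), None)
    rr_band = (
        derive_rr_band(rr_criterion.rr_bands)
        if rr_criterion is not None and rr_criterion.rr_bands
        else None
    )
    policy = tuple(
        LSIPolicy(action=LSIAction(kind=kind), enabled=False) for kind in _ALL_LSI_KINDS
    )
    return ConsensusSpecification(
        threshold=threshold,
        variant="majority",
        criteria=criteria,
        rr_band=rr_band,
        lsi_policy=policy,
    )


def build_variant(base: ConsensusSpecification, variant: str) -> ConsensusSpecification:
    """Derive the discussion-modified or CBRN variant from the majority base.

    modified: the rate-counting criterion is replaced by a binary
    respiratory-distress question; a major-external-bleeding question with a
    hemorrhage-control intervention precedes the pulse check; 1-2 airway
    positioning attempts are allowed before the dead tier; the antidote
    autoinjector is enabled.  cbrn: additionally drops radial-pulse
    palpation (infeasible in protective gear).
    """
    if variant not in ("modified", "cbrn"):
        raise UsageError(f"unknown variant '{variant}'")
    if base.variant != "majority":
        raise UsageError(
            f"variants derive from the majority specification, not '{base.variant}'"
        )

    p1 = list(base.p1_criteria())

    def swap(old: str, new: str) -> None:
        if old in p1:
            p1[p1.index(old)] = new

    swap("p1_rr", "p1_respiratory_distress")
    if "p1_radial_pulse_absent" in p1:
        p1.insert(p1.index("p1_radial_pulse_absent"), "p1_major_external_hemorrhage")
    else:
        p1.append("p1_major_external_hemorrhage")
    if variant == "cbrn" and "p1_radial_pulse_absent" in p1:
        p1.remove("p1_radial_pulse_absent")

    criteria = dict(base.criteria)
    criteria[Tier.P1_IMMEDIATE_RED] = _ordered(p1)

    enabled_kinds = {
        LSIKind.AIRWAY_POSITIONING,
        LSIKind.HEMORRHAGE_CONTROL,
        LSIKind.ANTIDOTE_AUTOINJECTOR,
    }
    policy = tuple(
        LSIPolicy(action=LSIAction(kind=kind), enabled=kind in enabled_kinds)
        for kind in _ALL_LSI_KINDS
    )
    return replace(
        base,
        variant=variant,
        criteria=criteria,
        lsi_policy=policy,
        allow_airway_attempts=True,
    )


# ---------------------------------------------------------------------------
# Consensus -> rule file (the derived tool is just another system)


def consensus_to_system(spec: ConsensusSpecification) -> TriageSystemDefinition:
    """Compile a consensus specification into the generic tree schema."""
    enabled = spec.enabled_lsis()
    core = [t.value for t in (Tier.P3_DELAYED_GREEN, Tier.P2_URGENT_YELLOW, Tier.P1_IMMEDIATE_RED, Tier.PX_DEAD_BLACK)]
    red = {"tier": Tier.P1_IMMEDIATE_RED.value}
    nodes: list[dict] = [
        {
            "id": "walking",
            "predicate": {"name": "ask", "field": "ambulatory"},
            "on_yes": {"tier": Tier.P3_DELAYED_GREEN.value},
            "on_no": {"node": "breathing"},
        }
    ]
    if spec.allow_airway_attempts:
        not_breathing = {"node": "airway_response"}
        airway = {
            "id": "airway_response",
            "predicate": {"name": "ask", "field": "breathing_after_airway_positioning"},
            "max_attempts": spec.max_airway_attempts,
            "on_yes": dict(red),
            "on_no": {"tier": Tier.PX_DEAD_BLACK.value},
        }
        if LSIKind.AIRWAY_POSITIONING in enabled:
            airway["lsi_before"] = [{"kind": LSIKind.AIRWAY_POSITIONING.value}]
    else:
        not_breathing = {"tier": Tier.PX_DEAD_BLACK.value}
        airway = None

    p1 = spec.p1_criteria()
    chain: list[dict] = []
    if "p1_rr" in p1:
        if spec.rr_band is None:
            raise UsageError("majority specification lacks a derived rr band")
        params: dict = {"normal_max": spec.rr_band.normal_max}
        if spec.rr_band.normal_min is not None:
            params["normal_min"] = spec.rr_band.normal_min
        chain.append(
            {
                "id": "resp_rate",
                "predicate": {"name": "rr_outside", **params},
                "on_yes": dict(red),
            }
        )
    if "p1_respiratory_distress" in p1:
        chain.append(
            {
                "id": "resp_distress",
                "predicate": {"name": "ask", "field": "respiratory_distress"},
                "on_yes": dict(red),
            }
        )
    if "p1_major_external_hemorrhage" in p1:
        on_yes = dict(red)
        if LSIKind.HEMORRHAGE_CONTROL in enabled:
            on_yes["lsi"] = [{"kind": LSIKind.HEMORRHAGE_CONTROL.value}]
        chain.append(
            {
                "id": "major_hemorrhage",
                "predicate": {"name": "ask", "field": "major_external_hemorrhage"},
                "on_yes": on_yes,
            }
        )
    if "p1_radial_pulse_absent" in p1:
        chain.append(
            {
                "id": "radial_pulse",
                "predicate": {"name": "ask", "field": "radial_pulse_palpable"},
                "invert": True,  # pass is YES; marker replaced below
            }
        )
    if "p1_commands_unable" in p1:
        chain.append(
            {
                "id": "commands",
                "predicate": {"name": "ask", "field": "follows_commands"},
                "invert": True,
            }
        )

    # wire the chain: each check falls through to the next, last one ends P2
    for i, node in enumerate(chain):
        nxt = (
            {"node": chain[i + 1]["id"]}
            if i + 1 < len(chain)
            else {"tier": Tier.P2_URGENT_YELLOW.value}
        )
        if node.pop("invert", False):
            node["on_yes"] = nxt
            node["on_no"] = dict(red)
        else:
            node["on_no"] = nxt
    first_check = {"node": chain[0]["id"]} if chain else {"tier": Tier.P2_URGENT_YELLOW.value}

    nodes.append(
        {
            "id": "breathing",
            "predicate": {"name": "ask", "field": "spontaneous_breathing"},
            "on_yes": first_check,
            "on_no": not_breathing,
        }
    )
    if airway is not None:
        nodes.append(airway)
    nodes.extend(chain)

    definition = {
        "id": f"CONSENSUS_{spec.variant.upper()}",
        "name": f"Translational consensus triage ({spec.variant} variant)",
        "tiers": core,
        "global_sorting": False,
        "options": {},
        "root": "walking",
        "nodes": nodes,
    }
    return load_system(definition)
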