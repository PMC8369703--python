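"""Declarative decision-tree engine and the seven shipped triage systems.

Each system is a rule file (YAML) of binary decision nodes whose predicates
are named tests with thresholds as data, terminating in triage tiers.  The
engine is generic: the derived consensus specifications serialize to the
same schema and run on the same code path.
"""

from __future__ import annotations

import functools
import hashlib
import itertools
from importlib import resources
from pathlib import Path
from typing import Iterable, Iterator, Optional, Union

import yaml
from pydantic import BaseModel, ConfigDict, ValidationError, model_validator

from .errors import (
    ConfigurationError,
    MissingFieldError,
    SchemaError,
    StructuralError,
)
from .model import (
    NO,
    UNKNOWN,
    YES,
    Assessment,
    LSIAction,
    Ternary,
    Tier,
    TriageResult,
)

SYSTEM_IDS = ("START_mSTART", "FDNY_START", "MPTT", "ASAV", "SALT", "CFT", "TS")

# ---------------------------------------------------------------------------
# Predicates: named tests over Assessment fields, thresholds carried as data.
# Each returns True/False, or None when the interrogated field is unknown.


def _tern(value: Ternary) -> Optional[bool]:
    return None if value is UNKNOWN else value is YES


def _ask(a: Assessment, p: dict, options: dict) -> Optional[bool]:
    return _tern(getattr(a, p["field"]))


def _rr_outside(a: Assessment, p: dict, options: dict) -> Optional[bool]:
    """Abnormal iff RR < normal_min or RR > normal_max (inclusive-normal band)."""
    rr = a.respiratory_rate
    if rr is None:
        return None
    lo = p.get("normal_min")
    hi = p["normal_max"]
    return (lo is not None and rr < lo) or rr > hi


def _cap_refill_gt(a: Assessment, p: dict, options: dict) -> Optional[bool]:
    cr = a.capillary_refill_seconds
    return None if cr is None else cr > p["threshold"]


def _hr_ge(a: Assessment, p: dict, options: dict) -> Optional[bool]:
    hr = a.heart_rate
    return None if hr is None else hr >= p["threshold"]


def _hr_gt(a: Assessment, p: dict, options: dict) -> Optional[bool]:
    hr = a.heart_rate
    return None if hr is None else hr > p["threshold"]


def _gcs_lt(a: Assessment, p: dict, options: dict) -> Optional[bool]:
    g = a.gcs
    return None if g is None else g < p["threshold"]


def _cold_conditions(a: Assessment, p: dict, options: dict) -> Optional[bool]:
    # Environment switch selecting a perfusion proxy; an options flag can
    # force the cold-mode proxy (e.g. mSTART always palpates the radial pulse).
    opt = p.get("or_option")
    if opt and options.get(opt):
        return True
    return a.cold_environment


_PREDICATES = {
    "ask": (_ask, lambda p: [p["field"]]),
    "rr_outside": (_rr_outside, lambda p: ["respiratory_rate"]),
    "cap_refill_gt": (_cap_refill_gt, lambda p: ["capillary_refill_seconds"]),
    "hr_ge": (_hr_ge, lambda p: ["heart_rate"]),
    "hr_gt": (_hr_gt, lambda p: ["heart_rate"]),
    "gcs_lt": (_gcs_lt, lambda p: ["gcs"]),
    "cold_conditions": (_cold_conditions, lambda p: []),  # bool field, never unknown
}


# ---------------------------------------------------------------------------
# Rule-file schema


class Branch(BaseModel):
    model_config = ConfigDict(extra="forbid")

    node: Optional[str] = None
    tier: Optional[Tier] = None
    lsi: list[LSIAction] = []

    @model_validator(mode="after")
    def _one_target(self) -> "Branch":
        if (self.node is None) == (self.tier is None):
            raise ValueError("branch must name exactly one of 'node' or 'tier'")
        return self


class Predicate(BaseModel):
    model_config = ConfigDict(extra="allow")

    name: str

    @model_validator(mode="after")
    def _known(self) -> "Predicate":
        if self.name not in _PREDICATES:
            raise ValueError(f"unknown predicate '{self.name}'")
        return self

    def params(self) -> dict:
        return {k: v for k, v in self.model_dump().items() if k != "name"}

    def fields_read(self) -> list[str]:
        return _PREDICATES[self.name][1](self.params())

    def answer(self, assessment: Assessment, options: dict) -> Optional[bool]:
        return _PREDICATES[self.name][0](assessment, self.params(), options)


class DecisionNode(BaseModel):
    model_config = ConfigDict(extra="forbid")

    id: str
    predicate: Predicate
    on_yes: Branch
    on_no: Branch
    lsi_before: list[LSIAction] = []
    max_attempts: Optional[int] = None


class TriageSystemDefinition(BaseModel):
    model_config = ConfigDict(extra="forbid")

    id: str
    name: str
    tiers: list[Tier]
    root: str
    nodes: list[DecisionNode]
    global_sorting: bool = False
    options: dict = {}
    extra_lsi_inventory: list[LSIAction] = []

    @functools.cached_property
    def node_map(self) -> dict[str, DecisionNode]:
        return {n.id: n for n in self.nodes}

    @property
    def lsi_inventory(self) -> list[LSIAction]:
        seen: dict = {}
        for node in self.nodes:
            for lsi in node.lsi_before:
                seen[lsi.kind] = lsi
            for branch in (node.on_yes, node.on_no):
                for lsi in branch.lsi:
                    seen[lsi.kind] = lsi
        for lsi in self.extra_lsi_inventory:
            seen.setdefault(lsi.kind, lsi)
        return list(seen.values())

    def fields_used(self) -> list[str]:
        """Assessment fields the tree may interrogate, in first-use order."""
        out: list[str] = []
        for node in self.nodes:
            for f in node.predicate.fields_read():
                if f not in out:
                    out.append(f)
            if node.predicate.name == "cold_conditions":
                if "cold_environment" not in out:
                    out.append("cold_environment")
        return out


def _validate_structure(system: TriageSystemDefinition) -> None:
    nodes = system.node_map
    if len(nodes) != len(system.nodes):
        dupes = [n.id for n in system.nodes if sum(m.id == n.id for m in system.nodes) > 1]
        raise StructuralError(f"duplicate node ids in '{system.id}': {sorted(set(dupes))}")
    if system.root not in nodes:
        raise StructuralError(f"root node '{system.root}' not defined in '{system.id}'")
    tier_vocab = set(system.tiers)
    for node in system.nodes:
        for label, branch in (("on_yes", node.on_yes), ("on_no", node.on_no)):
            if branch.node is not None and branch.node not in nodes:
                raise StructuralError(
                    f"node '{node.id}' {label} references missing node "
                    f"'{branch.node}' in '{system.id}'"
                )
            if branch.tier is not None and branch.tier not in tier_vocab:
                raise StructuralError(
                    f"node '{node.id}' {label} terminates in tier "
                    f"'{branch.tier.value}' outside the vocabulary of '{system.id}'"
                )
    # cycle detection / totality: every path from root must terminate
    WHITE, GRAY, BLACK = 0, 1, 2
    color = {nid: WHITE for nid in nodes}

    def visit(nid: str, path: tuple[str, ...]) -> None:
        if color[nid] == GRAY:
            raise StructuralError(
                f"cycle detected in '{system.id}' at node '{nid}' "
                f"(path {' -> '.join(path + (nid,))})"
            )
        if color[nid] == BLACK:
            return
        color[nid] = GRAY
        node = nodes[nid]
        for branch in (node.on_yes, node.on_no):
            if branch.node is not None:
                visit(branch.node, path + (nid,))
        color[nid] = BLACK

    visit(system.root, ())


def load_system(source: Union[str, Path, dict], **option_overrides) -> TriageSystemDefinition:
    """Parse and validate a rule file (YAML text, path, or mapping).

    Keyword overrides update the system's ``options`` (e.g.
    ``always_radial_pulse=True`` for mSTART behavior, ``enable_orange=True``
    for the FDNY secondary tier flag).
    """
    if isinstance(source, dict):
        data = source
    else:
        text = Path(source).read_text() if isinstance(source, Path) else source
        if isinstance(source, str) and "\n" not in source and source.endswith(".yaml"):
            text = Path(source).read_text()
        try:
            data = yaml.safe_load(text)
        except yaml.YAMLError as exc:
            raise SchemaError(f"rule file is not valid YAML: {exc}") from exc
    if not isinstance(data, dict):
        raise SchemaError("rule file must be a mapping")
    try:
        system = TriageSystemDefinition.model_validate(data)
    except ValidationError as exc:
        first = exc.errors()[0]
        loc = ".".join(str(p) for p in first["loc"])
        raise SchemaError(f"rule file schema violation at '{loc}': {first['msg']}") from exc
    if option_overrides:
        system = system.model_copy(update={"options": {**system.options, **option_overrides}})
    _validate_structure(system)
    return system


# ---------------------------------------------------------------------------
# Shipped fixtures


def _fixture_dir():
    return resources.files("triagekit") / "systems"


@functools.lru_cache(maxsize=None)
def load_all_systems() -> dict[str, TriageSystemDefinition]:
    """The seven shipped system definitions, keyed by id."""
    out = {}
    for sid in SYSTEM_IDS:
        out[sid] = load_system((_fixture_dir() / f"{sid}.yaml").read_text())
    return out


def get_system(system_id: str, **option_overrides) -> TriageSystemDefinition:
    systems = load_all_systems()
    if system_id not in systems:
        raise KeyError(system_id)
    system = systems[system_id]
    if option_overrides:
        system = load_system(
            system.model_dump(mode="json", exclude_defaults=False), **option_overrides
        )
    return system


def fixture_checksums() -> dict[str, str]:
    """sha256 of each shipped rule file, for reproducibility logging."""
    out = {}
    for sid in SYSTEM_IDS:
        text = (_fixture_dir() / f"{sid}.yaml").read_text()
        out[sid] = hashlib.sha256(text.encode()).hexdigest()
    return out


# ---------------------------------------------------------------------------
# Evaluation


def _reachable_ranks(system: TriageSystemDefinition) -> dict[str, int]:
    """Max severity rank (P1=3 ... PX/GRAY=0) reachable from each node."""
    memo: dict[str, int] = {}

    def rank_of(branch: Branch) -> int:
        if branch.tier is not None:
            return branch.tier.severity_rank or 0
        return visit(branch.node)  # type: ignore[arg-type]

    def visit(nid: str) -> int:
        if nid not in memo:
            node = system.node_map[nid]
            memo[nid] = -1  # sentinel; trees are acyclic (validated on load)
            memo[nid] = max(rank_of(node.on_yes), rank_of(node.on_no))
        return memo[nid]

    visit(system.root)
    return memo


def evaluate(
    system: TriageSystemDefinition,
    assessment: Assessment,
    impute_safer: bool = False,
) -> TriageResult:
    """Walk the system's tree over one casualty.

    An unknown field raises :class:`MissingFieldError` unless
    ``impute_safer`` is set, in which case the branch whose reachable
    outcome has the higher treatment priority is taken (avoiding
    under-triage) and the result is flagged.
    """
    ranks = _reachable_ranks(system) if impute_safer else {}
    trace: list[tuple[str, str]] = []
    lsis: list[LSIAction] = []
    flags: list[str] = []
    node = system.node_map[system.root]
    while True:
        lsis.extend(node.lsi_before)
        answer = node.predicate.answer(assessment, system.options)
        if answer is None:
            if not impute_safer:
                fields = node.predicate.fields_read()
                raise MissingFieldError(fields[0] if fields else node.id, node.id, system.id)

            def branch_rank(branch: Branch) -> int:
                if branch.tier is not None:
                    return branch.tier.severity_rank or 0
                return ranks[branch.node]

            answer = branch_rank(node.on_yes) >= branch_rank(node.on_no)
            if "IMPUTED" not in flags:
                flags.append("IMPUTED")
        trace.append((node.id, "yes" if answer else "no"))
        branch = node.on_yes if answer else node.on_no
        lsis.extend(branch.lsi)
        if branch.tier is not None:
            tier = branch.tier
            break
        node = system.node_map[branch.node]
    if system.options.get("enable_orange") and tier in (
        Tier.P2_URGENT_YELLOW,
        Tier.P3_DELAYED_GREEN,
    ):
        # FDNY-START ORANGE is a secondary assessment of deterioration risk;
        # the primary result is flagged as eligible, never re-tiered here.
        flags.append("ORANGE_ELIGIBLE")
    return TriageResult(tier=tier, trace=trace, lsis_recommended=lsis, flags=flags)


def replay_trace(system: TriageSystemDefinition, trace: list[tuple[str, str]]) -> Tier:
    """Re-derive the tier from a recorded trace (consistency check)."""
    node = system.node_map[system.root]
    for nid, answer in trace:
        if node.id != nid:
            raise StructuralError(f"trace diverges: expected node '{node.id}', got '{nid}'")
        branch = node.on_yes if answer == "yes" else node.on_no
        if branch.tier is not None:
            return branch.tier
        node = system.node_map[branch.node]
    raise StructuralError("trace ended before reaching a terminal tier")


def missing_fields(system: TriageSystemDefinition, assessment: Assessment) -> list[str]:
    """Unknown fields reachable during evaluation (see completeness_check)."""
    missing: list[str] = []
    seen_nodes: set[str] = set()

    def walk(nid: str) -> None:
        if nid in seen_nodes:
            return
        seen_nodes.add(nid)
        node = system.node_map[nid]
        answer = node.predicate.answer(assessment, system.options)
        if answer is None:
            for f in node.predicate.fields_read():
                if f not in missing:
                    missing.append(f)
            branches = (node.on_yes, node.on_no)
        else:
            branches = (node.on_yes if answer else node.on_no,)
        for branch in branches:
            if branch.node is not None:
                walk(branch.node)

    walk(system.root)
    return missing


# ---------------------------------------------------------------------------
# Assessment-space enumeration (oracle support)

_BASELINE = dict(
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

# Representative grids spanning both sides of every shipped threshold:
# RR thresholds 10/12/21/29/30, HR 100 (>=) and 120 (>), CF 2 s, GCS 14.
DEFAULT_GRIDS: dict[str, list] = {
    "respiratory_rate": [5.0, 9.0, 10.0, 11.0, 12.0, 21.0, 22.0, 29.0, 30.0, 31.0, 35.0],
    "capillary_refill_seconds": [1.0, 3.0],
    "heart_rate": [80.0, 99.0, 100.0, 120.0, 121.0],
    "gcs": [13, 14, 15],
    "cold_environment": [False, True],
    **{
        f: ["yes", "no"]
        for f in (
            "ambulatory",
            "spontaneous_breathing",
            "breathing_after_airway_positioning",
            "respiratory_distress",
            "radial_pulse_palpable",
            "follows_commands",
            "purposeful_movement",
            "major_external_hemorrhage",
            "hemorrhage_controlled_after_intervention",
            "obvious_death_signs",
            "survivable_given_resources",
            "can_wave",
            "minor_injuries_only",
        )
    },
}


def enumerate_assessment_space(grids: dict[str, list]) -> Iterator[Assessment]:
    """Exhaustive cartesian enumeration over per-field value grids.

    Deterministic order; the stream length equals the product of grid sizes.
    A combination with spontaneous breathing present is coerced to 'no
    airway-positioning response' so every emitted record is well formed.
    """
    if not grids:
        raise ConfigurationError("no grids given")
    for field, values in grids.items():
        if field not in Assessment.model_fields:
            raise ConfigurationError(f"unknown assessment field '{field}'")
        if not values:
            raise ConfigurationError(f"empty grid for field '{field}'")
    return _enumerate(grids)


def _enumerate(grids: dict[str, list]) -> Iterator[Assessment]:
    fields = [f for f in Assessment.model_fields if f in grids]
    for combo in itertools.product(*(grids[f] for f in fields)):
        record = dict(_BASELINE)
        record.update(zip(fields, combo))
        if record["spontaneous_breathing"] == "yes":
            record["breathing_after_airway_positioning"] = "no"
            record["airway_positioning_attempts"] = 0
        else:
            record["airway_positioning_attempts"] = (
                2 if record["breathing_after_airway_positioning"] == "no" else 1
            )
        yield Assessment(**record)


def system_grids(system: TriageSystemDefinition) -> dict[str, list]:
    """Default grids restricted to the fields a system interrogates."""
    return {f: DEFAULT_GRIDS[f] for f in system.fields_used() if f in DEFAULT_GRIDS}


# ---------------------------------------------------------------------------
# SALT global sorting (a pre-pass ordering hint, not a tier assignment)


def salt_global_sort(assessments: Iterable[Assessment]) -> list[int]:
    """Assessment order under SALT global sorting.

    Still casualties (no waving, no walking) are assessed first, those able
    to wave / make purposeful movements second, walkers third.  Stable for
    ties; every casualty still traverses SALT's individual tree.
    """

    def group(a: Assessment) -> int:
        if a.ambulatory is YES:
            return 2
        if a.can_wave is YES or a.purposeful_movement is YES:
            return 1
        return 0

    indexed = list(enumerate(assessments))
    indexed.sort(key=lambda pair: (group(pair[1]), pair[0]))
    return [i for i, _ in indexed]


def system_to_yaml(system: TriageSystemDefinition) -> str:
    """Serialize a definition back to the rule-file schema."""
    data = system.model_dump(mode="json", exclude_none=True)
    for node in data["nodes"]:
        for key in ("on_yes", "on_no"):
            branch = node[key]
            if not branch.get("lsi"):
                branch.pop("lsi", None)
        if not node.get("lsi_before"):
            node.pop("lsi_before", None)
    if not data.get("extra_lsi_inventory"):
        data.pop("extra_lsi_inventory", None)
    return yaml.safe_dump(data, sort_keys=False)
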