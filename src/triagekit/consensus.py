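"""Evaluation of casualties under a consensus specification, cross-system
classification, and inter-system agreement statistics.

``evaluate_consensus`` is a direct implementation of the variant semantics;
the same specification compiled to a rule file and run through the generic
tree engine must produce identical tiers (checked by the test suite), since
the derived tool is deliberately "just another system".
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Optional, Sequence, Union

import numpy as np
import pandas as pd
from sklearn.metrics import cohen_kappa_score

from .errors import DomainError, MissingFieldError
from .model import (
    UNKNOWN,
    YES,
    Assessment,
    LSIAction,
    LSIKind,
    Tier,
    Training,
    TRAINING_ORDER,
    TriageResult,
)
from .synthesis import ConsensusSpecification, consensus_to_system
from .systems import TriageSystemDefinition, evaluate

# Equipment an intervention cannot be improvised without.
_LSI_EQUIPMENT = {
    LSIKind.CHEST_DECOMPRESSION: "decompression kit",
    LSIKind.ANTIDOTE_AUTOINJECTOR: "antidote autoinjectors",
}


@dataclass(frozen=True)
class RescuerProfile:
    """Who is triaging: training level and equipment carried.

    No intervention is recommended as performable beyond the rescuer's
    training or equipment; it is still recorded as indicated.
    """

    training: Training = Training.ADVANCED
    equipment: frozenset[str] = frozenset(
        {"tourniquet/dressing", "airway adjuncts", "decompression kit", "antidote autoinjectors"}
    )

    def permits(self, action: LSIAction) -> bool:
        if TRAINING_ORDER[self.training] < TRAINING_ORDER[action.requires_training]:
            return False
        needed = _LSI_EQUIPMENT.get(action.kind)
        return needed is None or needed in self.equipment


def evaluate_consensus(
    spec: ConsensusSpecification,
    assessment: Assessment,
    rescuer: Optional[RescuerProfile] = None,
) -> TriageResult:
    """Triage one casualty under a consensus variant.

    Majority semantics: walking -> GREEN; not breathing -> BLACK; RR outside
    the derived band, absent radial pulse, or failure to follow commands ->
    RED; otherwise YELLOW.  The modified/CBRN variants substitute the
    respiratory-distress question for rate counting, insert the
    major-bleeding question with a control intervention, and allow airway
    positioning attempts before the dead tier (CBRN drops the pulse check).
    Interventions indicated but outside the rescuer's capability are traced
    as "indicated, not performed", never silently dropped.
    """
    rescuer = rescuer or RescuerProfile()
    system_id = f"CONSENSUS_{spec.variant.upper()}"
    trace: list[tuple[str, str]] = []
    lsis: list[LSIAction] = []
    enabled = spec.enabled_lsis()

    def ask(fieldname: str, criterion: str) -> bool:
        value = getattr(assessment, fieldname)
        if value is UNKNOWN:
            raise MissingFieldError(fieldname, criterion, system_id)
        answer = value is YES
        trace.append((criterion, "yes" if answer else "no"))
        return answer

    def recommend(kind: LSIKind) -> None:
        action = enabled.get(kind)
        if action is None:
            return
        if rescuer.permits(action):
            lsis.append(action)
            trace.append((f"lsi:{kind.value}", "performed"))
        else:
            trace.append((f"lsi:{kind.value}", "indicated, not performed"))

    def result(tier: Tier) -> TriageResult:
        return TriageResult(tier=tier, trace=trace, lsis_recommended=lsis)

    p1 = spec.p1_criteria()

    if ask("ambulatory", "walking"):
        return result(Tier.P3_DELAYED_GREEN)
    if not ask("spontaneous_breathing", "breathing"):
        if spec.allow_airway_attempts:
            recommend(LSIKind.AIRWAY_POSITIONING)
            if ask("breathing_after_airway_positioning", "airway_response"):
                return result(Tier.P1_IMMEDIATE_RED)
        return result(Tier.PX_DEAD_BLACK)
    if "p1_rr" in p1:
        if spec.rr_band is None:
            raise DomainError("specification interrogates RR but has no band")
        rr = assessment.respiratory_rate
        if rr is None:
            raise MissingFieldError("respiratory_rate", "resp_rate", system_id)
        outside = not spec.rr_band.contains(rr)
        trace.append(("resp_rate", "yes" if outside else "no"))
        if outside:
            return result(Tier.P1_IMMEDIATE_RED)
    if "p1_respiratory_distress" in p1 and ask("respiratory_distress", "resp_distress"):
        return result(Tier.P1_IMMEDIATE_RED)
    if "p1_major_external_hemorrhage" in p1 and ask(
        "major_external_hemorrhage", "major_hemorrhage"
    ):
        recommend(LSIKind.HEMORRHAGE_CONTROL)
        return result(Tier.P1_IMMEDIATE_RED)
    if "p1_radial_pulse_absent" in p1 and not ask("radial_pulse_palpable", "radial_pulse"):
        return result(Tier.P1_IMMEDIATE_RED)
    if "p1_commands_unable" in p1 and not ask("follows_commands", "commands"):
        return result(Tier.P1_IMMEDIATE_RED)
    return result(Tier.P2_URGENT_YELLOW)


# ---------------------------------------------------------------------------
# Cross-system classification

Evaluable = Union[TriageSystemDefinition, ConsensusSpecification]


def _column_id(obj: Evaluable) -> str:
    return obj.id if isinstance(obj, TriageSystemDefinition) else f"CONSENSUS_{obj.variant.upper()}"


def cross_classify(
    systems: Sequence[Evaluable],
    cohort: Sequence[Assessment],
    impute_safer: bool = False,
) -> pd.DataFrame:
    """Tier matrix (casualty x system) over a cohort.

    Consensus specifications are compiled to the generic engine when safer
    imputation is requested, so partial assessments behave uniformly.
    """
    columns: dict[str, list[str]] = {}
    for obj in systems:
        cid = _column_id(obj)
        tiers: list[str] = []
        for idx, assessment in enumerate(cohort):
            try:
                if isinstance(obj, TriageSystemDefinition):
                    res = evaluate(obj, assessment, impute_safer=impute_safer)
                elif impute_safer:
                    res = evaluate(consensus_to_system(obj), assessment, impute_safer=True)
                else:
                    res = evaluate_consensus(obj, assessment)
            except MissingFieldError as exc:
                exc.add_note(f"casualty index {idx}, system {cid}")
                raise
            tiers.append(res.tier.value)
        columns[cid] = tiers
    return pd.DataFrame(columns, index=pd.RangeIndex(len(cohort), name="casualty"))


# ---------------------------------------------------------------------------
# Agreement

# Extended tiers folded onto the four-category core space: GRAY is a subset
# of IMMEDIATE casualties; ORANGE marks GREEN/YELLOW casualties at risk of
# deterioration and maps to its parent urgent tier.
_CORE_FOLD = {
    Tier.GRAY_EXPECTANT.value: Tier.P1_IMMEDIATE_RED.value,
    Tier.ORANGE_EXTENDED.value: Tier.P2_URGENT_YELLOW.value,
}

_CORE_LABELS = [t.value for t in (
    Tier.P3_DELAYED_GREEN,
    Tier.P2_URGENT_YELLOW,
    Tier.P1_IMMEDIATE_RED,
    Tier.PX_DEAD_BLACK,
)]


def fold_to_core(tiers: Iterable[str]) -> list[str]:
    return [_CORE_FOLD.get(t, t) for t in tiers]


@dataclass
class AgreementMatrices:
    raw: pd.DataFrame
    kappa: pd.DataFrame


def agreement_matrix(tier_matrix: pd.DataFrame) -> AgreementMatrices:
    """Pairwise raw and chance-corrected (Cohen's kappa) agreement.

    Computed on the four core tiers after folding extended tiers.  When both
    marginals are degenerate (a single category on both sides) kappa is
    undefined; it is reported as 1.0 under perfect raw agreement and 0.0
    otherwise.
    """
    if tier_matrix.shape[1] < 2:
        raise DomainError("agreement requires at least two systems")
    if tier_matrix.shape[0] < 1:
        raise DomainError("agreement requires at least one casualty")
    cols = list(tier_matrix.columns)
    folded = {c: fold_to_core(tier_matrix[c]) for c in cols}
    raw = pd.DataFrame(np.eye(len(cols)), index=cols, columns=cols)
    kappa = pd.DataFrame(np.ones((len(cols), len(cols))), index=cols, columns=cols)
    for i, a in enumerate(cols):
        for j, b in enumerate(cols):
            if j <= i:
                continue
            xa, xb = folded[a], folded[b]
            observed = float(np.mean([p == q for p, q in zip(xa, xb)]))
            if len(set(xa)) == 1 and len(set(xb)) == 1:
                k = 1.0 if observed == 1.0 else 0.0
            else:
                k = float(cohen_kappa_score(xa, xb, labels=_CORE_LABELS))
                if np.isnan(k):
                    k = 1.0 if observed == 1.0 else 0.0
            raw.iloc[i, j] = raw.iloc[j, i] = observed
            kappa.iloc[i, j] = kappa.iloc[j, i] = k
    return AgreementMatrices(raw=raw, kappa=kappa)
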