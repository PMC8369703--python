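"""Synthetic casualty cohorts with a latent severity reference standard,
and triage-performance metrics (over-/under-triage, sensitivity/specificity,
agreement with the reference).

The reference standard is explicitly synthetic: there is no published gold
standard for primary-triage correctness, so each casualty is generated from
a latent severity class that maps deterministically onto a reference tier
(minor -> P3, moderate -> P2, severe/critical -> P1, unsalvageable -> PX).
"""

from __future__ import annotations

import enum
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from pydantic import BaseModel, ConfigDict, Field, model_validator
from sklearn.metrics import cohen_kappa_score

from .errors import UsageError
from .model import Assessment, Ternary, Tier
from .consensus import (
    Evaluable,
    _CORE_LABELS,
    evaluate_consensus,
    fold_to_core,
)
from .systems import TriageSystemDefinition, evaluate


class Severity(str, enum.Enum):
    MINOR = "minor"
    MODERATE = "moderate"
    SEVERE = "severe"
    CRITICAL = "critical"
    UNSALVAGEABLE = "unsalvageable"


TRUE_TIER = {
    Severity.MINOR: Tier.P3_DELAYED_GREEN,
    Severity.MODERATE: Tier.P2_URGENT_YELLOW,
    Severity.SEVERE: Tier.P1_IMMEDIATE_RED,
    Severity.CRITICAL: Tier.P1_IMMEDIATE_RED,
    Severity.UNSALVAGEABLE: Tier.PX_DEAD_BLACK,
}


class ClassParams(BaseModel):
    """Conditional vital-sign distributions for one severity class.

    Respiratory and heart rates are truncated normal draws; binary findings
    are Bernoulli.  ``rr_tachypnea`` / ``rr_bradypnea`` are the probabilities
    of drawing from the deranged-rate components instead of the central one.
    """

    model_config = ConfigDict(extra="forbid")

    p_ambulatory: float = Field(ge=0, le=1)
    p_breathing: float = Field(default=1.0, ge=0, le=1)
    rr_mean: float = 16.0
    rr_sd: float = 2.0
    rr_tachypnea: float = Field(default=0.0, ge=0, le=1)
    rr_tachy_mean: float = 38.0
    rr_brady_mean: float = 7.0
    rr_bradypnea: float = Field(default=0.0, ge=0, le=1)
    hr_mean: float = 85.0
    hr_sd: float = 10.0
    p_radial: float = Field(ge=0, le=1)
    p_commands: float = Field(ge=0, le=1)
    p_distress: float = Field(ge=0, le=1)
    p_hemorrhage: float = Field(ge=0, le=1)
    p_controlled: float = Field(default=0.5, ge=0, le=1)
    p_minor_only: float = Field(default=0.0, ge=0, le=1)
    gcs_low: int = Field(default=15, ge=3, le=15)
    gcs_high: int = Field(default=15, ge=3, le=15)
    p_survivable: float = Field(default=1.0, ge=0, le=1)
    p_obvious_death: float = Field(default=0.0, ge=0, le=1)


DEFAULT_SEVERITY_PROBS = {
    Severity.MINOR: 0.45,
    Severity.MODERATE: 0.25,
    Severity.SEVERE: 0.15,
    Severity.CRITICAL: 0.10,
    Severity.UNSALVAGEABLE: 0.05,
}

DEFAULT_CLASS_PARAMS: dict[Severity, ClassParams] = {
    Severity.MINOR: ClassParams(
        p_ambulatory=0.95, rr_mean=16, rr_sd=2, hr_mean=85, hr_sd=10,
        p_radial=0.995, p_commands=0.99, p_distress=0.01,
        p_hemorrhage=0.02, p_controlled=0.9, p_minor_only=0.9,
        gcs_low=14, gcs_high=15,
    ),
    Severity.MODERATE: ClassParams(
        p_ambulatory=0.15, rr_mean=19, rr_sd=3, hr_mean=95, hr_sd=12,
        p_radial=0.98, p_commands=0.95, p_distress=0.05,
        p_hemorrhage=0.10, p_controlled=0.8, p_minor_only=0.05,
        gcs_low=13, gcs_high=15,
    ),
    Severity.SEVERE: ClassParams(
        p_ambulatory=0.03, rr_mean=26, rr_sd=4,
        rr_tachypnea=0.45, rr_bradypnea=0.10,
        hr_mean=115, hr_sd=15,
        p_radial=0.55, p_commands=0.55, p_distress=0.55,
        p_hemorrhage=0.30, p_controlled=0.5,
        gcs_low=8, gcs_high=14, p_survivable=0.98,
    ),
    Severity.CRITICAL: ClassParams(
        p_ambulatory=0.0, rr_mean=28, rr_sd=5,
        rr_tachypnea=0.60, rr_bradypnea=0.20,
        hr_mean=135, hr_sd=15,
        p_radial=0.15, p_commands=0.08, p_distress=0.85,
        p_hemorrhage=0.45, p_controlled=0.4,
        gcs_low=3, gcs_high=8, p_survivable=0.75,
    ),
    Severity.UNSALVAGEABLE: ClassParams(
        p_ambulatory=0.0, p_breathing=0.0,
        p_radial=0.0, p_commands=0.0, p_distress=0.0,
        p_hemorrhage=0.30, p_controlled=0.0,
        gcs_low=3, gcs_high=3, p_survivable=0.0, p_obvious_death=0.4,
    ),
}


class CohortSpecification(BaseModel):
    model_config = ConfigDict(extra="forbid")

    n: int = Field(ge=0)
    seed: int = 0
    severity_probs: dict[Severity, float] = DEFAULT_SEVERITY_PROBS
    class_params: dict[Severity, ClassParams] = DEFAULT_CLASS_PARAMS
    cold_environment_prob: float = Field(default=0.2, ge=0, le=1)

    @model_validator(mode="after")
    def _probs_normalized(self) -> "CohortSpecification":
        total = sum(self.severity_probs.values())
        if any(p < 0 for p in self.severity_probs.values()) or abs(total - 1.0) > 1e-9:
            raise ValueError(f"severity_probs must be nonnegative and sum to 1, got {total}")
        missing = set(Severity) - set(self.severity_probs)
        if missing:
            raise ValueError(f"severity_probs missing classes: {sorted(m.value for m in missing)}")
        return self


@dataclass(frozen=True)
class ReferenceStandard:
    casualty_index: int
    severity: Severity
    true_tier: Tier


def _truncated_normal(rng: np.random.Generator, mean: float, sd: float, low: float) -> float:
    for _ in range(100):
        x = rng.normal(mean, sd)
        if x >= low:
            return float(round(x, 1))
    return float(low)


def _bern(rng: np.random.Generator, p: float) -> bool:
    return bool(rng.random() < p)


def _tern(flag: bool) -> Ternary:
    return Ternary.YES if flag else Ternary.NO


def generate_cohort(
    spec: CohortSpecification,
) -> tuple[list[Assessment], list[ReferenceStandard]]:
    """Draw a seeded synthetic cohort with mutually consistent findings.

    Only unsalvageable casualties are generated apneic; perfusion proxies
    (radial pulse, capillary refill) are kept concordant; command-following
    implies purposeful movement and waving ability.
    """
    rng = np.random.default_rng(spec.seed)
    classes = list(Severity)
    probs = np.array([spec.severity_probs[c] for c in classes])
    cohort: list[Assessment] = []
    reference: list[ReferenceStandard] = []
    for i in range(spec.n):
        sev = classes[int(rng.choice(len(classes), p=probs))]
        p = spec.class_params[sev]
        breathing = _bern(rng, p.p_breathing)
        ambulatory = breathing and _bern(rng, p.p_ambulatory)
        if breathing:
            u = rng.random()
            if u < p.rr_tachypnea:
                rr = _truncated_normal(rng, p.rr_tachy_mean, 3.0, 31.0)
            elif u < p.rr_tachypnea + p.rr_bradypnea:
                rr = _truncated_normal(rng, p.rr_brady_mean, 1.5, 1.0)
            else:
                rr = _truncated_normal(rng, p.rr_mean, p.rr_sd, 4.0)
            hr = _truncated_normal(rng, p.hr_mean, p.hr_sd, 20.0)
        else:
            rr, hr = 0.0, 0.0
        radial = breathing and _bern(rng, p.p_radial)
        cap_refill = (
            float(round(rng.uniform(0.5, 1.9), 1))
            if radial
            else float(round(rng.uniform(2.1, 6.0), 1))
        )
        commands = breathing and _bern(rng, p.p_commands)
        # walkers reliably follow the command that made them walk
        if ambulatory:
            commands = True
        purposeful = commands or _bern(rng, 0.3 if breathing else 0.0)
        distress = breathing and _bern(rng, p.p_distress)
        hemorrhage = _bern(rng, p.p_hemorrhage)
        controlled = hemorrhage and _bern(rng, p.p_controlled)
        gcs = int(rng.integers(p.gcs_low, p.gcs_high + 1)) if breathing else 3
        cohort.append(
            Assessment(
                ambulatory=_tern(ambulatory),
                spontaneous_breathing=_tern(breathing),
                breathing_after_airway_positioning=Ternary.NO,
                airway_positioning_attempts=0 if breathing else 2,
                respiratory_rate=rr,
                respiratory_distress=_tern(distress),
                radial_pulse_palpable=_tern(radial),
                capillary_refill_seconds=cap_refill,
                heart_rate=hr,
                follows_commands=_tern(commands),
                purposeful_movement=_tern(purposeful),
                gcs=gcs,
                major_external_hemorrhage=_tern(hemorrhage),
                hemorrhage_controlled_after_intervention=_tern(controlled),
                obvious_death_signs=_tern(_bern(rng, p.p_obvious_death)),
                cold_environment=_bern(rng, spec.cold_environment_prob),
                survivable_given_resources=_tern(_bern(rng, p.p_survivable)),
                can_wave=_tern(commands),
                minor_injuries_only=_tern(_bern(rng, p.p_minor_only)),
            )
        )
        reference.append(ReferenceStandard(i, sev, TRUE_TIER[sev]))
    return cohort, reference


# ---------------------------------------------------------------------------
# Performance metrics

_REPORT_TIERS = [t.value for t in (
    Tier.P3_DELAYED_GREEN,
    Tier.P2_URGENT_YELLOW,
    Tier.P1_IMMEDIATE_RED,
    Tier.PX_DEAD_BLACK,
    Tier.GRAY_EXPECTANT,
)]


@dataclass
class PerformanceReport:
    """Confusion matrix and mis-triage metrics against the reference.

    Rates are computed over *rankable* casualties: reference tier and
    assigned tier both within the ordered P3 < P2 < P1 scale.  Casualties
    whose reference or assignment is PX/GRAY stay in the confusion matrix
    but not in the rates, because mis-triage of a dead or expectant casualty
    has no defined direction.  The reference standard is synthetic.
    """

    system_id: str
    confusion: pd.DataFrame  # true tier (rows) x assigned tier (columns)
    n: int
    n_rankable: int
    under_triage_rate: float
    over_triage_rate: float
    correct_rate: float
    sensitivity: dict[str, float]
    specificity: dict[str, float]
    kappa_vs_reference: float

    def summary(self) -> str:
        lines = [
            f"system: {self.system_id}  (n={self.n}, rankable={self.n_rankable}; "
            "synthetic reference standard)",
            f"under-triage {self.under_triage_rate:.3f}  "
            f"over-triage {self.over_triage_rate:.3f}  "
            f"correct {self.correct_rate:.3f}  "
            f"kappa {self.kappa_vs_reference:.3f}",
        ]
        for tier in _CORE_LABELS:
            lines.append(
                f"  {tier}: sensitivity {self.sensitivity[tier]:.3f} "
                f"specificity {self.specificity[tier]:.3f}"
            )
        return "\n".join(lines)


def assign_tiers(
    system: Evaluable, cohort: Sequence[Assessment], impute_safer: bool = False
) -> list[Tier]:
    if isinstance(system, TriageSystemDefinition):
        return [evaluate(system, a, impute_safer=impute_safer).tier for a in cohort]
    return [evaluate_consensus(system, a).tier for a in cohort]


def score_system(
    system: Evaluable,
    cohort: Sequence[Assessment],
    reference: Sequence[ReferenceStandard],
    impute_safer: bool = False,
    assigned: Optional[Sequence[Tier]] = None,
) -> PerformanceReport:
    """Score a system (or consensus variant) against the reference standard.

    ``assigned`` lets a caller score precomputed tiers (e.g. a column of a
    cross-classification matrix) without re-evaluating.
    """
    if len(cohort) != len(reference):
        raise UsageError(
            f"cohort ({len(cohort)}) and reference ({len(reference)}) lengths differ"
        )
    if assigned is None:
        assigned = assign_tiers(system, cohort, impute_safer=impute_safer)
    elif len(assigned) != len(reference):
        raise UsageError("assigned tiers and reference lengths differ")

    if isinstance(system, TriageSystemDefinition):
        system_id = system.id
    elif system is None:
        system_id = "precomputed"
    else:
        system_id = f"CONSENSUS_{system.variant.upper()}"
    true = [r.true_tier for r in reference]
    confusion = pd.DataFrame(
        0, index=_REPORT_TIERS, columns=_REPORT_TIERS, dtype=int
    )
    confusion.index.name = "true_tier"
    confusion.columns.name = "assigned_tier"
    for t, a in zip(true, assigned):
        confusion.loc[t.value, a.value] += 1

    under = over = correct = 0
    for t, a in zip(true, assigned):
        rt, ra = t.severity_rank, a.severity_rank
        if rt is None or ra is None:
            continue
        if ra < rt:
            under += 1
        elif ra > rt:
            over += 1
        else:
            correct += 1
    n_rankable = under + over + correct

    sensitivity: dict[str, float] = {}
    specificity: dict[str, float] = {}
    true_core = [t.value for t in true]
    assigned_core = fold_to_core([a.value for a in assigned])
    for tier in _CORE_LABELS:
        tp = sum(1 for t, a in zip(true_core, assigned_core) if t == tier and a == tier)
        fn = sum(1 for t, a in zip(true_core, assigned_core) if t == tier and a != tier)
        tn = sum(1 for t, a in zip(true_core, assigned_core) if t != tier and a != tier)
        fp = sum(1 for t, a in zip(true_core, assigned_core) if t != tier and a == tier)
        sensitivity[tier] = tp / (tp + fn) if tp + fn else float("nan")
        specificity[tier] = tn / (tn + fp) if tn + fp else float("nan")

    if len(set(true_core)) == 1 and len(set(assigned_core)) == 1:
        kappa = 1.0 if true_core == assigned_core else 0.0
    else:
        kappa = float(cohen_kappa_score(true_core, assigned_core, labels=_CORE_LABELS))
        if np.isnan(kappa):
            kappa = 1.0 if true_core == assigned_core else 0.0

    return PerformanceReport(
        system_id=system_id,
        confusion=confusion,
        n=len(cohort),
        n_rankable=n_rankable,
        under_triage_rate=under / n_rankable if n_rankable else 0.0,
        over_triage_rate=over / n_rankable if n_rankable else 0.0,
        correct_rate=correct / n_rankable if n_rankable else 0.0,
        sensitivity=sensitivity,
        specificity=specificity,
        kappa_vs_reference=kappa,
    )
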