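"""Deterministic engines for the three cervical-spine-injury prediction rules.

Three prospectively derived clinical prediction rules are implemented:

* **PECARN CSI** — the pediatric-specific three-tier rule. High-risk
  factors (GCS 3-8 or unresponsive on AVPU; abnormal airway, breathing or
  circulation; focal neurologic deficit) indicate CT; otherwise any
  CART-derived risk factor (altered mental status, defined as GCS 9-14,
  verbal/pain on AVPU, or other signs; self-reported neck pain or neck
  tenderness on examination; substantial head or torso injury) indicates
  radiography; otherwise the child is clinically cleared. High-risk
  evaluation strictly precedes low-risk evaluation.

* **NEXUS** — imaging is recommended unless *all* low-risk criteria hold:
  no posterior midline c-spine tenderness, no intoxication, normal
  alertness (GCS 15, remembers 3 objects, no delayed response), no focal
  neurologic deficit, no painful distracting injury.

* **CCR** (Canadian C-spine Rule) — a cascade for patients with GCS 15 and
  normal vital signs: any high-risk factor (age >= 65, dangerous mechanism,
  paresthesias in the extremities) mandates imaging; otherwise at least one
  low-risk criterion (simple rear-end crash, sitting in the ED, ambulatory
  at any time, delayed onset of neck pain, absent midline tenderness) must
  hold to permit examining range of motion; finally the patient is cleared
  only if able to actively rotate the neck 45 degrees each way. Patients
  failing the GCS/vital-signs gate are classified positive and flagged
  ``gated_positive`` for audit.

Unknown handling is a policy, configurable via :class:`RulePolicy`; the
defaults are the ones used throughout this package and documented in
``docs/methods.md``: PECARN treats unknown factors as absent (the rule is
presence-of-factor based); NEXUS requires positive verification of each
clearance criterion, so unknowns fail clearance, *except* that the two
memory/response items default to satisfied in an alert GCS-15 child (they
cannot be administered to preverbal children); CCR treats unknowns
conservatively (unknown vitals fail the gate, unknown low-risk criteria do
not count as satisfied, unknown rotation means imaging).
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from typing import Iterable, Sequence

from .records import (
    DANGEROUS_MECHANISM_FLAGS,
    Avpu,
    MechanismDetail,
    PatientRecord,
    TriState,
)

PRESENT = TriState.PRESENT
ABSENT = TriState.ABSENT
UNKNOWN = TriState.UNKNOWN


class Rule(str, enum.Enum):
    PECARN = "pecarn"
    NEXUS = "nexus"
    CCR = "ccr"


class Tier(str, enum.Enum):
    """Disposition tier; PECARN uses all three, NEXUS/CCR collapse to imaging."""

    CLEARED = "cleared"
    RADIOGRAPHY = "radiography"
    CT = "ct"
    IMAGING = "imaging"


class Applicability(str, enum.Enum):
    APPLICABLE = "applicable"
    GATED_POSITIVE = "gated_positive"


@dataclass(frozen=True)
class RuleDecision:
    """Outcome of one rule applied to one record."""

    rule: Rule
    tier: Tier
    fired_criteria: tuple[str, ...] = ()
    applicability: Applicability = Applicability.APPLICABLE

    @property
    def positive(self) -> bool:
        return self.tier is not Tier.CLEARED


@dataclass(frozen=True)
class RulePolicy:
    """Configurable unknown-handling switches (defaults documented above)."""

    #: NEXUS: unknown memory/response items count as satisfied in an alert,
    #: GCS-15 child (the items cannot be administered to preverbal children).
    nexus_preverbal_exception: bool = True
    #: NEXUS: fall back to substantial head/torso injury when the dedicated
    #: painful-distracting-injury field is unknown (variable crosswalk).
    nexus_distracting_from_substantial: bool = True


DEFAULT_POLICY = RulePolicy()


def _altered_mental_status(r: PatientRecord) -> bool:
    """PECARN 'altered mental status': GCS 9-14, verbal/pain on AVPU, or other signs."""
    if r.gcs_total is not None and 9 <= r.gcs_total <= 14:
        return True
    if r.avpu in (Avpu.VERBAL, Avpu.PAIN):
        return True
    return r.altered_mental_status_other_signs is PRESENT


def pecarn_classify(
    record: PatientRecord, policy: RulePolicy = DEFAULT_POLICY
) -> RuleDecision:
    """Apply the three-tier PECARN CSI rule to one record."""
    high: list[str] = []
    if record.gcs_total is not None and record.gcs_total <= 8:
        high.append("pecarn.high.gcs3_8")
    if record.avpu is Avpu.UNRESPONSIVE:
        high.append("pecarn.high.unresponsive")
    if record.abnormal_abc is PRESENT:
        high.append("pecarn.high.abnormal_abc")
    if record.focal_neuro_deficit is PRESENT:
        high.append("pecarn.high.focal_deficit")
    if high:
        return RuleDecision(Rule.PECARN, Tier.CT, tuple(high))

    low: list[str] = []
    if _altered_mental_status(record):
        low.append("pecarn.low.altered_mental_status")
    if record.self_reported_neck_pain is PRESENT or record.neck_tenderness_exam is PRESENT:
        low.append("pecarn.low.neck_pain_or_tenderness")
    if record.substantial_head_or_torso_injury is PRESENT:
        low.append("pecarn.low.substantial_injury")
    if low:
        return RuleDecision(Rule.PECARN, Tier.RADIOGRAPHY, tuple(low))
    return RuleDecision(Rule.PECARN, Tier.CLEARED)


def nexus_classify(
    record: PatientRecord, policy: RulePolicy = DEFAULT_POLICY
) -> RuleDecision:
    """Apply the NEXUS low-risk criteria; cleared only if all are verified."""
    fired: list[str] = []

    if record.posterior_midline_tenderness is not ABSENT:
        fired.append("nexus.posterior_midline_tenderness")
    if record.intoxication is not ABSENT:
        fired.append("nexus.intoxication")

    alert = record.gcs_total == 15
    memory_ok = record.remembers_3_objects is PRESENT
    response_ok = record.delayed_response is ABSENT
    if policy.nexus_preverbal_exception and alert and record.avpu is Avpu.ALERT:
        memory_ok = memory_ok or record.remembers_3_objects is UNKNOWN
        response_ok = response_ok or record.delayed_response is UNKNOWN
    if not (alert and memory_ok and response_ok):
        fired.append("nexus.not_alert")

    if record.focal_neuro_deficit is not ABSENT:
        fired.append("nexus.focal_deficit")

    distracting = record.painful_distracting_injury
    if distracting is UNKNOWN and policy.nexus_distracting_from_substantial:
        distracting = record.substantial_head_or_torso_injury
    if distracting is not ABSENT:
        fired.append("nexus.distracting_injury")

    if fired:
        return RuleDecision(Rule.NEXUS, Tier.IMAGING, tuple(fired))
    return RuleDecision(Rule.NEXUS, Tier.CLEARED)


def ccr_classify(
    record: PatientRecord, policy: RulePolicy = DEFAULT_POLICY
) -> RuleDecision:
    """Apply the Canadian C-spine Rule cascade to one record."""
    # Stage 0 — applicability gate: GCS 15 and normal vital signs.
    if record.gcs_total != 15 or record.normal_vital_signs is not PRESENT:
        return RuleDecision(
            Rule.CCR,
            Tier.IMAGING,
            ("ccr.gate.gcs_or_vitals",),
            Applicability.GATED_POSITIVE,
        )

    # Stage 1 — high-risk factors mandate imaging.
    high: list[str] = []
    if record.age_years >= 65:  # retained for rule fidelity; ages here are 0-17
        high.append("ccr.high.age_ge_65")
    if record.mechanism_detail & DANGEROUS_MECHANISM_FLAGS:
        high.append("ccr.high.dangerous_mechanism")
    if record.paresthesias_extremities is PRESENT:
        high.append("ccr.high.paresthesias")
    if high:
        return RuleDecision(Rule.CCR, Tier.IMAGING, tuple(high))

    # Stage 2 — at least one low-risk criterion must hold to assess motion.
    low_risk_satisfied = (
        MechanismDetail.SIMPLE_REAR_END_MVC in record.mechanism_detail
        or record.able_to_sit_in_ed is PRESENT
        or record.ambulatory_any_time is PRESENT
        or record.delayed_onset_neck_pain is PRESENT
        or record.posterior_midline_tenderness is ABSENT
    )
    if not low_risk_satisfied:
        return RuleDecision(Rule.CCR, Tier.IMAGING, ("ccr.low.none_satisfied",))

    # Stage 3 — active 45-degree rotation clears; unknown is conservative.
    if record.able_rotate_neck_45 is PRESENT:
        return RuleDecision(Rule.CCR, Tier.CLEARED)
    return RuleDecision(Rule.CCR, Tier.IMAGING, ("ccr.rotation.unable",))


_CLASSIFIERS = {
    Rule.PECARN: pecarn_classify,
    Rule.NEXUS: nexus_classify,
    Rule.CCR: ccr_classify,
}


def classify(
    record: PatientRecord, rule: Rule | str, policy: RulePolicy = DEFAULT_POLICY
) -> RuleDecision:
    """Apply one rule to one record."""
    return _CLASSIFIERS[Rule(rule)](record, policy)


def classify_cohort(
    records: Iterable[PatientRecord],
    rule: Rule | str,
    policy: RulePolicy = DEFAULT_POLICY,
) -> list[tuple[str, RuleDecision]]:
    """Apply one rule to every record, preserving order.

    Returns ``(record_id, RuleDecision)`` pairs, one per record.
    """
    fn = _CLASSIFIERS[Rule(rule)]
    return [(r.record_id, fn(r, policy)) for r in records]


def decisions_frame(pairs: Sequence[tuple[str, RuleDecision]]):
    """Tabulate decisions as a pandas DataFrame (for CSV export)."""
    import pandas as pd

    return pd.DataFrame(
        {
            "record_id": [rid for rid, _ in pairs],
            "rule": [d.rule.value for _, d in pairs],
            "tier": [d.tier.value for _, d in pairs],
            "positive": [d.positive for _, d in pairs],
            "fired_criteria": [";".join(d.fired_criteria) for _, d in pairs],
            "applicability": [d.applicability.value for _, d in pairs],
        }
    )
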