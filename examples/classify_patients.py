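"""Classify individual patients with all three prediction rules.

Builds two example children and prints each rule's disposition and the
criteria that fired: a toddler with a severe presentation (low GCS, abnormal
circulation) and a teenager with isolated neck pain after a simple rear-end
crash. The tier is the imaging the rule suggests; ``fired`` lists why.
"""

from csirules import PatientRecord, Rule, classify
from csirules.records import Avpu, Mechanism, MechanismDetail, TriState

P, A = TriState.PRESENT, TriState.ABSENT

toddler = PatientRecord(
    record_id="toddler",
    age_years=2,
    mechanism=Mechanism.MVC,
    mechanism_detail={MechanismDetail.MVC_HIGH_SPEED},
    gcs_total=6,
    avpu=Avpu.PAIN,
    abnormal_abc=P,
    focal_neuro_deficit=A,
    normal_vital_signs=A,
    csi_present=True,
)

teen = PatientRecord(
    record_id="teen",
    age_years=15,
    mechanism=Mechanism.MVC,
    mechanism_detail={MechanismDetail.SIMPLE_REAR_END_MVC},
    gcs_total=15,
    avpu=Avpu.ALERT,
    self_reported_neck_pain=P,
    neck_tenderness_exam=A,
    posterior_midline_tenderness=A,
    intoxication=A,
    focal_neuro_deficit=A,
    painful_distracting_injury=A,
    remembers_3_objects=P,
    delayed_response=A,
    paresthesias_extremities=A,
    normal_vital_signs=P,
    able_to_sit_in_ed=P,
    ambulatory_any_time=P,
    able_rotate_neck_45=P,
)

for patient in (toddler, teen):
    print(f"\n{patient.record_id} (age {patient.age_years}):")
    for rule in Rule:
        d = classify(patient, rule)
        fired = ", ".join(d.fired_criteria) or "-"
        print(f"  {rule.value:7s} tier={d.tier.value:11s} fired: {fired}")

print(
    "\nThe toddler triggers the pediatric rule's high-risk (CT) tier and both"
    "\nadult-derived rules; the teen with isolated self-reported neck pain is"
    "\nsent to radiography by the pediatric rule but cleared by NEXUS (no"
    "\nmidline tenderness) and by the CCR (low-risk mechanism, full rotation)."
)
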