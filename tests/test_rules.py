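"""Rule-engine behavior: published criteria, unknown handling, invariants."""

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from csirules.records import (
    Avpu,
    Mechanism,
    MechanismDetail,
    PatientRecord,
    TriState,
)
from csirules.rules import (
    Applicability,
    Rule,
    RulePolicy,
    Tier,
    ccr_classify,
    classify,
    classify_cohort,
    nexus_classify,
    pecarn_classify,
)

P, A, U = TriState.PRESENT, TriState.ABSENT, TriState.UNKNOWN

#: Order used for the PECARN monotonicity property.
TIER_RANK = {Tier.CLEARED: 0, Tier.RADIOGRAPHY: 1, Tier.CT: 2}

PECARN_PREDICTORS = (
    "abnormal_abc",
    "focal_neuro_deficit",
    "altered_mental_status_other_signs",
    "self_reported_neck_pain",
    "neck_tenderness_exam",
    "substantial_head_or_torso_injury",
)


def rec(**kw):
    """A record with every factor explicitly normal unless overridden."""
    base = dict(
        record_id="t",
        age_years=kw.pop("age_years", 10),
        mechanism=Mechanism.FALL,
        gcs_total=15,
        avpu=Avpu.ALERT,
        remembers_3_objects=P,
        delayed_response=A,
        normal_vital_signs=P,
        able_to_sit_in_ed=P,
        ambulatory_any_time=P,
        able_rotate_neck_45=P,
    )
    for f in (
        "abnormal_abc",
        "focal_neuro_deficit",
        "altered_mental_status_other_signs",
        "self_reported_neck_pain",
        "neck_tenderness_exam",
        "posterior_midline_tenderness",
        "substantial_head_or_torso_injury",
        "intoxication",
        "painful_distracting_injury",
        "paresthesias_extremities",
        "delayed_onset_neck_pain",
    ):
        base.setdefault(f, A)
    base.update(kw)
    return PatientRecord(**base)


class TestPecarn:
    def test_gcs_5_is_ct_tier(self):
        d = pecarn_classify(rec(gcs_total=5, avpu=Avpu.PAIN))
        assert d.tier is Tier.CT
        assert "pecarn.high.gcs3_8" in d.fired_criteria

    def test_unresponsive_avpu_is_ct_tier(self):
        d = pecarn_classify(rec(gcs_total=None, avpu=Avpu.UNRESPONSIVE))
        assert d.tier is Tier.CT

    def test_neck_pain_alone_is_radiography(self):
        d = pecarn_classify(rec(self_reported_neck_pain=P))
        assert d.tier is Tier.RADIOGRAPHY
        assert d.fired_criteria == ("pecarn.low.neck_pain_or_tenderness",)

    @pytest.mark.parametrize(
        "kw",
        [
            dict(gcs_total=12, avpu=Avpu.VERBAL),
            dict(avpu=Avpu.VERBAL),
            dict(altered_mental_status_other_signs=P),
            dict(neck_tenderness_exam=P),
            dict(substantial_head_or_torso_injury=P),
        ],
    )
    def test_low_risk_factors_are_radiography(self, kw):
        assert pecarn_classify(rec(**kw)).tier is Tier.RADIOGRAPHY

    def test_no_factors_cleared(self):
        d = pecarn_classify(rec())
        assert d.tier is Tier.CLEARED and not d.positive and d.fired_criteria == ()

    def test_high_risk_precedence_over_low(self):
        d = pecarn_classify(rec(focal_neuro_deficit=P, self_reported_neck_pain=P))
        assert d.tier is Tier.CT
        assert "pecarn.high.focal_deficit" in d.fired_criteria
        assert not any(c.startswith("pecarn.low") for c in d.fired_criteria)

    def test_unknowns_treated_as_absent(self):
        unknowns = {f: U for f in PECARN_PREDICTORS}
        assert pecarn_classify(rec(**unknowns)).tier is Tier.CLEARED

    def test_unknown_gcs_uses_avpu_alone(self):
        assert pecarn_classify(rec(gcs_total=None, avpu=Avpu.ALERT)).tier is Tier.CLEARED
        assert (
            pecarn_classify(rec(gcs_total=None, avpu=Avpu.PAIN)).tier
            is Tier.RADIOGRAPHY
        )


class TestNexus:
    def test_all_criteria_satisfied_cleared(self):
        assert nexus_classify(rec()).tier is Tier.CLEARED

    @pytest.mark.parametrize(
        "kw, criterion",
        [
            (dict(posterior_midline_tenderness=P), "nexus.posterior_midline_tenderness"),
            (dict(intoxication=P), "nexus.intoxication"),
            (dict(gcs_total=14), "nexus.not_alert"),
            (dict(remembers_3_objects=A), "nexus.not_alert"),
            (dict(delayed_response=P), "nexus.not_alert"),
            (dict(focal_neuro_deficit=P), "nexus.focal_deficit"),
            (dict(painful_distracting_injury=P), "nexus.distracting_injury"),
        ],
    )
    def test_single_adverse_criterion_fails_clearance(self, kw, criterion):
        d = nexus_classify(rec(**kw))
        assert d.tier is Tier.IMAGING and criterion in d.fired_criteria

    def test_unknown_fails_clearance(self):
        assert nexus_classify(rec(posterior_midline_tenderness=U)).positive
        assert nexus_classify(rec(intoxication=U)).positive

    def test_preverbal_memory_exception(self):
        preverbal = rec(age_years=1, remembers_3_objects=U, delayed_response=U)
        assert nexus_classify(preverbal).tier is Tier.CLEARED
        strict = RulePolicy(nexus_preverbal_exception=False)
        assert nexus_classify(preverbal, strict).tier is Tier.IMAGING

    def test_exception_requires_alert_gcs15(self):
        woozy = rec(gcs_total=13, remembers_3_objects=U, delayed_response=U)
        assert nexus_classify(woozy).tier is Tier.IMAGING

    def test_distracting_mapped_from_substantial_injury(self):
        mapped = rec(painful_distracting_injury=U, substantial_head_or_torso_injury=P)
        d = nexus_classify(mapped)
        assert d.tier is Tier.IMAGING and "nexus.distracting_injury" in d.fired_criteria
        no_map = RulePolicy(nexus_distracting_from_substantial=False)
        # unknown dedicated field with mapping off still fails clearance
        assert nexus_classify(mapped, no_map).positive
        assert nexus_classify(
            rec(painful_distracting_injury=A, substantial_head_or_torso_injury=P)
        ).tier is Tier.CLEARED


class TestCcr:
    def test_gate_failure_is_gated_positive(self):
        for kw in (dict(gcs_total=12), dict(normal_vital_signs=A),
                   dict(normal_vital_signs=U), dict(gcs_total=None)):
            d = ccr_classify(rec(**kw))
            assert d.positive and d.applicability is Applicability.GATED_POSITIVE

    def test_dangerous_mechanism_triggers_imaging(self):
        d = ccr_classify(rec(mechanism_detail={MechanismDetail.FALL_GE_1M}))
        assert d.tier is Tier.IMAGING
        assert d.fired_criteria == ("ccr.high.dangerous_mechanism",)

    def test_paresthesias_triggers_imaging(self):
        d = ccr_classify(rec(paresthesias_extremities=P))
        assert d.tier is Tier.IMAGING and "ccr.high.paresthesias" in d.fired_criteria

    def test_simple_rear_end_then_rotation_clears(self):
        d = ccr_classify(
            rec(
                mechanism=Mechanism.MVC,
                mechanism_detail={MechanismDetail.SIMPLE_REAR_END_MVC},
                able_to_sit_in_ed=A,
                ambulatory_any_time=A,
                posterior_midline_tenderness=P,
                able_rotate_neck_45=P,
            )
        )
        assert d.tier is Tier.CLEARED

    def test_no_low_risk_criterion_images_regardless_of_rotation(self):
        d = ccr_classify(
            rec(
                able_to_sit_in_ed=A,
                ambulatory_any_time=A,
                delayed_onset_neck_pain=A,
                posterior_midline_tenderness=P,
                able_rotate_neck_45=P,
            )
        )
        assert d.tier is Tier.IMAGING
        assert d.fired_criteria == ("ccr.low.none_satisfied",)

    def test_unknown_low_risk_criteria_do_not_count(self):
        d = ccr_classify(
            rec(
                able_to_sit_in_ed=U,
                ambulatory_any_time=U,
                delayed_onset_neck_pain=U,
                posterior_midline_tenderness=U,
            )
        )
        assert d.tier is Tier.IMAGING

    def test_unknown_rotation_is_conservative(self):
        assert ccr_classify(rec(able_rotate_neck_45=U)).tier is Tier.IMAGING
        assert ccr_classify(rec(able_rotate_neck_45=A)).tier is Tier.IMAGING
        assert ccr_classify(rec(able_rotate_neck_45=P)).tier is Tier.CLEARED


class TestClassifyCohort:
    def test_empty_cohort(self):
        assert classify_cohort([], Rule.PECARN) == []

    def test_elementwise_matches_single_classifier(self, random_records):
        subset = random_records[:1000]
        for rule, single in (
            (Rule.PECARN, pecarn_classify),
            (Rule.NEXUS, nexus_classify),
            (Rule.CCR, ccr_classify),
        ):
            pairs = classify_cohort(subset, rule)
            assert [rid for rid, _ in pairs] == [r.record_id for r in subset]
            assert all(d == single(r) for (_, d), r in zip(pairs, subset))

    def test_default_cohort_pecarn_positivity_near_published(self, default_cohort):
        """At study conditions ~41% of children carry at least one factor."""
        pairs = classify_cohort(default_cohort, Rule.PECARN)
        rate = sum(d.positive for _, d in pairs) / len(pairs)
        assert abs(rate - 0.411) < 0.05


# --- property tests ---------------------------------------------------------

tristate = st.sampled_from([P, A, U])
record_strategy = st.builds(
    PatientRecord,
    record_id=st.just("h"),
    age_years=st.integers(0, 17),
    mechanism=st.sampled_from(list(Mechanism)),
    mechanism_detail=st.frozensets(st.sampled_from(list(MechanismDetail)), max_size=3),
    gcs_total=st.one_of(st.none(), st.integers(3, 15)),
    avpu=st.sampled_from(list(Avpu)),
    abnormal_abc=tristate,
    focal_neuro_deficit=tristate,
    altered_mental_status_other_signs=tristate,
    self_reported_neck_pain=tristate,
    neck_tenderness_exam=tristate,
    posterior_midline_tenderness=tristate,
    substantial_head_or_torso_injury=tristate,
    intoxication=tristate,
    remembers_3_objects=tristate,
    delayed_response=tristate,
    painful_distracting_injury=tristate,
    paresthesias_extremities=tristate,
    normal_vital_signs=tristate,
    able_to_sit_in_ed=tristate,
    ambulatory_any_time=tristate,
    delayed_onset_neck_pain=tristate,
    able_rotate_neck_45=tristate,
    csi_present=st.booleans(),
)


@settings(max_examples=200, derandomize=True)
@given(record_strategy, st.sampled_from(PECARN_PREDICTORS))
def test_pecarn_monotone_in_predictors(record, predictor):
    """Flipping any factor from absent to present never lowers the tier."""
    if getattr(record, predictor) is not A:
        record = record.model_copy(update={predictor: A})
    before = TIER_RANK[pecarn_classify(record).tier]
    after = TIER_RANK[pecarn_classify(record.model_copy(update={predictor: P})).tier]
    assert after >= before


@settings(max_examples=300, derandomize=True)
@given(record_strategy)
def test_nexus_conjunctivity(record):
    """Cleared exactly when all five clearance criteria are verified."""
    policy = RulePolicy()
    d = nexus_classify(record, policy)

    alert = record.gcs_total == 15
    exception = alert and record.avpu is Avpu.ALERT
    memory = record.remembers_3_objects is P or (
        exception and record.remembers_3_objects is U
    )
    response = record.delayed_response is A or (
        exception and record.delayed_response is U
    )
    distracting = record.painful_distracting_injury
    if distracting is U:
        distracting = record.substantial_head_or_torso_injury
    should_clear = (
        record.posterior_midline_tenderness is A
        and record.intoxication is A
        and alert and memory and response
        and record.focal_neuro_deficit is A
        and distracting is A
    )
    assert (d.tier is Tier.CLEARED) == should_clear
    assert d.positive == (d.tier is not Tier.CLEARED)


@settings(max_examples=300, derandomize=True)
@given(record_strategy)
def test_ccr_cascade_order(record):
    """Fired criteria come from exactly one stage, in cascade order."""
    d = ccr_classify(record)
    stages = {c.split(".")[1] for c in d.fired_criteria}
    assert len(stages) <= 1
    if d.applicability is Applicability.GATED_POSITIVE:
        assert stages == {"gate"}
        assert record.gcs_total != 15 or record.normal_vital_signs is not P
    elif stages == {"high"}:
        assert record.gcs_total == 15 and record.normal_vital_signs is P
    elif stages in ({"low"}, {"rotation"}):
        # deciding at a late stage implies every earlier stage was passed
        from csirules.records import DANGEROUS_MECHANISM_FLAGS

        assert record.gcs_total == 15 and record.normal_vital_signs is P
        assert not (record.mechanism_detail & DANGEROUS_MECHANISM_FLAGS)
        assert record.paresthesias_extremities is not P


@settings(max_examples=100, derandomize=True)
@given(record_strategy)
def test_determinism_and_positive_flag(record):
    for rule in Rule:
        d1, d2 = classify(record, rule), classify(record, rule)
        assert d1 == d2
        assert d1.positive == (d1.tier is not Tier.CLEARED)
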