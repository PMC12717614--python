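"""Synthetic cohorts for the prediction-rule analysis.

The real study data (22 430 children evaluated after blunt trauma at
pediatric trauma centers) are not public. Two synthetic stand-ins are
provided:

:func:`generate_cohort`
    A stochastic cohort with the published *marginal* structure: cohort
    size, CSI prevalence (1.9%), the 0-8 / 9-17 age split, per-stratum
    predictor prevalences, the mechanism-of-injury distribution, and
    observed imaging rates. Predictor-outcome association is modeled with
    per-predictor probability multipliers conditioned on CSI status:
    given a marginal prevalence ``p`` and multiplier ``m``,
    ``P(factor | CSI) = m * P(factor | no CSI)`` with the mixture pinned
    to ``p``. A handful of clinically motivated couplings (neck pain with
    examination tenderness, severe-physiology clustering, AVPU with GCS)
    are built in via marginal-preserving conditionals, so configured
    marginals are honored exactly in expectation.

:func:`build_table_exact_fixture`
    A deterministic cohort of 22 430 archetype records whose predictor
    patterns are solved so that each rule engine reproduces the published
    per-stratum confusion counts cell-for-cell, and the PECARN tier counts
    match the published cleared/radiography/CT allocation. Each rule is
    driven by a predictor no other rule reads, so the per-rule marginal
    counts are satisfiable simultaneously; the cross-rule joint overlap is
    a free modeling choice (leading-index assignment) because the true
    joint distribution was never published.
"""

from __future__ import annotations

from typing import Callable, Optional

import numpy as np
from pydantic import BaseModel, Field, model_validator

from .records import (
    Avpu,
    ManagementAnnotation,
    Mechanism,
    MechanismDetail,
    ObservedImaging,
    PatientRecord,
    Sex,
    TriState,
)

PRESENT = TriState.PRESENT
ABSENT = TriState.ABSENT
UNKNOWN = TriState.UNKNOWN


class InfeasibleConfigError(ValueError):
    """A configured marginal/multiplier pair implies a probability > 1."""


def conditional_rates(
    name: str, marginal: float, multiplier: float, prevalence: float
) -> tuple[float, float]:
    """Solve P(factor | no CSI), P(factor | CSI) from a marginal and multiplier.

    With ``p1 = m * p0`` and ``prev * p1 + (1 - prev) * p0 = p``:
    ``p0 = p / (1 + (m - 1) * prev)``.
    """
    p0 = marginal / (1.0 + (multiplier - 1.0) * prevalence)
    p1 = multiplier * p0
    if p1 > 1.0:
        raise InfeasibleConfigError(
            f"predictor {name!r}: P(factor | CSI) = {p1:.3f} > 1 "
            f"(marginal {marginal}, multiplier {multiplier})"
        )
    return p0, p1


class StratumRates(BaseModel):
    """Per-stratum predictor marginal probabilities."""

    self_reported_neck_pain: float = Field(ge=0, le=1)
    neck_tenderness_exam: float = Field(ge=0, le=1)
    substantial_head_or_torso_injury: float = Field(ge=0, le=1)
    altered_mental_status: float = Field(ge=0, le=1)
    gcs_3_8: float = Field(ge=0, le=1)
    unresponsive: float = Field(ge=0, le=1)
    abnormal_abc: float = Field(ge=0, le=1)
    focal_neuro_deficit: float = Field(ge=0, le=1)
    paresthesias_extremities: float = Field(ge=0, le=1)
    intoxication: float = Field(ge=0, le=1)

    @model_validator(mode="after")
    def _unresponsive_within_gcs38(self):
        if self.unresponsive > self.gcs_3_8 + 1e-12:
            raise ValueError("unresponsive prevalence cannot exceed GCS 3-8 prevalence")
        return self


class StratumMultipliers(BaseModel):
    """Per-predictor risk multipliers, P(factor | CSI) / P(factor | no CSI)."""

    self_reported_neck_pain: float = Field(gt=0)
    neck_tenderness_exam: float = Field(gt=0)
    substantial_head_or_torso_injury: float = Field(gt=0)
    altered_mental_status: float = Field(gt=0)
    gcs_3_8: float = Field(gt=0)
    abnormal_abc: float = Field(gt=0)
    focal_neuro_deficit: float = Field(gt=0)
    paresthesias_extremities: float = Field(gt=0)
    intoxication: float = Field(gt=0)


# Published per-stratum predictor prevalences; high-risk factors had
# "similar proportions in both age groups" and use the overall figure.
RATES_0_8 = StratumRates(
    self_reported_neck_pain=0.107,
    neck_tenderness_exam=0.079,
    substantial_head_or_torso_injury=0.138,
    altered_mental_status=0.097,
    gcs_3_8=0.023,
    unresponsive=0.015,
    abnormal_abc=0.044,
    focal_neuro_deficit=0.027,
    paresthesias_extremities=0.02,
    intoxication=0.0,
)
RATES_9_17 = StratumRates(
    self_reported_neck_pain=0.321,
    neck_tenderness_exam=0.258,
    substantial_head_or_torso_injury=0.075,
    altered_mental_status=0.097,
    gcs_3_8=0.023,
    unresponsive=0.015,
    abnormal_abc=0.044,
    focal_neuro_deficit=0.027,
    paresthesias_extremities=0.03,
    intoxication=0.02,
)

# Multipliers calibrated analytically (closed-form union probabilities under
# the coupling structure) against the published rule sensitivities; younger
# children need stronger association because their factor base rates are lower.
MULT_0_8 = StratumMultipliers(
    self_reported_neck_pain=4.0,
    neck_tenderness_exam=4.0,
    substantial_head_or_torso_injury=3.0,
    altered_mental_status=4.0,
    gcs_3_8=10.0,
    abnormal_abc=10.0,
    focal_neuro_deficit=10.0,
    paresthesias_extremities=10.0,
    intoxication=1.0,
)
MULT_9_17 = StratumMultipliers(
    self_reported_neck_pain=2.0,
    neck_tenderness_exam=2.0,
    substantial_head_or_torso_injury=2.5,
    altered_mental_status=3.0,
    gcs_3_8=6.0,
    abnormal_abc=6.0,
    focal_neuro_deficit=6.0,
    paresthesias_extremities=6.0,
    intoxication=1.5,
)

# Mechanism-of-injury distributions (per-stratum counts from the published
# demographics table, normalized at generation time).
MECHANISM_COUNTS_0_8: dict[Mechanism, int] = {
    Mechanism.MVC: 2948,
    Mechanism.MOTORIZED_RECREATIONAL: 269,
    Mechanism.STRUCK_BY_CAR: 589,
    Mechanism.FALL: 5054,
    Mechanism.DIVING: 4,
    Mechanism.SPORTS: 340,
    Mechanism.CHILD_ABUSE: 1246,
    Mechanism.ASSAULT: 51,
    Mechanism.OTHER: 620,
    Mechanism.UNKNOWN: 512,
}
MECHANISM_COUNTS_9_17: dict[Mechanism, int] = {
    Mechanism.MVC: 3410,
    Mechanism.MOTORIZED_RECREATIONAL: 981,
    Mechanism.STRUCK_BY_CAR: 866,
    Mechanism.FALL: 2390,
    Mechanism.DIVING: 34,
    Mechanism.SPORTS: 1879,
    Mechanism.CHILD_ABUSE: 81,
    Mechanism.ASSAULT: 484,
    Mechanism.OTHER: 611,
    Mechanism.UNKNOWN: 61,
}

# Observed imaging distributions per stratum (no imaging / radiography / CT /
# MRI only / other), used for children without CSI; children with CSI are
# always imaged (CT-weighted) since CSI was radiologically confirmed.
IMAGING_COUNTS_0_8 = {
    ObservedImaging.NONE: 5018,
    ObservedImaging.RADIOGRAPHY: 5206,
    ObservedImaging.CT: 1380,
    ObservedImaging.MRI_ONLY: 23,
    ObservedImaging.OTHER: 6,
}
IMAGING_COUNTS_9_17 = {
    ObservedImaging.NONE: 4552,
    ObservedImaging.RADIOGRAPHY: 3706,
    ObservedImaging.CT: 2476,
    ObservedImaging.MRI_ONLY: 53,
    ObservedImaging.OTHER: 10,
}

# Probability that a given mechanism carries a CCR "dangerous mechanism"
# sub-flag, and which flag it maps to. Motorized recreational vehicles are
# dangerous by definition.
MECHANISM_DANGEROUS: dict[Mechanism, tuple[float, MechanismDetail]] = {
    Mechanism.MVC: (0.20, MechanismDetail.MVC_HIGH_SPEED),
    Mechanism.MOTORIZED_RECREATIONAL: (1.0, MechanismDetail.MOTORIZED_REC_VEHICLE),
    Mechanism.STRUCK_BY_CAR: (0.20, MechanismDetail.BICYCLE_COLLISION),
    Mechanism.FALL: (0.20, MechanismDetail.FALL_GE_1M),
    Mechanism.DIVING: (0.90, MechanismDetail.AXIAL_LOAD),
    Mechanism.SPORTS: (0.08, MechanismDetail.AXIAL_LOAD),
    Mechanism.CHILD_ABUSE: (0.05, MechanismDetail.AXIAL_LOAD),
    Mechanism.ASSAULT: (0.05, MechanismDetail.AXIAL_LOAD),
    Mechanism.OTHER: (0.05, MechanismDetail.FALL_GE_1M),
    Mechanism.UNKNOWN: (0.02, MechanismDetail.FALL_GE_1M),
}


class GeneratorConfig(BaseModel):
    """Study-condition parameters for the stochastic cohort generator."""

    n: int = Field(default=22430, gt=0)
    csi_prevalence: float = Field(default=0.019, ge=0, le=1)
    age_0_8_share: float = Field(default=11633 / 22430, ge=0, le=1)
    male_share: float = Field(default=0.583, ge=0, le=1)
    seed: int = 20251219

    rates_0_8: StratumRates = RATES_0_8
    rates_9_17: StratumRates = RATES_9_17
    multipliers_0_8: StratumMultipliers = MULT_0_8
    multipliers_9_17: StratumMultipliers = MULT_9_17

    # Marginal-preserving couplings (clinical clustering).
    tenderness_given_neck_pain: float = Field(default=0.70, ge=0, le=1)
    gcs38_given_abnormal_abc: float = Field(default=0.35, ge=0, le=1)
    focal_given_abnormal_abc: float = Field(default=0.30, ge=0, le=1)
    midline_given_tenderness: float = Field(default=0.75, ge=0, le=1)
    midline_base: float = Field(default=0.05, ge=0, le=1)
    dangerous_mechanism_csi_odds: float = Field(default=2.5, gt=0)


DEFAULT_CONFIG = GeneratorConfig()

_AGE_WEIGHTS_0_8 = np.array([2.0, 1.6, 1.4, 1.2, 1.0, 0.9, 0.8, 0.7, 0.6])
_AGE_WEIGHTS_9_17 = np.array([0.6, 0.8, 1.0, 1.2, 1.3, 1.3, 1.2, 1.0, 0.8])

_CSI_IMAGING = (
    (ObservedImaging.CT, 0.55),
    (ObservedImaging.RADIOGRAPHY, 0.30),
    (ObservedImaging.MRI_ONLY, 0.14),
    (ObservedImaging.OTHER, 0.01),
)


def _tri(flag: bool) -> TriState:
    return PRESENT if flag else ABSENT


def _conditional_given(
    name: str, target: float, p_cond: float, given_rate: float
) -> float:
    """Rate among the complement so the class marginal stays at ``target``."""
    rem = (target - p_cond * given_rate) / (1.0 - given_rate)
    if rem < -1e-9 or rem > 1.0:
        raise InfeasibleConfigError(
            f"coupling for {name!r} infeasible: remainder rate {rem:.4f}"
        )
    return min(max(rem, 0.0), 1.0)


def _class_rate(name: str, rates: StratumRates, mult: StratumMultipliers,
                prev: float, csi: bool) -> float:
    p0, p1 = conditional_rates(name, getattr(rates, name), getattr(mult, name), prev)
    return p1 if csi else p0


def _generate_one(
    rng: np.random.Generator,
    idx: int,
    age: int,
    csi: bool,
    rates: StratumRates,
    mult: StratumMultipliers,
    cfg: GeneratorConfig,
    imaging_modalities: list[ObservedImaging],
    imaging_probs: np.ndarray,
    mechanisms: list[Mechanism],
    mechanism_probs: np.ndarray,
) -> PatientRecord:
    prev = cfg.csi_prevalence
    r = lambda name: _class_rate(name, rates, mult, prev, csi)  # noqa: E731

    # Severe-physiology cluster: ABC first, then GCS 3-8 and focal deficit
    # at elevated rates among ABC-abnormal children (marginals preserved).
    p_abc = r("abnormal_abc")
    abc = rng.random() < p_abc
    p_g = r("gcs_3_8")
    gcs38 = rng.random() < (
        min(cfg.gcs38_given_abnormal_abc, 1.0)
        if abc
        else _conditional_given("gcs_3_8", p_g, cfg.gcs38_given_abnormal_abc, p_abc)
    )
    p_f = r("focal_neuro_deficit")
    focal = rng.random() < (
        cfg.focal_given_abnormal_abc
        if abc
        else _conditional_given(
            "focal_neuro_deficit", p_f, cfg.focal_given_abnormal_abc, p_abc
        )
    )

    if gcs38:
        gcs: Optional[int] = int(rng.integers(3, 9))
        unresp_frac = rates.unresponsive / rates.gcs_3_8 if rates.gcs_3_8 else 0.0
        avpu = Avpu.UNRESPONSIVE if rng.random() < unresp_frac else Avpu.PAIN
        ams_manifest = None
    else:
        gcs = 15
        avpu = Avpu.ALERT
        # Altered mental status (GCS 9-14 / verbal-pain AVPU / other signs)
        # is drawn among non-severe children; dividing by 1 - P(GCS 3-8)
        # keeps the construct's class marginal at the configured rate.
        p_ams = r("altered_mental_status") / (1.0 - p_g)
        if p_ams > 1.0:
            raise InfeasibleConfigError("altered_mental_status rate exceeds 1 after coupling")
        if rng.random() < p_ams:
            ams_manifest = rng.choice(["gcs_9_14", "verbal", "other_signs"], p=[0.5, 0.2, 0.3])
            if ams_manifest == "gcs_9_14":
                gcs = int(rng.integers(9, 15))
                avpu = Avpu.VERBAL
            elif ams_manifest == "verbal":
                avpu = Avpu.VERBAL
        else:
            ams_manifest = None

    # Neck pain and examination tenderness are strongly correlated.
    p_pain = r("self_reported_neck_pain")
    pain = rng.random() < p_pain
    p_tender = r("neck_tenderness_exam")
    tender = rng.random() < (
        cfg.tenderness_given_neck_pain
        if pain
        else _conditional_given(
            "neck_tenderness_exam", p_tender, cfg.tenderness_given_neck_pain, p_pain
        )
    )
    midline = rng.random() < (cfg.midline_given_tenderness if tender else cfg.midline_base)

    subst = rng.random() < r("substantial_head_or_torso_injury")
    distracting = subst or rng.random() < 0.02
    paresthesias = rng.random() < r("paresthesias_extremities")
    intox = rates.intoxication > 0 and rng.random() < r("intoxication")

    # Mechanism and CCR sub-flags (dangerous mechanisms are enriched in CSI).
    mechanism = mechanisms[rng.choice(len(mechanisms), p=mechanism_probs)]
    detail: set[MechanismDetail] = set()
    p_danger, flag = MECHANISM_DANGEROUS[mechanism]
    if csi:
        p_danger = min(0.95, p_danger * cfg.dangerous_mechanism_csi_odds)
    if rng.random() < p_danger:
        detail.add(flag)
    elif mechanism is Mechanism.MVC and rng.random() < 0.08:
        detail.add(MechanismDetail.SIMPLE_REAR_END_MVC)

    # NEXUS memory/response items cannot be administered to preverbal children.
    if age < 4:
        remembers, delayed = UNKNOWN, UNKNOWN
    elif ams_manifest is not None:
        remembers = _tri(rng.random() >= 0.6)
        delayed = _tri(rng.random() < 0.4)
    else:
        remembers, delayed = PRESENT, ABSENT

    vitals_abnormal = rng.random() < (0.8 if abc else 0.02)
    sit = ABSENT if gcs < 15 else _tri(rng.random() < 0.85)
    ambulatory = ABSENT if gcs < 15 else _tri(rng.random() < 0.60)
    delayed_onset = _tri(pain and rng.random() < 0.12)
    if gcs < 15:
        rotate = UNKNOWN
    elif pain or tender:
        rotate = _tri(rng.random() >= 0.55)
    else:
        rotate = _tri(rng.random() >= 0.03)

    if csi:
        mods, probs = zip(*_CSI_IMAGING)
        imaging = mods[rng.choice(len(mods), p=np.array(probs) / sum(probs))]
        mgmt = (
            ManagementAnnotation.SURGICAL
            if rng.random() < 0.10
            else ManagementAnnotation.COLLAR
            if rng.random() < 0.60
            else ManagementAnnotation.NONE
        )
    else:
        imaging = imaging_modalities[rng.choice(len(imaging_modalities), p=imaging_probs)]
        mgmt = (
            ManagementAnnotation.COLLAR
            if rng.random() < 0.02
            else ManagementAnnotation.NONE
        )

    return PatientRecord(
        record_id=f"S{idx:06d}",
        age_years=age,
        sex=Sex.MALE if rng.random() < cfg.male_share else Sex.FEMALE,
        mechanism=mechanism,
        mechanism_detail=frozenset(detail),
        gcs_total=gcs,
        avpu=avpu,
        abnormal_abc=_tri(abc),
        focal_neuro_deficit=_tri(focal),
        altered_mental_status_other_signs=_tri(ams_manifest == "other_signs"),
        self_reported_neck_pain=_tri(pain),
        neck_tenderness_exam=_tri(tender),
        posterior_midline_tenderness=_tri(midline),
        substantial_head_or_torso_injury=_tri(subst),
        intoxication=_tri(intox),
        remembers_3_objects=remembers,
        delayed_response=delayed,
        painful_distracting_injury=_tri(distracting),
        paresthesias_extremities=_tri(paresthesias),
        normal_vital_signs=_tri(not vitals_abnormal),
        able_to_sit_in_ed=sit,
        ambulatory_any_time=ambulatory,
        delayed_onset_neck_pain=delayed_onset,
        able_rotate_neck_45=rotate,
        csi_present=csi,
        observed_imaging=imaging,
        management_annotation=mgmt,
    )


def generate_cohort(config: GeneratorConfig | None = None) -> list[PatientRecord]:
    """Draw a synthetic cohort; reproducible given ``config.seed``."""
    cfg = config or DEFAULT_CONFIG
    rng = np.random.default_rng(cfg.seed)

    stratum_data = {}
    for young, rates, mult, mech_counts, img_counts, ages, age_w in (
        (True, cfg.rates_0_8, cfg.multipliers_0_8, MECHANISM_COUNTS_0_8,
         IMAGING_COUNTS_0_8, np.arange(0, 9), _AGE_WEIGHTS_0_8),
        (False, cfg.rates_9_17, cfg.multipliers_9_17, MECHANISM_COUNTS_9_17,
         IMAGING_COUNTS_9_17, np.arange(9, 18), _AGE_WEIGHTS_9_17),
    ):
        mechanisms = list(mech_counts)
        mech_p = np.array([mech_counts[m] for m in mechanisms], dtype=float)
        modalities = list(img_counts)
        img_p = np.array([img_counts[m] for m in modalities], dtype=float)
        stratum_data[young] = (
            rates, mult, mechanisms, mech_p / mech_p.sum(),
            modalities, img_p / img_p.sum(), ages, age_w / age_w.sum(),
        )

    records = []
    for i in range(cfg.n):
        young = rng.random() < cfg.age_0_8_share
        rates, mult, mechanisms, mech_p, modalities, img_p, ages, age_p = stratum_data[young]
        age = int(ages[rng.choice(len(ages), p=age_p)])
        csi = rng.random() < cfg.csi_prevalence
        records.append(
            _generate_one(
                rng, i, age, csi, rates, mult, cfg,
                modalities, img_p, mechanisms, mech_p,
            )
        )
    return records


def marginal_probes() -> dict[str, Callable[[PatientRecord], bool]]:
    """Record-level probes matching each configured predictor marginal.

    Used to verify empirically that generated cohorts honor the configured
    per-stratum prevalences (the altered-mental-status probe excludes
    GCS 3-8 children, who belong to the severe high-risk construct).
    """
    return {
        "self_reported_neck_pain": lambda r: r.self_reported_neck_pain is PRESENT,
        "neck_tenderness_exam": lambda r: r.neck_tenderness_exam is PRESENT,
        "substantial_head_or_torso_injury": (
            lambda r: r.substantial_head_or_torso_injury is PRESENT
        ),
        "altered_mental_status": lambda r: (
            (r.gcs_total is None or r.gcs_total > 8)
            and (
                (r.gcs_total is not None and 9 <= r.gcs_total <= 14)
                or r.avpu in (Avpu.VERBAL, Avpu.PAIN)
                or r.altered_mental_status_other_signs is PRESENT
            )
        ),
        "gcs_3_8": lambda r: r.gcs_total is not None and r.gcs_total <= 8,
        "unresponsive": lambda r: r.avpu is Avpu.UNRESPONSIVE,
        "abnormal_abc": lambda r: r.abnormal_abc is PRESENT,
        "focal_neuro_deficit": lambda r: r.focal_neuro_deficit is PRESENT,
        "paresthesias_extremities": lambda r: r.paresthesias_extremities is PRESENT,
        "intoxication": lambda r: r.intoxication is PRESENT,
    }


# ---------------------------------------------------------------------------
# Table-exact fixture
# ---------------------------------------------------------------------------

# Published per-stratum confusion counts (tp, fp, fn, tn) for each rule; the
# overall rows are their exact sums.
TABLE2_COUNTS: dict[tuple[str, str], tuple[int, int, int, int]] = {
    ("pecarn", "age_0_8"): (179, 3675, 14, 7765),
    ("nexus", "age_0_8"): (169, 3210, 24, 8230),
    ("ccr", "age_0_8"): (168, 3568, 25, 7872),
    ("pecarn", "age_9_17"): (225, 5146, 15, 5411),
    ("nexus", "age_9_17"): (202, 4429, 38, 6128),
    ("ccr", "age_9_17"): (225, 5868, 15, 4689),
    ("pecarn", "all"): (404, 8821, 29, 13176),
    ("nexus", "all"): (371, 7639, 62, 14358),
    ("ccr", "all"): (393, 9436, 40, 12561),
}

# Published PECARN tier allocation (radiography_n, ct_n) per stratum.
PECARN_TIERS: dict[str, tuple[int, int]] = {
    "age_0_8": (3163, 691),
    "age_9_17": (4513, 858),
    "all": (7676, 1549),
}

# Observed imaging counts per stratum, as published.
OBSERVED_IMAGING_COUNTS: dict[str, dict[ObservedImaging, int]] = {
    "age_0_8": IMAGING_COUNTS_0_8,
    "age_9_17": IMAGING_COUNTS_9_17,
}

_STRATUM_N = {"age_0_8": 11633, "age_9_17": 10797}


def _fixture_baseline(rid: str, age: int, csi: bool) -> PatientRecord:
    """An archetype record cleared by all three rules before triggers are set."""
    return PatientRecord(
        record_id=rid,
        age_years=age,
        sex=Sex.UNKNOWN,
        mechanism=Mechanism.FALL,
        mechanism_detail=frozenset(),
        gcs_total=15,
        avpu=Avpu.ALERT,
        abnormal_abc=ABSENT,
        focal_neuro_deficit=ABSENT,
        altered_mental_status_other_signs=ABSENT,
        self_reported_neck_pain=ABSENT,
        neck_tenderness_exam=ABSENT,
        posterior_midline_tenderness=ABSENT,
        substantial_head_or_torso_injury=ABSENT,
        intoxication=ABSENT,
        remembers_3_objects=PRESENT,
        delayed_response=ABSENT,
        painful_distracting_injury=ABSENT,
        paresthesias_extremities=ABSENT,
        normal_vital_signs=PRESENT,
        able_to_sit_in_ed=PRESENT,
        ambulatory_any_time=PRESENT,
        delayed_onset_neck_pain=ABSENT,
        able_rotate_neck_45=PRESENT,
        csi_present=csi,
    )


def build_table_exact_fixture() -> list[PatientRecord]:
    """Deterministic 22 430-record cohort reproducing the published counts.

    Construction: within each (age stratum x CSI status) cell, each rule's
    positives occupy a leading index range, driven by a trigger predictor
    private to that rule:

    * PECARN CT tier — abnormal airway/breathing/circulation;
    * PECARN radiography tier — self-reported neck pain;
    * NEXUS — intoxication;
    * CCR — paresthesias in the extremities.

    Because no other rule reads its neighbor's trigger, all nine per-stratum
    confusion rows and the PECARN tier counts are met exactly and no joint
    constraint needs relaxing; the cross-rule overlap pattern itself is
    synthetic (the true joint distribution was never published). PECARN
    true positives are placed in the CT tier (their published CT/radiography
    split is not recoverable from printed counts).

    Observed imaging modalities are assigned per stratum at the published
    counts, CT first so children with CSI carry advanced imaging.
    """
    records: list[PatientRecord] = []
    for stratum, ages in (("age_0_8", range(0, 9)), ("age_9_17", range(9, 18))):
        n_s = _STRATUM_N[stratum]
        tp_p, fp_p, fn_p, tn_p = TABLE2_COUNTS[("pecarn", stratum)]
        tp_n, fp_n, *_ = TABLE2_COUNTS[("nexus", stratum)]
        tp_c, fp_c, *_ = TABLE2_COUNTS[("ccr", stratum)]
        rad_total, ct_total = PECARN_TIERS[stratum]
        csi_n = tp_p + fn_p

        cells = (
            # (cell size, csi?, pecarn ct, pecarn radiography, nexus pos, ccr pos)
            (csi_n, True, tp_p, 0, tp_n, tp_c),
            (n_s - csi_n, False, ct_total - tp_p, rad_total, fp_n, fp_c),
        )
        ages = list(ages)
        stratum_records: list[PatientRecord] = []
        for size, csi, n_ct, n_rad, n_nexus, n_ccr in cells:
            for i in range(size):
                rid = f"F-{stratum}-{'csi' if csi else 'nocsi'}-{i:05d}"
                rec = _fixture_baseline(rid, ages[i % len(ages)], csi)
                updates: dict = {}
                if i < n_ct:
                    updates["abnormal_abc"] = PRESENT
                elif i < n_ct + n_rad:
                    updates["self_reported_neck_pain"] = PRESENT
                if i < n_nexus:
                    updates["intoxication"] = PRESENT
                if i < n_ccr:
                    updates["paresthesias_extremities"] = PRESENT
                if csi:
                    updates["management_annotation"] = (
                        ManagementAnnotation.COLLAR
                        if i % 2 == 0
                        else ManagementAnnotation.NONE
                    )
                if updates:
                    rec = rec.model_copy(update=updates)
                stratum_records.append(rec)

        # Observed imaging at the published stratum counts, CT first.
        assignments: list[ObservedImaging] = []
        for modality in (
            ObservedImaging.CT,
            ObservedImaging.RADIOGRAPHY,
            ObservedImaging.MRI_ONLY,
            ObservedImaging.OTHER,
            ObservedImaging.NONE,
        ):
            assignments.extend([modality] * OBSERVED_IMAGING_COUNTS[stratum][modality])
        stratum_records = [
            rec.model_copy(update={"observed_imaging": modality})
            for rec, modality in zip(stratum_records, assignments, strict=True)
        ]
        records.extend(stratum_records)
    return records
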