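"""Patient-record model, validation, and CSV round-trip I/O.

A :class:`PatientRecord` is one child evaluated for possible cervical spine
injury (CSI) after blunt trauma: demographics, the predictor variables read
by the three prediction rules, the reference-standard CSI status, the
imaging modality actually obtained, and a descriptive injury-management
annotation.

Predictor variables are *tri-state*: ``present`` / ``absent`` / ``unknown``.
The distinction between ``absent`` and ``unknown`` matters because the rule
engines treat them differently (see :mod:`csirules.rules`), so CSV I/O never
coerces one into the other; an empty cell reads as ``unknown``.
"""

from __future__ import annotations

import enum
import logging
from typing import Iterable, Optional, Sequence

import pandas as pd
from pydantic import BaseModel, Field, field_validator

logger = logging.getLogger(__name__)


class TriState(str, enum.Enum):
    PRESENT = "present"
    ABSENT = "absent"
    UNKNOWN = "unknown"

    def __bool__(self) -> bool:  # pragma: no cover - guard against misuse
        raise TypeError(
            "TriState has no truth value; compare against TriState.PRESENT etc."
        )


class Avpu(str, enum.Enum):
    ALERT = "alert"
    VERBAL = "verbal"
    PAIN = "pain"
    UNRESPONSIVE = "unresponsive"
    UNKNOWN = "unknown"


class Sex(str, enum.Enum):
    FEMALE = "female"
    MALE = "male"
    UNKNOWN = "unknown"


class Mechanism(str, enum.Enum):
    """Injury mechanism categories."""

    MVC = "motor_vehicle_crash"
    MOTORIZED_RECREATIONAL = "motorcycle_atv_motorized_scooter"
    STRUCK_BY_CAR = "struck_by_car"
    FALL = "fall"
    DIVING = "diving"
    SPORTS = "sports_recreation"
    CHILD_ABUSE = "suspected_child_abuse"
    ASSAULT = "assault"
    OTHER = "other"
    UNKNOWN = "unknown"


class MechanismDetail(str, enum.Enum):
    """Mechanism sub-flags read by the Canadian C-spine Rule.

    The first five constitute the CCR "dangerous mechanism" category; a
    simple rear-end motor vehicle crash is instead one of the CCR low-risk
    criteria.
    """

    FALL_GE_1M = "fall_ge_1m_5stairs"
    AXIAL_LOAD = "axial_load_to_head"
    MVC_HIGH_SPEED = "mvc_high_speed_rollover_ejection"
    MOTORIZED_REC_VEHICLE = "motorized_recreational_vehicle"
    BICYCLE_COLLISION = "bicycle_collision"
    SIMPLE_REAR_END_MVC = "simple_rear_end_mvc"


DANGEROUS_MECHANISM_FLAGS = frozenset(
    {
        MechanismDetail.FALL_GE_1M,
        MechanismDetail.AXIAL_LOAD,
        MechanismDetail.MVC_HIGH_SPEED,
        MechanismDetail.MOTORIZED_REC_VEHICLE,
        MechanismDetail.BICYCLE_COLLISION,
    }
)


class ObservedImaging(str, enum.Enum):
    NONE = "none"
    RADIOGRAPHY = "radiography"
    CT = "ct"
    MRI_ONLY = "mri_only"
    OTHER = "other"


class ManagementAnnotation(str, enum.Enum):
    """Descriptive injury-management annotation; excluded from all statistics."""

    NONE = "none"
    COLLAR = "collar"
    BRACE = "brace"
    HALO = "halo"
    SURGICAL = "surgical"


#: Tri-state predictor fields, in canonical (CSV header) order.
TRISTATE_FIELDS: tuple[str, ...] = (
    "abnormal_abc",
    "focal_neuro_deficit",
    "altered_mental_status_other_signs",
    "self_reported_neck_pain",
    "neck_tenderness_exam",
    "posterior_midline_tenderness",
    "substantial_head_or_torso_injury",
    "intoxication",
    "remembers_3_objects",
    "delayed_response",
    "painful_distracting_injury",
    "paresthesias_extremities",
    "normal_vital_signs",
    "able_to_sit_in_ed",
    "ambulatory_any_time",
    "delayed_onset_neck_pain",
    "able_rotate_neck_45",
)


class PatientRecord(BaseModel):
    """One child evaluated for possible CSI after blunt trauma."""

    model_config = {"use_enum_values": False, "validate_assignment": True}

    record_id: str
    age_years: int = Field(ge=0, le=17)
    sex: Sex = Sex.UNKNOWN
    mechanism: Mechanism = Mechanism.UNKNOWN
    mechanism_detail: frozenset[MechanismDetail] = frozenset()
    gcs_total: Optional[int] = Field(default=None, ge=3, le=15)
    avpu: Avpu = Avpu.UNKNOWN

    abnormal_abc: TriState = TriState.UNKNOWN
    focal_neuro_deficit: TriState = TriState.UNKNOWN
    altered_mental_status_other_signs: TriState = TriState.UNKNOWN
    self_reported_neck_pain: TriState = TriState.UNKNOWN
    neck_tenderness_exam: TriState = TriState.UNKNOWN
    posterior_midline_tenderness: TriState = TriState.UNKNOWN
    substantial_head_or_torso_injury: TriState = TriState.UNKNOWN
    intoxication: TriState = TriState.UNKNOWN
    remembers_3_objects: TriState = TriState.UNKNOWN
    delayed_response: TriState = TriState.UNKNOWN
    painful_distracting_injury: TriState = TriState.UNKNOWN
    paresthesias_extremities: TriState = TriState.UNKNOWN
    normal_vital_signs: TriState = TriState.UNKNOWN
    able_to_sit_in_ed: TriState = TriState.UNKNOWN
    ambulatory_any_time: TriState = TriState.UNKNOWN
    delayed_onset_neck_pain: TriState = TriState.UNKNOWN
    able_rotate_neck_45: TriState = TriState.UNKNOWN

    csi_present: bool = False
    observed_imaging: ObservedImaging = ObservedImaging.NONE
    management_annotation: ManagementAnnotation = ManagementAnnotation.NONE

    @field_validator("mechanism_detail", mode="before")
    @classmethod
    def _parse_detail(cls, v):
        if isinstance(v, str):
            v = frozenset(
                MechanismDetail(tok) for tok in v.split(";") if tok.strip()
            )
        return frozenset(v) if v is not None else frozenset()

    def avpu_gcs_consistent(self) -> bool:
        """True unless AVPU says unresponsive while GCS is known and > 8."""
        if self.avpu is Avpu.UNRESPONSIVE and self.gcs_total is not None:
            return self.gcs_total <= 8
        return True


#: Canonical CSV column order.
CSV_COLUMNS: tuple[str, ...] = (
    "record_id",
    "age_years",
    "sex",
    "mechanism",
    "mechanism_detail",
    "gcs_total",
    "avpu",
    *TRISTATE_FIELDS,
    "csi_present",
    "observed_imaging",
    "management_annotation",
)


class CohortValidationError(ValueError):
    """A record failed validation; message names the record and field."""


class CohortStratum:
    """A labelled sub-cohort: ``all``, ``age_0_8`` or ``age_9_17``."""

    VALID_LABELS = ("all", "age_0_8", "age_9_17")

    def __init__(self, label: str, records: Sequence[PatientRecord]):
        if label not in self.VALID_LABELS:
            raise ValueError(f"unknown stratum label {label!r}")
        records = list(records)
        if label == "age_0_8" and any(r.age_years > 8 for r in records):
            raise ValueError("age_0_8 stratum contains a record older than 8")
        if label == "age_9_17" and any(r.age_years < 9 for r in records):
            raise ValueError("age_9_17 stratum contains a record younger than 9")
        self.label = label
        self.records = records

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)

    def __repr__(self) -> str:  # pragma: no cover
        return f"CohortStratum({self.label!r}, n={len(self)})"


def stratify_by_age(
    records: Iterable[PatientRecord],
) -> tuple[CohortStratum, CohortStratum]:
    """Partition a cohort at the 8/9-year boundary.

    Children 8 years old or younger have anatomic differences (fulcrum
    higher in the cervical spine, proportionally larger head) that change
    both the risk and the typical level of CSI, which is why accuracy is
    reported separately for the two groups.
    """
    young = [r for r in records if r.age_years <= 8]
    old = [r for r in records if r.age_years >= 9]
    return CohortStratum("age_0_8", young), CohortStratum("age_9_17", old)


def _record_to_row(r: PatientRecord) -> dict:
    row = {
        "record_id": r.record_id,
        "age_years": r.age_years,
        "sex": r.sex.value,
        "mechanism": r.mechanism.value,
        "mechanism_detail": ";".join(sorted(d.value for d in r.mechanism_detail)),
        "gcs_total": "" if r.gcs_total is None else r.gcs_total,
        "avpu": r.avpu.value,
        "csi_present": str(r.csi_present).lower(),
        "observed_imaging": r.observed_imaging.value,
        "management_annotation": r.management_annotation.value,
    }
    for f in TRISTATE_FIELDS:
        row[f] = getattr(r, f).value
    return row


def write_cohort(records: Iterable[PatientRecord], path) -> None:
    """Write records to CSV with the canonical header (UTF-8, one row each)."""
    df = pd.DataFrame([_record_to_row(r) for r in records], columns=CSV_COLUMNS)
    df.to_csv(path, index=False)


def _row_to_record(row: dict) -> PatientRecord:
    kwargs = dict(row)
    for f in TRISTATE_FIELDS:
        val = kwargs.get(f, "")
        kwargs[f] = TriState(val) if val else TriState.UNKNOWN
    gcs = kwargs.get("gcs_total", "")
    kwargs["gcs_total"] = int(float(gcs)) if str(gcs).strip() else None
    kwargs["avpu"] = Avpu(kwargs["avpu"]) if kwargs.get("avpu") else Avpu.UNKNOWN
    kwargs["sex"] = Sex(kwargs["sex"]) if kwargs.get("sex") else Sex.UNKNOWN
    kwargs["mechanism"] = (
        Mechanism(kwargs["mechanism"]) if kwargs.get("mechanism") else Mechanism.UNKNOWN
    )
    csi = str(kwargs.get("csi_present", "false")).strip().lower()
    if csi not in {"true", "false"}:
        raise ValueError(f"csi_present must be true/false, got {csi!r}")
    kwargs["csi_present"] = csi == "true"
    kwargs["observed_imaging"] = (
        ObservedImaging(kwargs["observed_imaging"])
        if kwargs.get("observed_imaging")
        else ObservedImaging.NONE
    )
    kwargs["management_annotation"] = (
        ManagementAnnotation(kwargs["management_annotation"])
        if kwargs.get("management_annotation")
        else ManagementAnnotation.NONE
    )
    return PatientRecord(**kwargs)


def read_cohort(path, strict: bool = True) -> list[PatientRecord]:
    """Read a cohort CSV, validating every record.

    Parameters
    ----------
    path
        CSV file with the canonical header (:data:`CSV_COLUMNS`).
    strict
        If True (default), abort on the first malformed row with a
        :class:`CohortValidationError` naming the record and field.
        Otherwise skip malformed rows and log how many were dropped.

    Unknown tri-states are preserved as ``unknown``, never coerced to
    ``absent``. A record whose AVPU says unresponsive while GCS > 8 is
    accepted with a logged warning (the generator never emits one).
    """
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    missing = [c for c in CSV_COLUMNS if c not in df.columns]
    if missing:
        raise CohortValidationError(f"cohort CSV missing columns: {missing}")
    records: list[PatientRecord] = []
    skipped = 0
    for _, row in df.iterrows():
        rid = row.get("record_id", "<missing id>")
        try:
            rec = _row_to_record(row.to_dict())
        except Exception as exc:
            msg = f"record {rid!r}: invalid row ({exc})"
            if strict:
                raise CohortValidationError(msg) from exc
            skipped += 1
            logger.warning(msg)
            continue
        if not rec.avpu_gcs_consistent():
            logger.warning(
                "record %r: AVPU unresponsive but GCS %s > 8", rid, rec.gcs_total
            )
        records.append(rec)
    if skipped:
        logger.warning("skipped %d malformed rows from %s", skipped, path)
    return records
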