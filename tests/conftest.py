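"""Shared fixtures: the table-exact cohort, generated cohorts, random records."""

from __future__ import annotations

import numpy as np
import pytest

from csirules import GeneratorConfig, generate_cohort
from csirules.records import (
    Avpu,
    Mechanism,
    MechanismDetail,
    ObservedImaging,
    PatientRecord,
    TriState,
)
from csirules.simulate import build_table_exact_fixture

TRI = (TriState.PRESENT, TriState.ABSENT, TriState.UNKNOWN)


def make_random_records(n: int, seed: int) -> list[PatientRecord]:
    """Arbitrary valid records spanning the whole predictor space.

    Unlike the calibrated generator, every field is drawn uniformly and
    independently, so edge combinations (all-unknown, contradictory flags)
    are well represented for property testing.
    """
    rng = np.random.default_rng(seed)
    mechs = list(Mechanism)
    details = list(MechanismDetail)
    imaging = list(ObservedImaging)
    out = []
    tristate_fields = [
        f for f, t in PatientRecord.model_fields.items()
        if t.annotation is TriState
    ]
    for i in range(n):
        kwargs = {
            "record_id": f"R{i:06d}",
            "age_years": int(rng.integers(0, 18)),
            "mechanism": mechs[rng.integers(len(mechs))],
            "mechanism_detail": frozenset(
                d for d in details if rng.random() < 0.1
            ),
            "gcs_total": None if rng.random() < 0.1 else int(rng.integers(3, 16)),
            "avpu": list(Avpu)[rng.integers(len(Avpu))],
            "csi_present": bool(rng.random() < 0.3),
            "observed_imaging": imaging[rng.integers(len(imaging))],
        }
        for f in tristate_fields:
            kwargs[f] = TRI[rng.integers(3)]
        out.append(PatientRecord(**kwargs))
    return out


@pytest.fixture(scope="session")
def fixture_cohort():
    return build_table_exact_fixture()


@pytest.fixture(scope="session")
def default_cohort():
    """Default-configuration synthetic cohort (n=22 430, fixed seed)."""
    return generate_cohort(GeneratorConfig())


@pytest.fixture(scope="session")
def large_cohort():
    """Large cohort for law-of-large-numbers marginal checks."""
    return generate_cohort(GeneratorConfig(n=100_000, seed=20251219))


@pytest.fixture(scope="session")
def random_records():
    return make_random_records(1500, seed=7)
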