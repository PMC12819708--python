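"""Shared fixtures and strategies for the pulpdta test suite."""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import strategies as st

from pulpdta.cohort import (
    Cohort,
    PatientRecord,
    SyntheticConfig,
    canonical_fixture,
)


@pytest.fixture(scope="session")
def fixture_cohort() -> Cohort:
    return canonical_fixture()


def make_cohort(pos_values, neg_values) -> Cohort:
    """Minimal cohort: positives get pain category 3, negatives 1."""
    records = []
    for i, v in enumerate(pos_values):
        records.append(PatientRecord(
            patient_id=f"pos{i}", hs_crp=float(v), below_lod=v == 0.0,
            vas=8.0, pain_category=3))
    for i, v in enumerate(neg_values):
        records.append(PatientRecord(
            patient_id=f"neg{i}", hs_crp=float(v), below_lod=v == 0.0,
            vas=3.0, pain_category=1))
    return Cohort(tuple(records), provenance="synthetic")


@st.composite
def patient_records(draw: st.DrawFn, patient_id: str) -> PatientRecord:
    censored = draw(st.booleans())
    if censored:
        hs_crp = 0.0
    else:
        hs_crp = draw(st.floats(min_value=0.5, max_value=200.0,
                                allow_nan=False))
    return PatientRecord(
        patient_id=patient_id,
        hs_crp=hs_crp,
        below_lod=censored,
        vas=draw(st.floats(min_value=0.0, max_value=10.0, allow_nan=False)),
        pain_category=draw(st.integers(min_value=0, max_value=3)),
        tooth_type=draw(st.sampled_from(
            [None, "molar", "premolar", "incisor", "other"])),
    )


@st.composite
def cohorts(draw: st.DrawFn, min_size: int = 1,
            max_size: int = 20) -> Cohort:
    n = draw(st.integers(min_value=min_size, max_value=max_size))
    records = tuple(draw(patient_records(f"H{i:03d}")) for i in range(n))
    return Cohort(records, provenance="file")
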