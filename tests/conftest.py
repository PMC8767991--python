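"""Shared fixtures: the default hierarchy, hand-built visit frames, and
seeded synthetic cohorts at desk scale."""

from __future__ import annotations

import pandas as pd
import pytest

from icdvar import PartitionSpec, load_hierarchy
from icdvar.synthetic import default_config, generate


@pytest.fixture(scope="session")
def hierarchy():
    return load_hierarchy()


@pytest.fixture(scope="session")
def years():
    return PartitionSpec.years(2019, 2020)


def make_visits(rows):
    """Build a canonical visit frame from (date, modality, specialty, sex,
    age, codes) tuples."""
    return pd.DataFrame({
        "visit_id": [f"v{i}" for i in range(len(rows))],
        "patient_id": [f"p{i % 3}" for i in range(len(rows))],
        "date": pd.to_datetime([r[0] for r in rows]),
        "modality": [r[1] for r in rows],
        "specialty": [r[2] for r in rows],
        "sex": [r[3] for r in rows],
        "age": [r[4] for r in rows],
        "codes": [r[5] for r in rows],
    })


@pytest.fixture()
def small_visits():
    return make_visits([
        ("2019-03-04", "face_to_face", "general_medicine", "female", 54, "I10;E11"),
        ("2019-06-10", "face_to_face", "nursing", "male", 67, "I10;I10"),
        ("2019-09-21", "telemedicine", "general_medicine", "female", 30, "Z20"),
        ("2019-11-02", "face_to_face", "pediatrics", "male", 4, ""),
        ("2020-02-14", "telemedicine", "general_medicine", "female", 41, "Z20;J06"),
        ("2020-05-30", "telemedicine", "nursing", "male", 78, "E119"),
        ("2020-08-15", "face_to_face", "general_medicine", "female", 15, "M54;T14"),
        ("2020-12-01", "telemedicine", "general_medicine", "male", 62, ""),
        ("2021-01-05", "face_to_face", "general_medicine", "female", 50, "I10"),
    ])


@pytest.fixture(scope="session")
def cohort_100k():
    """~100k-visit synthetic cohort (~110k codes), reference-calibrated."""
    return generate(default_config(seed=7, scale=0.035))


@pytest.fixture(scope="session")
def cohort_100k_config():
    return default_config(seed=7, scale=0.035)


@pytest.fixture(scope="session")
def cohort_1k():
    """Tiny cohort for brute-force oracle comparisons."""
    return generate(default_config(seed=11, scale=0.00035))
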