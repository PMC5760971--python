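import numpy as np
import pandas as pd
import pytest

from tgi_cutoff.io import ALL_COLUMNS


def make_subject(subject_id="S1", **overrides):
    """One fully-valid subject row as a dict; override any field."""
    row = {
        "subject_id": subject_id,
        "sex": "female",
        "ethnicity": "mixed",
        "age": 35,
        "waist": 80.0,
        "weight": 62.0,
        "height": 160.0,
        "sbp": 110.0,
        "dbp": 70.0,
        "glucose": 90.0,
        "triglycerides": 100.0,
        "total_cholesterol": 180.0,
        "hdl": 50.0,
        "insulin": 8.0,
        "dm2": 0,
        "coronary_disease": 0,
        "arrhythmia": 0,
        "cerebrovascular_disease": 0,
        "pcos": 0,
        "lipid_lowering_drugs": 0,
    }
    row.update(overrides)
    return row


@pytest.fixture
def toy_cohort_df():
    """Three valid subjects spanning both sexes."""
    return pd.DataFrame(
        [
            make_subject("S1"),
            make_subject("S2", sex="male", age=52, glucose=105.0, triglycerides=160.0),
            make_subject("S3", age=24, insulin=5.5, triglycerides=75.0),
        ],
        columns=list(ALL_COLUMNS),
    )


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
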