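import numpy as np
import pandas as pd
import pytest

from obgrs.cohort import SNPAnnotation, load_cohort


@pytest.fixture
def tcf7l2():
    return SNPAnnotation("rs7903146", "TCF7L2", "C", "T", "T")


def make_phenotype_frame(n=5, genotypes=None, **overrides):
    """Small deterministic phenotype table for loader tests."""
    rng = np.random.default_rng(42)
    df = pd.DataFrame(
        {
            "subject_id": [f"P{i}" for i in range(n)],
            "age": np.linspace(60, 75, n).round(1),
            "sex": ["male", "female"] * (n // 2) + ["male"] * (n % 2),
            "center": ["C1"] * n,
            "arm": ["control"] * n,
            "bmi": np.linspace(24, 36, n).round(1),
            "t2d_prevalent": [False] * n,
            "followup_years": np.linspace(1.0, 6.0, n).round(1),
            "t2d_incident": [False] * n,
            "energy_kcal": rng.normal(2200, 300, n).round(0),
            "meddiet_score": [9] * n,
            "alcohol_g": [5.0] * n,
            "smoker": [False] * n,
            "physical_activity": [200.0] * n,
            "dyslipidemia": [True] * n,
            "hypertension": [True] * n,
        }
    )
    if genotypes is not None:
        for snp, calls in genotypes.items():
            df["snp:" + snp] = calls
    for col, values in overrides.items():
        df[col] = values
    return df


@pytest.fixture
def small_cohort(tcf7l2):
    df = make_phenotype_frame(5, genotypes={"rs7903146": ["CC", "CT", "TT", "CT", "CC"]})
    return load_cohort(df, annotations=[tcf7l2])
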