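import numpy as np
import pandas as pd
import pytest

from ascmaturity.cohort import CohortTable
from ascmaturity.harmonize import MATURITY_MARKERS


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def make_cohort(n=40, n_datasets=4, seed=0, missing_frac=0.0, dpi_range=(5, 180)):
    """Small synthetic cohort table with optional MCAR missingness."""
    rng = np.random.default_rng(seed)
    dpis = rng.uniform(*dpi_range, size=n)
    df = pd.DataFrame({
        "sample_id": [f"s{i:03d}" for i in range(n)],
        "dataset_id": [f"d{i % n_datasets}" for i in range(n)],
        "subject_id": [f"subj{i // 2}" for i in range(n)],
        "dpi": dpis,
        "age": rng.uniform(18, 70, size=n),
        "sex": rng.choice(["F", "M"], size=n),
        "tissue": "blood",
        "asc_count": rng.integers(60, 500, size=n),
    })
    for k, m in enumerate(MATURITY_MARKERS):
        df[m] = np.sin(dpis / (10 + 5 * k)) + rng.normal(0, 0.2, size=n)
    if missing_frac:
        mask = rng.random((n, len(MATURITY_MARKERS))) < missing_frac
        block = df[list(MATURITY_MARKERS)].to_numpy()
        block[mask] = np.nan
        df[list(MATURITY_MARKERS)] = block
    return CohortTable(df=df)


@pytest.fixture
def small_cohort():
    return make_cohort(n=40, seed=1)


@pytest.fixture
def missing_cohort():
    return make_cohort(n=60, seed=2, missing_frac=0.25)
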