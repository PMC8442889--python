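import numpy as np
import pandas as pd
import pytest

from painclust.schema import SYMPTOMS
from painclust.simulate import GeneratorConfig, default_profiles, simulate_baseline


@pytest.fixture(scope="session")
def profiles():
    return default_profiles()


@pytest.fixture(scope="session")
def table_means(profiles):
    """3x9 matrix of published per-cluster clustering-symptom means."""
    return profiles.means.loc[list(SYMPTOMS)].T  # rows: clusters 1..3


@pytest.fixture(scope="session")
def clean_cohort():
    """Uncorrelated synthetic baseline cohort at the published profiles."""
    cfg = GeneratorConfig(n=3000, correlation=0.0, seed=20260926)
    return simulate_baseline(cfg)


def make_cohort_frame(n=5, seed=0, **overrides):
    """Minimal valid cohort DataFrame for IO tests."""
    rng = np.random.default_rng(seed)
    df = pd.DataFrame(
        {
            "patient_id": [f"P{i:03d}" for i in range(n)],
            "timepoint": "baseline",
            "assessment_date": "2020-01-01",
            "completed": True,
            "age": 40,
        }
    )
    for s in SYMPTOMS:
        df[s] = rng.normal(50, 10, size=n).round(1)
    for col, val in overrides.items():
        df[col] = val
    return df
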