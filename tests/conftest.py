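import warnings

import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

import rwemu

settings.register_profile("ci", derandomize=True, max_examples=25, deadline=None)
settings.load_profile("ci")

warnings.filterwarnings("ignore", category=FutureWarning)


@pytest.fixture(scope="session")
def small_cohort() -> rwemu.PatientTable:
    """Default confounded aNSCLC-like cohort at desk scale."""
    return rwemu.generate_base_cohort(rwemu.CohortConfig(n_patients=2500, seed=11))


@pytest.fixture(scope="session")
def feature_matrix(small_cohort) -> pd.DataFrame:
    return rwemu.build_feature_matrix(small_cohort)


@pytest.fixture(scope="session")
def nsclc_trial() -> rwemu.TrialSpec:
    return rwemu.example_trial_spec("aNSCLC-like")


@pytest.fixture(scope="session")
def risk_scores(small_cohort, feature_matrix) -> pd.Series:
    """Fast benchmark-Cox mortality scores for the small cohort."""
    model = rwemu.fit_benchmark_cox(
        feature_matrix, ["age", "albumin", "hemoglobin", "ecog_cat", "weight_pct_change"]
    )
    return pd.Series(
        model.predict_risk(feature_matrix),
        index=pd.Index(feature_matrix["patient_id"]),
        name="risk_score",
    )


def exp_survival_sample(n, lam=0.08, censor=30.0, beta=0.5, seed=0):
    """Single-covariate exponential survival data with admin censoring."""
    rng = np.random.default_rng(seed)
    x = rng.normal(size=n)
    t_death = rng.exponential(1.0 / (lam * np.exp(beta * x)))
    time = np.minimum(t_death, censor)
    event = (t_death <= censor).astype(int)
    return time, event, x
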