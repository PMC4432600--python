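import numpy as np
import pandas as pd
import pytest

import circannual as ca


def make_meta(n, seed=0, start="2010-01-01", span_days=730, subjects=None):
    """Minimal valid sample metadata with random dates."""
    rng = np.random.default_rng(seed)
    dates = pd.to_datetime(start) + pd.to_timedelta(
        rng.integers(0, span_days + 1, size=n), unit="D")
    return pd.DataFrame({
        "sample_id": [f"V{i:05d}" for i in range(n)],
        "subject_id": subjects if subjects is not None else [f"S{i:05d}" for i in range(n)],
        "date": [d.date().isoformat() for d in dates],
        "age": rng.uniform(1, 10, size=n).round(2),
        "sex": rng.choice(["F", "M"], size=n),
    })


@pytest.fixture(scope="session")
def small_study():
    cfg = ca.SimulationConfig(n_subjects=30, visits_per_subject=4, n_features=60,
                              frac_seasonal=0.3, acrophase_mode="winter", seed=42)
    return ca.simulate_cohort(cfg)


@pytest.fixture(scope="session")
def mixed_spec():
    return ca.ModelSpec(fixed_covariates=["age", "sex"],
                        random_intercepts=["subject_id"])


@pytest.fixture(scope="session")
def ols_spec():
    return ca.ModelSpec()
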