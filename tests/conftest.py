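import matplotlib
import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

matplotlib.use("Agg")

settings.register_profile(
    "suite",
    deadline=None,
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20230313)


@pytest.fixture(scope="session")
def small_cohort():
    """A modest multi-site cohort shared by read-only tests."""
    from normbench.synthetic import CohortConfig, generate_cohort

    cfg = CohortConfig(n_sites=3, subjects_per_site=80, n_features=6, seed=42)
    cov, features, truth = generate_cohort(cfg)
    return cfg, cov, features, truth


@pytest.fixture(scope="session")
def three_site_covariates():
    """Covariate table with three sites for design-matrix tests."""
    rng = np.random.default_rng(7)
    n = 120
    return pd.DataFrame(
        {
            "age": rng.uniform(10, 80, n),
            "sex": rng.integers(0, 2, n),
            "site": np.repeat(["a", "b", "c"], n // 3),
            "qc": rng.gamma(3.0, 1.2, n),
        },
        index=pd.Index([f"sub-{i:03d}" for i in range(n)], name="subject_id"),
    )
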