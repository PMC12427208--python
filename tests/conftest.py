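import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

from sarcotype import CohortConfig, gen_cohort

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


SMALL_CONFIG = CohortConfig(
    n_samples=60,
    n_subtypes=3,
    n_genes=300,
    markers_per_subtype_per_direction=12,
    hazards_per_month=(0.010, 0.030, 0.028),
    seed=5,
)


@pytest.fixture(scope="session")
def small_cohort():
    """A compact 3-subtype cohort for fast module-level tests."""
    return gen_cohort(SMALL_CONFIG)


@pytest.fixture()
def toy_counts():
    """3-gene x 4-sample toy count matrix with hand-checkable CPMs."""
    from sarcotype import CountMatrix

    values = pd.DataFrame(
        [[100, 0, 50, 5], [0, 0, 0, 0], [10, 1, 2, 0]],
        index=["gA", "gB", "gC"],
        columns=["s1", "s2", "s3", "s4"],
    )
    lib = pd.Series([1e6, 1e6, 1e6, 1e6], index=values.columns)
    return CountMatrix(values, libsize=lib)


@pytest.fixture(scope="session")
def two_group_survival():
    """Exponential two-group data with true hazard ratio 2, light censoring."""
    rng = np.random.default_rng(21)
    n = 2000
    grp = rng.integers(0, 2, n)
    lam = np.where(grp == 1, 0.04, 0.02)
    t = rng.exponential(1.0 / lam)
    c = rng.exponential(1.0 / 0.005, n)
    return pd.DataFrame(
        {
            "time": np.minimum(t, c),
            "event": (t <= c).astype(int),
            "grp": grp.astype(float),
        }
    )
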