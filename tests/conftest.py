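import numpy as np
import pandas as pd
import pytest

from utilmap import GeneratorConfig, make_cohort


@pytest.fixture(scope="session")
def default_cohort() -> pd.DataFrame:
    """A medium default-condition cohort shared across read-only tests."""
    return make_cohort(GeneratorConfig(n_subjects=1050, seed=20230223))


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)


def linear_cohort(n: int = 200, seed: int = 0, noise: float = 0.0) -> pd.DataFrame:
    """Cohort whose utility is an exact (optionally noisy) linear function of
    the total score, with no ceiling observations — handy for degenerate-limit
    checks."""
    cohort = make_cohort(GeneratorConfig(n_subjects=n, seed=seed))
    rng_ = np.random.default_rng(seed + 1)
    u = 0.2 + 0.005 * cohort["total"].to_numpy(dtype=float)
    if noise:
        u = u + rng_.normal(0.0, noise, n)
    cohort["utility"] = np.clip(u, -0.391, 0.999)
    return cohort
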