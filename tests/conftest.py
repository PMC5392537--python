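import numpy as np
import pytest

from epiage.cohort import AgeTrendSpec, CohortSpec, default_cohort_spec, generate_cohort
from epiage.panel import default_panel


@pytest.fixture(scope="session")
def panel():
    return default_panel()


@pytest.fixture(scope="session")
def small_cohort():
    """n=300 cohort with the default 45-CpG trend set."""
    spec = default_cohort_spec(n_samples=300, seed=11)
    matrix, truth = generate_cohort(spec)
    return matrix, truth


def make_linear_spec(n=200, slope=0.005, intercept=0.2, noise_sd=0.0, seed=0, **kw):
    """Single linear CpG cohort, convenient for exact-value checks."""
    trend = AgeTrendSpec("cg00000001", "linear", (intercept, slope), noise_sd,
                         "increasing" if slope > 0 else "none")
    return CohortSpec(n_samples=n, trend_specs=(trend,), seed=seed, **kw)
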