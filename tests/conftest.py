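import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

import stratmatch as sm

settings.register_profile(
    "ci", derandomize=True, deadline=None, suppress_health_check=list(HealthCheck)
)
settings.load_profile("ci")


def make_cohort(t, y, a, X=None, schema=None, ids=None):
    """Tiny cohort builder for hand-computed examples."""
    n = len(t)
    if X is None:
        X = pd.DataFrame({"x1": np.linspace(0.0, 1.0, n)})
        schema = (sm.CovariateSchema("x1", "continuous"),)
    return sm.Cohort(
        ids=np.arange(n) if ids is None else np.asarray(ids),
        X=X,
        a=np.asarray(a),
        t=np.asarray(t, dtype=float),
        y=np.asarray(y),
        schema=schema,
    )


@pytest.fixture(scope="session")
def default_cohort():
    """Mid-size confounded cohort shared by pipeline-level tests."""
    cohort, truth = sm.generate_cohort(sm.GeneratorConfig(n=1500, seed=3))
    return cohort, truth


@pytest.fixture(scope="session")
def stratified(default_cohort):
    cohort, _ = default_cohort
    return sm.stratify_cohort(cohort)
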