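import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

import deathcue as dc

settings.register_profile(
    "ci",
    deadline=None,
    max_examples=50,
    derandomize=True,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


def make_matrix(values, genotype=None, exposure=None, names=None, stage="raw",
                scale="raw"):
    """Small MetaboliteMatrix from a 2-D array; NaN entries are missing."""
    values = np.asarray(values, dtype=float)
    n, p = values.shape
    names = names or [f"m{j + 1}" for j in range(p)]
    idx = pd.Index([f"s{i + 1}" for i in range(n)], name="sample_id")
    genotype = genotype or ["control"] * n
    exposure = exposure or ["exposed"] * n
    return dc.MetaboliteMatrix(
        data=pd.DataFrame(values, index=idx, columns=names),
        sample_factors=pd.DataFrame(
            {"genotype": genotype, "exposure": exposure}, index=idx),
        scale=scale,
        stage=stage,
    )


@pytest.fixture
def toy_matrix_factory():
    return make_matrix


@pytest.fixture
def default_metabolome():
    """One default synthetic head-metabolome matrix (32 x 119, planted rank 10)."""
    return dc.simulate_metabolome(dc.MetabolomeSimSpec(seed=42))


@pytest.fixture
def cohort_2x2():
    """Seeded 2x2 survival cohort with a positive interaction."""
    return dc.simulate_cohorts(dc.SurvivalSimSpec(
        n_per_arm=120,
        log_hazard_effects=dc.LogHazardEffects(exposure=0.4, genotype=0.1,
                                               interaction=0.4),
        seed=7,
    ))
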