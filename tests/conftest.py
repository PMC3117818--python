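import numpy as np
import pytest

from apcpls import EffectSpec, generate_cohort

NULL_DIRECTION = np.array([1.0, -1.0, 1.0])  # age + cohort - period, year units


def project_to_rowspace(beta):
    """Projection of a coefficient vector onto the identifiable subspace of
    the year-unit linear APC design (orthogonal complement of (1,-1,1))."""
    u = NULL_DIRECTION / np.linalg.norm(NULL_DIRECTION)
    return beta - (beta @ u) * u


@pytest.fixture
def rng():
    return np.random.default_rng(20260919)


@pytest.fixture
def small_cohort():
    """A modest noise-bearing cohort without confounder effects."""
    return generate_cohort(
        EffectSpec(n_per_wave=300, seed=11, confounder_effects={}, noise_sd=5.0)
    )


@pytest.fixture
def cohort_with_confounders():
    return generate_cohort(EffectSpec(n_per_wave=400, seed=7, noise_sd=8.0))


def random_regression(rng, n=40, p=4, noise=1.0):
    X = rng.normal(size=(n, p))
    beta = rng.normal(size=p)
    y = X @ beta + noise * rng.normal(size=n)
    return X, y
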