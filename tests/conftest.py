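import numpy as np
import pytest
from hypothesis import settings

from ordmi import make_condition, simulate_dataset, summary_statistics

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")


@pytest.fixture(scope="session")
def c5_invariant_data():
    """Polytomous (C=5) strict-invariant two-group data, n_k=500."""
    cond = make_condition("negatively_skewed", 500, 5, 0, 1.0, 0.2)
    return simulate_dataset(cond, 2024)


@pytest.fixture(scope="session")
def c5_invariant_summary(c5_invariant_data):
    return summary_statistics(c5_invariant_data)


@pytest.fixture(scope="session")
def c5_noninvariant_data():
    """C=5 data with the last three focal unique variances inflated 1.5^2."""
    cond = make_condition("negatively_skewed", 500, 5, 3, 1.5**2, 0.2)
    return simulate_dataset(cond, 33)


@pytest.fixture(scope="session")
def c5_noninvariant_summary(c5_noninvariant_data):
    return summary_statistics(c5_noninvariant_data)


@pytest.fixture(scope="session")
def binary_invariant_data():
    """Dichotomous strict-invariant two-group data, n_k=500."""
    cond = make_condition("negatively_skewed", 500, 2, 0, 1.0, 0.0)
    return simulate_dataset(cond, 44)
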