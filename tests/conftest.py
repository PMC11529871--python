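import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "suite",
    derandomize=True,
    max_examples=25,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow, HealthCheck.function_scoped_fixture],
)
settings.load_profile("suite")


@pytest.fixture
def rng():
    return np.random.default_rng(7)


@pytest.fixture
def small_std():
    """Standardized 100 x 50 unlinked panel."""
    from sumrhe import simulate_genotypes, standardize

    return standardize(simulate_genotypes(100, 50, seed=11))


@pytest.fixture
def mid_std():
    """Standardized 300 x 400 unlinked panel (M > N exercises both trace routes)."""
    from sumrhe import simulate_genotypes, standardize

    return standardize(simulate_genotypes(300, 400, seed=13))
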