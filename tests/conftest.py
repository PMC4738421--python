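import numpy as np
import pytest
from hypothesis import HealthCheck, settings
from hypothesis import strategies as st

from mitoq import QualityDistribution

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=40,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@st.composite
def distributions(draw, min_Q=1, max_Q=14):
    """Random valid quality distributions (normalized, non-degenerate sizes)."""
    Q = draw(st.integers(min_value=min_Q, max_value=max_Q))
    raw = draw(
        st.lists(
            st.floats(min_value=0.0, max_value=1.0, allow_nan=False),
            min_size=Q + 1,
            max_size=Q + 1,
        ).filter(lambda v: sum(v) > 1e-3)
    )
    p = np.asarray(raw)
    return QualityDistribution(p / p.sum())


def random_distribution(rng, Q):
    p = rng.dirichlet(np.ones(Q + 1))
    return QualityDistribution(p / p.sum())


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20260927)
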