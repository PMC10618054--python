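import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci", max_examples=25, deadline=None,
    suppress_health_check=[HealthCheck.too_slow], derandomize=True,
)
settings.load_profile("ci")


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def random_map(rng):
    """A valid random normalized 20-locus contact map."""
    from chromocycle.contact_maps import ContactMap, normalize_adjacent, synthetic_region

    n = 20
    P = rng.uniform(0.0, 0.5, (n, n))
    P = 0.5 * (P + P.T)
    idx = np.arange(n - 1)
    P[idx, idx + 1] = P[idx + 1, idx] = rng.uniform(0.5, 0.8)
    np.fill_diagonal(P, 1.0)
    return normalize_adjacent(ContactMap(synthetic_region(n), P))
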