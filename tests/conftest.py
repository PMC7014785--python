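import numpy as np
import pytest


@pytest.fixture
def rng():
    return np.random.default_rng(20240611)


def random_instances(rng, n, k_max=10, s2_low=0.1, s2_high=2.0):
    """Random meta-analysis instances (y, s2) with 2 <= k <= k_max."""
    out = []
    for _ in range(n):
        k = rng.integers(2, k_max + 1)
        tau = rng.uniform(0, 2)
        s2 = rng.uniform(s2_low, s2_high, size=k)
        y = rng.normal(0, np.sqrt(tau), size=k) + rng.normal(0, np.sqrt(s2))
        out.append((y, s2))
    return out
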