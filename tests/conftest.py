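import numpy as np
import pytest

from confsel import default_domains
from confsel.synthetic import (
    TwoStateConfig,
    default_two_state_config,
    gen_two_state_tables,
)


@pytest.fixture(scope="session")
def domains():
    return default_domains()


@pytest.fixture(scope="session")
def noiseless_tables():
    """Two-domain two-state fixture with p_A=0.5, p_B=0.7 and zero noise."""
    cfg = default_two_state_config(30, 0.5, 0.7, seed=11, noise_h=0.0, noise_n=0.0)
    return gen_two_state_tables(cfg)


@pytest.fixture(scope="session")
def noisy_tables():
    """Same conditions with the study noise levels (0.005 / 0.025 ppm)."""
    cfg = default_two_state_config(30, 0.5, 0.7, seed=11)
    return gen_two_state_tables(cfg)


def make_single_domain_tables(p, n=30, seed=0, noise_h=0.005, noise_n=0.025):
    """Small helper: one-domain two-state fixture with known p."""
    rng = np.random.default_rng(seed)
    endpoints = {}
    for res in range(120, 120 + n):
        h0 = rng.uniform(7.2, 9.3)
        n0 = rng.uniform(105.0, 130.0)
        dh = rng.uniform(0.02, 0.30) * rng.choice([-1.0, 1.0])
        dn = rng.uniform(0.10, 1.50) * rng.choice([-1.0, 1.0])
        endpoints[res] = ((h0, n0), (h0 + dh, n0 + dn))
    cfg = TwoStateConfig(endpoints, p, noise_h=noise_h, noise_n=noise_n,
                         seed=seed + 1)
    return gen_two_state_tables(cfg)
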