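import numpy as np
import pytest

import cosolvstab as cs

# Nuisance baselines used across recovery tests: a plausible F350/330 curve
# rising from ~0.85 (folded) to ~1.05 (unfolded) with mild linear trends.
NUISANCE = dict(alpha_f=0.85, beta_f=0.0005, alpha_u=1.05, beta_u=0.002)
M_FOLDING = 1500.0  # J mol^-1 per %(v/v)


@pytest.fixture
def unfolding_params():
    def make(c_u50: float, temperature_c: float = 35.0, m_folding: float = M_FOLDING):
        return cs.UnfoldingModelParams.from_celsius(
            m_folding=m_folding, c_u50=c_u50, temperature_c=temperature_c, **NUISANCE
        )

    return make


@pytest.fixture
def activity_params():
    def make(c_a50: float, c_a_max: float = 0.0, sigma: float = 10.0,
             xi: float = 0.0, nu: float = 100.0, temperature_c: float = 35.0):
        return cs.ActivityModelParams.from_celsius(
            xi=xi, nu=nu, sigma=sigma, c_a_max=c_a_max, c_a50=c_a50,
            m_folding=M_FOLDING, temperature_c=temperature_c,
        )

    return make


@pytest.fixture
def random_unfolding_params():
    """Seeded draws of valid parameter sets with the midpoint inside 0-45."""

    def make(seed: int):
        rng = np.random.default_rng(seed)
        return cs.UnfoldingModelParams.from_celsius(
            alpha_f=rng.uniform(0.5, 1.0),
            beta_f=rng.uniform(0.0, 0.002),
            alpha_u=rng.uniform(1.1, 1.6),
            beta_u=rng.uniform(0.0, 0.003),
            m_folding=rng.uniform(800.0, 3000.0),
            c_u50=rng.uniform(10.0, 35.0),
            temperature_c=rng.uniform(25.0, 45.0),
        )

    return make
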