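import math

import numpy as np
import pytest

from pelletox import MMKinetics, PelletGeometry


@pytest.fixture
def kin_default():
    """Oxygen uptake kinetics of the studied pellets."""
    return MMKinetics(0.026, 0.11)


@pytest.fixture
def geom_small():
    """Smallest studied pellet class (D = 1400 um)."""
    return PelletGeometry(1400.0)


def make_modulus_scenario(rng, phi_m_range=(0.05, 20.0), beta_range=(0.1, 10.0)):
    """Random pellet scenario with a prescribed generalized Thiele modulus.

    Samples phi_m and beta log-uniformly, then back-solves the effective
    diffusivity that realises them at fixed kinetics, so solver sweeps
    cover the whole kinetic-to-diffusion-limited range.
    """
    phi_m = math.exp(rng.uniform(math.log(phi_m_range[0]), math.log(phi_m_range[1])))
    beta = math.exp(rng.uniform(math.log(beta_range[0]), math.log(beta_range[1])))
    c_s = rng.uniform(3.0, 8.0)
    R = rng.uniform(300.0, 3000.0)
    r_max = 0.026
    K_M = beta * c_s
    kin = MMKinetics(r_max, K_M)
    rate_s = r_max * c_s / (c_s + K_M)
    sat = c_s - K_M * math.log1p(c_s / K_M)
    d_eff = ((R / 3.0) * rate_s / phi_m) ** 2 / (2.0 * r_max * sat)
    return PelletGeometry(2 * R), kin, d_eff, c_s, phi_m
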