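import math

import numpy as np
import pytest
from scipy.integrate import quad

from dp4stereo.synthetic import SyntheticSpec, generate_truth


def student_t_cdf_quadrature(x: float, nu: float) -> float:
    """Independent Student-t CDF: numerical quadrature of the hand-written density."""
    c = math.gamma((nu + 1) / 2) / (math.gamma(nu / 2) * math.sqrt(nu * math.pi))

    def pdf(u: float) -> float:
        return c * (1 + u * u / nu) ** (-(nu + 1) / 2)

    val, _ = quad(pdf, 0.0, abs(x), epsabs=1e-13, epsrel=1e-13)
    return 0.5 + val if x >= 0 else 0.5 - val


@pytest.fixture(scope="session")
def small_system():
    """Deterministic 3-center synthetic system shared across tests."""
    spec = SyntheticSpec(n_centers=3, seed=11)
    return generate_truth(spec)


@pytest.fixture(scope="session")
def default_system():
    spec = SyntheticSpec(seed=42)
    return generate_truth(spec)
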