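import numpy as np
import pytest

import cttexture as ct

BODY = (1.89, 1.28)   # body-kernel reference (f_peak, sigma) in lp/cm
LUNG = (4.64, 1.83)   # lung-kernel reference
SPACING = ct.DEFAULT_PIXEL_SPACING_CM


@pytest.fixture(scope="session")
def body_params():
    """(alpha, beta) of the reduced model matching the body reference."""
    return ct.solve_model_params(*BODY)


@pytest.fixture(scope="session")
def body_curve(body_params):
    return ct.model_nps1d(*body_params)


@pytest.fixture(scope="session")
def lung_curve():
    alpha, beta = ct.solve_model_params(*LUNG)
    return ct.model_nps1d(alpha, beta)


@pytest.fixture(scope="session")
def body_stack(body_curve):
    """200-slice synthetic phantom stack with the body-kernel NPS."""
    return ct.generate_phantom_stack(body_curve, 200, 128, seed=42)


def symmetric_spectrum(rng, n, lo=0.5, hi=2.0):
    """Random positive spectrum with the real-field symmetry S[k] = S[-k]."""
    s = rng.uniform(lo, hi, (n, n))
    idx = (-np.arange(n)) % n
    return 0.5 * (s + s[np.ix_(idx, idx)])
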