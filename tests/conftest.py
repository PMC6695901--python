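import numpy as np
import pytest

from mucofilm.core import D2O, H2O, ScatteringCurve


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def h2o():
    return H2O


@pytest.fixture
def d2o():
    return D2O


@pytest.fixture
def debye_curve():
    """Noiseless Debye (Gaussian-coil) curve, Rg = 2.5 nm, on a log grid
    spanning q*Rg from well below 1 to well above 2."""
    from mucofilm.saxs import debye_form_factor

    q = np.logspace(np.log10(7e-4), np.log10(0.6), 150)
    return ScatteringCurve(q, 100.0 * debye_form_factor(q, 2.5))
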