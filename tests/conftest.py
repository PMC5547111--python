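import numpy as np
import pytest

from cyclicomp.models import make_model


@pytest.fixture
def rps_coexist():
    """Three-species game in the full-coexistence regime."""
    return make_model("rps", p=(2.5, 1.0, 0.5))


@pytest.fixture
def rps_pair():
    """Three-species game in the two-species regime."""
    return make_model("rps", p=(5.2, 1.0, 0.5))


@pytest.fixture
def rps_heteroclinic():
    """Three-species game in the extinction (attracting cycle) regime."""
    return make_model("rps", p=(1.0, 1.0, 0.5))


@pytest.fixture
def erps_template():
    return make_model("erps", p=(1.9, 2.0, 1.0, 1.3, 0.7))


@pytest.fixture
def rpsls_template():
    return make_model("rpsls", p=(0.3, 1.1, 2.5, 0.7, 1.0))


@pytest.fixture
def rng():
    return np.random.default_rng(1729)
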