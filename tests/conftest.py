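import pytest

from mbs_cua import default_parameters, generate_default_lifetable
from mbs_cua.synthetic import constant_lifetable


@pytest.fixture(scope="session")
def params():
    """Base-case point estimates."""
    return default_parameters()


@pytest.fixture(scope="session")
def lifetable():
    """Packaged Gompertz life table (ages 18-90, clamped beyond)."""
    return generate_default_lifetable()


@pytest.fixture(scope="session")
def zero_mortality():
    return constant_lifetable(0.0)
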