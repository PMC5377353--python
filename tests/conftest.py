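import pytest
from hypothesis import settings

from rhcalc import SaltParams, PolymerParams, builtin_registry

# Reproducible property tests: one profile, derandomized.
settings.register_profile("ci", derandomize=True, max_examples=100)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def registry():
    return builtin_registry()


@pytest.fixture(scope="session")
def nacl():
    return SaltParams(name="sodium chloride", x_ions=2, y_volume=0.027)


@pytest.fixture(scope="session")
def peg6000():
    return PolymerParams(name="PEG 6000", n_mw=6000.0, m_monomer=38.0)
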