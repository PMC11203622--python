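import numpy as np
import pytest
from hypothesis import settings

import helixspec as hx

settings.register_profile("ci", derandomize=True, max_examples=50)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def relay_spec():
    return hx.relay_helix_spec()


@pytest.fixture(scope="session")
def ideal_helix(relay_spec):
    return hx.make_ideal_helix(relay_spec)


@pytest.fixture(scope="session")
def bent_helix(relay_spec):
    """Helix with the relay-helix kink: H-bonds (22,26) and (23,27) broken."""
    return hx.make_bent_helix(relay_spec, [(22, 26), (23, 27)])


@pytest.fixture(scope="session")
def helix_series(ideal_helix, relay_spec):
    return hx.build_series(ideal_helix, relay_spec)


@pytest.fixture(scope="session")
def random_36(helix_series):
    """A random symmetric 36×36 Hamiltonian frame with random dipoles."""
    rng = np.random.default_rng(42)
    a = rng.normal(0.0, 4.0, (36, 36))
    h = (a + a.T) / 2.0 + np.diag(np.full(36, 1650.0))
    dip = rng.normal(0.0, 0.4, (36, 3))
    return h, dip
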