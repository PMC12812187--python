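import numpy as np
import pytest

import strokecea as sc


@pytest.fixture(scope="session")
def params():
    return sc.load_parameters()


@pytest.fixture(scope="session")
def det(params):
    """Deterministic model run at the parameter means."""
    return sc.run_deterministic(params)


@pytest.fixture(scope="session")
def psa_small(params):
    """A modest PSA used by uncertainty/VOI unit tests."""
    return sc.run_psa(params, n_draws=1_500, seed=7)


@pytest.fixture()
def rng():
    return np.random.default_rng(42)
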