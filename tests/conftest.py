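import numpy as np
import pytest

from negmap import DesignSpec, RTModelParams, gen_trials


@pytest.fixture(scope="session")
def design():
    return DesignSpec()


@pytest.fixture(scope="session")
def default_trials(design):
    """One realization of the full design at default parameters."""
    return gen_trials(design, RTModelParams(), seed=11)


@pytest.fixture(scope="session")
def noise_free_trials(design):
    """Deterministic trials: no noise, no subject effects, known Gaussian."""
    params = RTModelParams(delta_ling=0.0, delta_symb=0.0, tau_subj=0.0,
                           sigma_e=0.0, err_rate=0.0, amp=120.0, width=0.3)
    return gen_trials(design, params, seed=0)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
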