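import numpy as np
import pytest

from chromodyn.fixtures import make_genomic_fixture
from chromodyn.simulate import (IlluminationScheme, params_from_occupancies,
                                simulate_tracks)


@pytest.fixture(scope="session")
def study_params():
    """Kinetics used throughout: 20 % transient (1 s), 10 % stable (100 s)."""
    return params_from_occupancies(0.2, 0.1, tau_transient=1.0,
                                   tau_stable=100.0, p_bleach=0.3)


@pytest.fixture(scope="session")
def simulated_three_schemes(study_params):
    """One simulated experiment: fast, continuous and time-lapse movies."""
    fast = simulate_tracks(study_params, IlluminationScheme.fast(1000), 500, seed=11)
    cont = simulate_tracks(study_params, IlluminationScheme.continuous(600), 500, seed=12)
    tl = simulate_tracks(study_params, IlluminationScheme.timelapse(60), 500, seed=13)
    return fast, cont, tl


@pytest.fixture(scope="session")
def genomic_fixture():
    return make_genomic_fixture(n_peaks=200, seed=5)


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
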