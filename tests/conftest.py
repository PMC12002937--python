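import numpy as np
import pytest

import magbone as mb


@pytest.fixture(scope="session")
def truth():
    """Calibrated generator truth for all three materials."""
    return mb.default_truth()


@pytest.fixture(scope="session")
def deg_mg10():
    return mb.DegradationParams("surface_rate", r_prime=0.062, d_prime=0.068)


@pytest.fixture(scope="session")
def deg_mg5():
    return mb.DegradationParams("surface_rate", r_prime=1.104, d_prime=0.040)


@pytest.fixture(scope="session")
def grid230():
    return np.linspace(0.0, 230.0, 231)


@pytest.fixture(scope="session")
def ti_trajectory(truth, grid230):
    """Ti forward solve with ultrastructure states, reused across tests."""
    ti = truth["Ti"]
    return mb.simulate(ti.rem, grid230, ultra=ti.ultra["310"])


@pytest.fixture(scope="session")
def noise_free_study(truth):
    """Noise-free synthetic three-material study (medians = truth curves)."""
    return mb.generate_study(mb.study1_design(cv=0.0, lattice_sd=0.0), truth, seed=1)
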