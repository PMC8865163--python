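import numpy as np
import pytest

import tractnorm as tn


@pytest.fixture(scope="session")
def registry():
    return tn.default_tract_registry()


@pytest.fixture(scope="session")
def study():
    """One deterministic synthetic study shared across tests."""
    params = tn.SimulationParams(seed=20_220_124)
    controls, patients = tn.simulate_study(params)
    return params, controls, patients


@pytest.fixture(scope="session")
def references(study):
    _, controls, _ = study
    return {
        sex: tn.build_reference(controls.select(sex=sex), sex)
        for sex in (tn.Sex.MALE, tn.Sex.FEMALE)
    }


@pytest.fixture()
def rng():
    return np.random.default_rng(7)
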