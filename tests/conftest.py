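import numpy as np
import pytest

import fenpbpk as f


@pytest.fixture(scope="session")
def adult():
    return f.build_individual("male", 30.0)


@pytest.fixture(scope="session")
def adult_model(adult):
    return f.default_model(adult)


@pytest.fixture(scope="session")
def term_neonate():
    return f.build_individual("male", 0.0, 40.0)


@pytest.fixture(scope="session")
def preterm():
    return f.build_individual("male", 0.0, 32.0)


@pytest.fixture(scope="session")
def ziesenitz_regimen():
    """5 ug/kg intravenous fentanyl over 10 min."""
    return [f.DoseEvent("fentanyl", 0.0, 10.0 / 60.0, 5.0, per_kg=True)]


@pytest.fixture(scope="session")
def adult_long_run(adult_model, ziesenitz_regimen):
    """Adult reference simulation run to >= 99% elimination."""
    return f.simulate(adult_model, ziesenitz_regimen, t_end=7 * 24.0)


@pytest.fixture(scope="session")
def dense_early_grid():
    return np.concatenate([np.linspace(0.0, 0.5, 400),
                           np.linspace(0.5, 4.0, 120)[1:]])
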