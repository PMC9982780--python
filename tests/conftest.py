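import numpy as np
import pytest

import floxpk as fx


@pytest.fixture(scope="session")
def final_model():
    return fx.PopulationModel.final()


@pytest.fixture(scope="session")
def typical_params():
    # typical patient of the final model: CL = 19 * 66 * 0.06 L/h, V = 330 L,
    # f_u = 0.217 at the reference albumin
    return fx.IndividualParameters(75.24, 330.0, 0.217)


@pytest.fixture(scope="session")
def q4h_regimen():
    return fx.DosingRegimen(12000.0, "intermittent", interval=4.0, infusion_duration=0.5)


@pytest.fixture(scope="session")
def continuous_12g():
    return fx.DosingRegimen(12000.0, "continuous")


@pytest.fixture(scope="session")
def small_study():
    """A small rich-sampled synthetic study shared by estimation tests."""
    cfg = fx.StudyConfig(n_patients=12, sparse_fraction=0.0, samples_rich=(10, 12))
    return fx.generate_study(cfg, seed=2024)
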