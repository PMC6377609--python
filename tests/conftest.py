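import pytest

from larvapk import (
    DesignSpec,
    SimulationConfig,
    default_study_design,
    final_model_spec,
    reported_parameters,
    simulate_dataset,
)


@pytest.fixture(scope="session")
def design():
    return default_study_design()


@pytest.fixture(scope="session")
def final_spec():
    return final_model_spec()


@pytest.fixture(scope="session")
def truth():
    return reported_parameters()


@pytest.fixture(scope="session")
def dataset(design, truth, final_spec):
    """One study-design dataset at the reported estimates (fixed seed)."""
    cfg = SimulationConfig(design=design, truth=truth, modelspec=final_spec, seed=7)
    return simulate_dataset(cfg)


@pytest.fixture(scope="session")
def small_design():
    """A cut-down design for fast fitting in unit tests."""
    return DesignSpec(
        ages=(3, 4, 5),
        treatment_times=(15.0, 45.0, 90.0, 180.0),
        washout_times=(75.0, 120.0, 180.0, 240.0),
        replicates=2,
    )
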