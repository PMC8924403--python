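import numpy as np
import pytest

from metmap import (
    GeneratorConfig,
    OrganSite,
    TrajectoryParams,
    generate_corpus,
)


@pytest.fixture(scope="session")
def default_params() -> TrajectoryParams:
    """Moderate hazards for quick, label-balanced synthetic corpora."""
    return TrajectoryParams(
        onset_hazard={
            OrganSite.LUNGS: 0.12,
            OrganSite.LIVER: 0.15,
            OrganSite.ADRENAL_GLANDS: 0.05,
        },
        q_stable=0.7,
        benign_measurement_rate={OrganSite.LUNGS: 0.05},
    )


@pytest.fixture(scope="session")
def small_corpus(default_params):
    """300-patient labeled corpus shared by read-only tests."""
    config = GeneratorConfig(n_patients=300, seed=42)
    return generate_corpus(config, default_params)


@pytest.fixture(scope="session")
def tiny_corpus(default_params):
    config = GeneratorConfig(n_patients=12, seed=7)
    return generate_corpus(config, default_params)


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
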