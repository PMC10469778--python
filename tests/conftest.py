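import numpy as np
import pytest

from speechbeta import default_test_config, generate_session
from speechbeta.pipeline import PipelineConfig, run_pipeline


@pytest.fixture(scope="session")
def default_collection_bundle():
    """Full pipeline run on the default synthetic study collection.

    10 sessions of 80 utterances at 1000 Hz, fixed seed; shared across
    end-to-end tests because it is the expensive fixture.
    """
    config = PipelineConfig(sim=default_test_config(seed=1), n_sessions=10)
    return run_pipeline(config), config


@pytest.fixture(scope="session")
def single_session():
    """One default-condition session plus its ground truth."""
    return generate_session(default_test_config(seed=3))


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
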