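import pytest

from salpnet.codes import default_codes
from salpnet.config import PipelineConfig, SyntheticConfig
from salpnet.synthetic import generate_world


@pytest.fixture(scope="session")
def codes():
    return default_codes()


@pytest.fixture(scope="session")
def world():
    """Default-sized synthetic claims world, shared across tests."""
    return generate_world(SyntheticConfig(seed=20170101))


@pytest.fixture
def tiny_pipeline_config(tmp_path):
    """Small, fast end-to-end configuration."""
    syn = SyntheticConfig(
        n_hrrs=2,
        communities_per_hrr=2,
        physicians_per_community=20,
        n_patients=600,
        seed=11,
    )
    return PipelineConfig(
        synthetic=syn,
        output_dir=str(tmp_path / "out"),
        bootstrap_reps=10,
        fit_method="laplace",
    )
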