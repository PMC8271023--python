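import numpy as np
import pytest

from mibitime import SyntheticConfig, simulate_cohort
from mibitime.pipeline import PipelineConfig, quantify_cohort


@pytest.fixture(scope="session")
def small_config():
    """A fast, small synthetic cohort configuration shared across tests."""
    return SyntheticConfig(
        n_patients=8, image_size=(128, 128), mean_cells_per_image=60, seed=11
    )


@pytest.fixture(scope="session")
def small_cohort(small_config):
    return simulate_cohort(small_config)


@pytest.fixture(scope="session")
def small_quantified(small_cohort, small_config):
    pairs = list(zip(small_cohort.images, small_cohort.segmentations))
    records, thresholds = quantify_cohort(pairs, small_config.panel)
    return records, thresholds


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
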