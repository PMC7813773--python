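import numpy as np
import pytest
from hypothesis import settings

from exmort.glm_core import ModelSpec
from exmort.panel_io import MonthCoord
from exmort.synthetic_data import SyntheticConfig, generate_counts

settings.register_profile("ci", derandomize=True, max_examples=100)
settings.load_profile("ci")

TRAIN_START = MonthCoord(2013, 1)
TRAIN_END = MonthCoord(2020, 2)
PRED_MONTHS = [MonthCoord(2020, m) for m in (3, 4, 5, 6)]


@pytest.fixture(scope="session")
def default_spec():
    return ModelSpec(training_window=(TRAIN_START, TRAIN_END), year_center=2013)


@pytest.fixture(scope="session")
def synthetic_series():
    """One 90-month series (Jan 2013 - Jun 2020) with known truth."""
    return generate_counts(SyntheticConfig(seed=42))


@pytest.fixture()
def rng():
    return np.random.default_rng(7)
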