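import pathlib
import sys

import pytest
from hypothesis import settings

sys.path.insert(0, str(pathlib.Path(__file__).resolve().parent))

settings.register_profile("deterministic", derandomize=True, max_examples=40, deadline=None)
settings.load_profile("deterministic")

from icudea.severity_metrics import compute_performance  # noqa: E402
from icudea.synthetic_data import CohortConfig, generate_patients, generate_units  # noqa: E402


@pytest.fixture(scope="session")
def small_config():
    """A 12-unit cohort over a short window: ~1-2k patients, fast."""
    return CohortConfig(n_units=12, period_days=90.0, seed=7)


@pytest.fixture(scope="session")
def small_units(small_config):
    return generate_units(small_config)


@pytest.fixture(scope="session")
def small_patients(small_config, small_units):
    return generate_patients(small_units, small_config)


@pytest.fixture(scope="session")
def small_performance(small_patients):
    return compute_performance(small_patients)
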