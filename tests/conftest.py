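import logging

import pytest

from facohort.config import SynthConfig
from facohort.synth import make_cohort

logging.getLogger("facohort").setLevel(logging.ERROR)


@pytest.fixture(scope="session")
def small_config():
    """A reduced cohort for fast structural tests."""
    return SynthConfig(n_subjects=800, n_measured_dwellings=180, seed=11)


@pytest.fixture(scope="session")
def small_cohort(small_config):
    return make_cohort(small_config)
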