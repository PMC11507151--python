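import warnings

import numpy as np
import pytest

import ceplane as cp


@pytest.fixture(scope="session")
def default_cohort():
    """One default synthetic cohort (5+5 patients, 2 channels, 68 s @ 200 Hz)."""
    spec = cp.CohortSpec(seed=7)
    records, metadata = cp.gen_cohort(spec)
    return spec, records, metadata


@pytest.fixture(autouse=True)
def _quiet_undersampling():
    """Silence the expected M >> D! warning for D=6 on 15 s windows."""
    with warnings.catch_warnings():
        warnings.filterwarnings(
            "ignore", message=".*undersampled.*", category=UserWarning
        )
        yield


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
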