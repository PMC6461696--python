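import warnings

import numpy as np
import pytest

import noiseblind as nb

# Fitted nC_low < nC_high draws are expected in recovery harnesses and
# only warn by design; keep the test output readable.
warnings.filterwarnings(
    "ignore", message="nC_low < nC_high", category=UserWarning
)

EXP1_CONDITIONS = [(c, v) for c in (0.15, 0.6) for v in (0.0, 4.0, 10.0)]


@pytest.fixture(scope="session")
def group_params() -> nb.ObserverNoiseParams:
    """Group-mean noise magnitudes for the 2x3 design, in degrees."""
    return nb.ObserverNoiseParams(nC_low=10.1, nC_high=3.31, nV_med=3.0, nV_high=6.8)


@pytest.fixture(scope="session")
def exp1_conditions():
    return list(EXP1_CONDITIONS)


@pytest.fixture(scope="session")
def exp1_trials():
    return nb.sample_trial_sequence(nb.EXP1_CONFIG, seed=11)


@pytest.fixture(scope="session")
def grid():
    return nb.make_grid()
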