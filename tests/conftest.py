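"""Shared fixtures: simulated datasets and decoded results.

Heavy end-to-end objects (a decoded subject, the reduced SNR sweep) are
session-scoped so that property tests and the acceptance checks share one
computation.
"""

import numpy as np
import pytest

from dualdecode.decoding import crossval_decode
from dualdecode.dependency import snr_sensitivity_sweep
from dualdecode.simulate import SimulationConfig, generate_dataset

#: reduced study profile used throughout the suite: fewer trials than the
#: experiment's 512 but the same epoch grid, channel count and ERP
CI_TRIALS = 128
CI_SUBJECTS = 8
DECODE_WINDOW = (100.0, 700.0)


@pytest.fixture(scope="session")
def neg_epochs():
    """One simulated subject, negative (serial) mode at SNR 4."""
    cfg = SimulationConfig(n_trials=CI_TRIALS, correlation_mode="negative",
                           snr=4.0, seed=11)
    return generate_dataset(cfg)


@pytest.fixture(scope="session")
def neg_pair(neg_epochs):
    """Decoded horizontal/vertical pair for the negative-mode subject."""
    res_h = crossval_decode(neg_epochs, "horizontal", seed=21,
                            window_ms=DECODE_WINDOW)
    res_v = crossval_decode(neg_epochs, "vertical", seed=22,
                            window_ms=DECODE_WINDOW)
    return res_h, res_v


@pytest.fixture(scope="session")
def ci_sweep():
    """Reduced sensitivity sweep: 3 modes x 3 SNRs, 8 subjects each."""
    return snr_sensitivity_sweep(
        modes=("positive", "negative", "null"),
        snr_grid=(4.0, 0.5, 0.05),
        n_subjects=CI_SUBJECTS,
        seed=12345,
        base_config=SimulationConfig(n_trials=CI_TRIALS),
        decode_window_ms=DECODE_WINDOW,
        n_perm=500,
    )


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
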