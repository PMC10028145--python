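import logging

import numpy as np
import pytest

from tcsp import SimulationSpec, simulate_recording, preprocess, extract_epochs
from tcsp.io import EpochSet

# rank-deficiency warnings after CAR are expected throughout
logging.getLogger("tcsp").setLevel(logging.ERROR)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def make_gaussian_epochs(cov1, cov2, n_trials=30, n_samples=300, seed=0):
    """Two-class epochs drawn from zero-mean Gaussians with known covariances."""
    rng = np.random.default_rng(seed)
    n_ch = cov1.shape[0]
    l1 = np.linalg.cholesky(cov1)
    l2 = np.linalg.cholesky(cov2)
    data = np.concatenate([
        np.einsum("nm,imt->int", l1, rng.standard_normal((n_trials, n_ch, n_samples))),
        np.einsum("nm,imt->int", l2, rng.standard_normal((n_trials, n_ch, n_samples))),
    ])
    labels = np.repeat([1, 2], n_trials)
    return EpochSet(data, labels, rate=100.0, window_start=0.0)


def random_spd(n, rng):
    a = rng.standard_normal((n, n))
    return a @ a.T + n * np.eye(n)


@pytest.fixture(scope="session")
def sim_epochs():
    """Moderate-contrast simulated epochs, preprocessed and epoched once."""
    spec = SimulationSpec(n_trials=30, erd_depth=0.6, snr=1.0, seed=11)
    rec, truth = simulate_recording(spec)
    pre = preprocess(rec, band=(8.0, 32.0), target_rate=100.0)
    return extract_epochs(pre, window=(0.5, 3.0)), truth
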