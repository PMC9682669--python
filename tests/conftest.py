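import numpy as np
import pytest

import futilitysim as fs


@pytest.fixture(scope="session")
def design():
    """Reference design: n=500 equal allocation, Delta=0.09, threshold 0.90,
    Normal(0, 2^2) priors on the log-odds of both arms."""
    return fs.TrialDesign()


@pytest.fixture(scope="session")
def future():
    """Reference future phase III trial: 882 patients, one-sided alpha 0.025."""
    return fs.FutureTrialSpec()


@pytest.fixture()
def settings():
    """Reference chains: 1000 burn-in of 2500 total, no thinning."""
    return fs.McmcSettings(seed=20260930)


def batch_means_se(x, n_batches=30):
    """Monte Carlo SE of the mean of a (possibly autocorrelated) chain,
    estimated by non-overlapping batch means."""
    x = np.asarray(x, dtype=float)
    n = (x.size // n_batches) * n_batches
    batches = x[:n].reshape(n_batches, -1).mean(axis=1)
    return float(batches.std(ddof=1) / np.sqrt(n_batches))
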