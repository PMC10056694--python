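import numpy as np
import pytest

from bzinbnet.params import BNBParams, BZINBParams


@pytest.fixture
def rng():
    return np.random.default_rng(20230316)


@pytest.fixture
def bnb_params():
    """A moderately correlated BNB parameter set (rho = 0.5)."""
    return BNBParams(4.0, 2.0, 2.0, 3.0, 3.0)


@pytest.fixture
def bzinb_params(bnb_params):
    """Balanced-low masking on top of the rho=0.5 BNB component."""
    return BZINBParams(bnb_params, 0.75, 0.15, 0.05, 0.05)


def batch_se(x1, x2, n_batches=100):
    """Monte-Carlo standard error of a sample correlation, estimated by
    splitting the sample into batches (robust to non-normal counts)."""
    n = x1.size // n_batches
    cors = [
        np.corrcoef(x1[i * n : (i + 1) * n], x2[i * n : (i + 1) * n])[0, 1]
        for i in range(n_batches)
    ]
    return np.std(cors, ddof=1) / np.sqrt(n_batches)
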