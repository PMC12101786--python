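import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("reproducible", derandomize=True, deadline=None)
settings.load_profile("reproducible")


def chunked_se(values: np.ndarray, stat, n_chunks: int = 20) -> float:
    """Standard error of a statistic via non-overlapping chunks.

    Robust for weakly dependent sequences (the lag-1 correlation decays
    geometrically, so chunks of thousands of stimuli are effectively
    independent).
    """
    chunks = np.array_split(np.asarray(values), n_chunks)
    ests = np.array([stat(c) for c in chunks])
    return ests.std(ddof=1) / np.sqrt(n_chunks)


def empirical_ff(x: np.ndarray) -> float:
    return x.var(ddof=1) / x.mean()


def empirical_corr(x: np.ndarray, lag: int = 1) -> float:
    return np.corrcoef(x[:-lag], x[lag:])[0, 1]


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
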