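import numpy as np
import pytest

from actiseq.framing import AccelFrame, RawRecording
from actiseq.markov import MarkovChain
from actiseq.hmm import CHMMParams, GaussianMixtureEmissions


@pytest.fixture
def rng():
    return np.random.default_rng(0)


@pytest.fixture
def ten_channel_frame(rng):
    """One 512-sample, 10-channel frame with mixed posture/motion content."""
    t = np.arange(512) / 76.25
    window = 9.0 + np.sin(2 * np.pi * 2.0 * t)[None, :] * np.linspace(0.2, 1.0, 10)[:, None]
    window = window + 0.3 * rng.standard_normal((10, 512))
    return AccelFrame(window, start_index=0, rate=76.25)


def random_chmm(rng, q: int, d: int, m: int = 1, mean_scale: float = 3.0) -> CHMMParams:
    """A random valid cHMM for oracle tests."""
    prior = rng.dirichlet(np.ones(q))
    tpm = rng.dirichlet(np.ones(q), size=q)
    omm = MarkovChain([f"s{i}" for i in range(q)], prior, tpm)
    weights = rng.dirichlet(np.ones(m), size=q)
    means = rng.normal(0, mean_scale, (q, m, d))
    covs = np.zeros((q, m, d, d))
    for j in range(q):
        for k in range(m):
            a = rng.normal(0, 1, (d, d))
            covs[j, k] = a @ a.T + np.eye(d)
    return CHMMParams(omm, GaussianMixtureEmissions(weights, means, covs))
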