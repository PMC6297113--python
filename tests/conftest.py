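import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import mfbiclust as mb

settings.register_profile(
    "suite",
    derandomize=True,
    max_examples=25,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def blocks_noiseless():
    """8x8 matrix with three disjoint constant blocks (values 1, 2, 3), no noise."""
    return mb.generate_block_example(noise_sd=0.0, seed=0)


@pytest.fixture(scope="session")
def blocks_noiseless_fit(blocks_noiseless):
    """Deeply converged rank-3 NMF of the noiseless block matrix."""
    return mb.nmf_fit(
        blocks_noiseless.matrix, 3, seed=0, tol=1e-12, max_iter=2000, restarts=10
    )


def brute_force_model(ds):
    """Direct cell-by-cell evaluation of the additive bicluster model.

    Independent of the generator internals: walks the recorded truth and
    per-column effects and sums them into a fresh array.
    """
    p = ds.params
    X = np.full((p.m, p.n), float(p.mu))
    for b, beta in zip(ds.truth, ds.betas):
        for i in sorted(b.rows):
            for j in sorted(b.cols):
                X[i, j] += beta[j]
    return X
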