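"""Shared fixtures: small synthetic ensembles with ground truth.

Session-scoped so the (moderately expensive) simulation + HMM fit is paid once
and reused by the kinetics/thermo/acceptance tests.
"""

from __future__ import annotations

import numpy as np
import pytest

import smfret
from smfret.simulate import three_state_model


@pytest.fixture(scope="session")
def default_model():
    return three_state_model()


@pytest.fixture(scope="session")
def small_ensemble(default_model):
    """80 traces x 400 frames under the default three-state conditions."""
    return smfret.simulate_ensemble(
        default_model, n_traces=80, trace_length=400, seed=2024
    )


@pytest.fixture(scope="session")
def small_efret(small_ensemble):
    return [smfret.compute_efret(t) for t in small_ensemble.traces]


@pytest.fixture(scope="session")
def fitted3(small_efret):
    """Joint 3-state HMM fit of the small ensemble."""
    return smfret.fit_hmm(small_efret, 3, seed=0, n_restarts=2)


@pytest.fixture(scope="session")
def decoded_paths(fitted3, small_efret):
    return fitted3.decode(small_efret)


def random_hmm_params(rng: np.random.Generator, K: int):
    """A random, well-conditioned K-state Gaussian HMM parameter set."""
    means = np.sort(rng.uniform(0.0, 1.0, size=K))
    sds = rng.uniform(0.03, 0.15, size=K)
    trans = rng.uniform(0.05, 1.0, size=(K, K))
    trans /= trans.sum(axis=1, keepdims=True)
    start = rng.uniform(0.1, 1.0, size=K)
    start /= start.sum()
    return means, sds, trans, start
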