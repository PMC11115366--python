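"""Shared fixtures: synthetic islets and derived pipeline objects.

Session scope keeps the simulator and filtering cost paid once.
"""

import numpy as np
import pytest

import isletnet as isn


@pytest.fixture(scope="session")
def islet():
    """Default synthetic islet, seed 1."""
    return isn.generate_islet(isn.IsletSimConfig(seed=1))


@pytest.fixture(scope="session")
def islet_noiseless():
    """Zero-photon-noise islet for ground-truth recovery checks."""
    return isn.generate_islet(isn.IsletSimConfig(seed=1, noise_sd=0.0))


@pytest.fixture(scope="session")
def fast_rec(islet):
    return isn.bandpass_filter(islet.recording, isn.FilterSpec.named("fast"))


@pytest.fixture(scope="session")
def slow_rec(islet):
    return isn.bandpass_filter(islet.recording, isn.FilterSpec.named("slow"))


@pytest.fixture(scope="session")
def fast_binarized(fast_rec):
    return isn.binarize(fast_rec)


@pytest.fixture(scope="session")
def fast_similarity(fast_rec):
    return isn.pearson_matrix(fast_rec)


@pytest.fixture(scope="session")
def random_similarity():
    """Random symmetric similarity matrix over 50 cells (no ties)."""
    rng = np.random.default_rng(42)
    n = 50
    v = rng.uniform(-0.2, 1.0, size=(n, n))
    v = (v + v.T) / 2
    return isn.SimilarityMatrix(
        values=v, method="correlation", cell_ids=[f"c{i:03d}" for i in range(n)]
    )


def make_binarized(states, fs=1.0):
    states = np.asarray(states)
    return isn.BinarizedActivity(
        states=states, fs=fs, cell_ids=[f"c{i:03d}" for i in range(states.shape[1])]
    )
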