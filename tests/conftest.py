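"""Shared fixtures: small, fast simulated datasets for unit tests.

Unit tests run on reduced grids/time points; the full-scale study
conditions are exercised by the acceptance tests.
"""

import numpy as np
import pytest

from fndecomp import sim
from fndecomp.datatypes import SimConfig


@pytest.fixture(scope="session")
def small_sim():
    """A small multi-subject simulation (4 subjects, 4 sources, 48x48)."""
    config = SimConfig(
        n_subjects=4,
        n_sources=4,
        grid=(48, 48),
        n_timepoints=80,
        cnr=2.0,
        seed=11,
    )
    datasets, truths = sim.simulate_subjects(config, fwhm=4.0)
    return config, datasets, truths


@pytest.fixture(scope="session")
def laplace_mixture():
    """Whitened mixture of 3 Laplace spatial sources, plus the truth."""
    rng = np.random.default_rng(5)
    S = rng.laplace(size=(3, 5000))
    A = rng.standard_normal((3, 3))
    X = A @ S
    X = X - X.mean(axis=1, keepdims=True)
    cov = X @ X.T / X.shape[1]
    evals, evecs = np.linalg.eigh(cov)
    wh = (evecs / np.sqrt(evals)) @ evecs.T
    return wh @ X, S, wh @ A
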