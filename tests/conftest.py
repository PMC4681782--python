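"""Shared fixtures: small deterministic instances and the desk-scale ensemble."""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import settings

from recallnet.experiments import ExperimentConfig, run_ensemble
from recallnet.patterns import generate_patterns, partition_populations

settings.register_profile("ci", derandomize=True, max_examples=25, deadline=None)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def small_patterns():
    """A small instance (N=200, P=8) for exact/oracle comparisons."""
    return generate_patterns(200, 8, 0.1, seed=1234)


@pytest.fixture(scope="session")
def small_partition(small_patterns):
    return partition_populations(small_patterns)


@pytest.fixture(scope="session")
def scaled_ensemble():
    """Desk-scale reference ensemble: 50 trials at N=2e4, T=100 cycles.

    Used by the recall-statistics tests and the acceptance checks; one run
    per session (a few minutes).
    """
    config = ExperimentConfig.scaled_profile(master_seed=0)
    return run_ensemble(config)


@pytest.fixture(scope="session")
def ensemble_similarities(scaled_ensemble):
    """Per-trial intersection matrices with the diagonal zeroed for ranking."""
    sims = []
    for res in scaled_ensemble:
        sim = res.intersections.astype(np.float64)
        np.fill_diagonal(sim, 0.0)
        sims.append(sim)
    return sims
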