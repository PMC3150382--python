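"""Shared fixtures: seeded random matrices and trees.

All randomness is seeded; hypothesis runs derandomised so the suite is
reproducible run to run.
"""

import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import hcsym

settings.register_profile(
    "suite", derandomize=True, max_examples=50, deadline=None,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("suite")


def random_distance_matrix(n: int, rng: np.random.Generator,
                           labels=None) -> hcsym.DistanceMatrix:
    vals = rng.uniform(0.1, 10.0, size=(n, n))
    vals = (vals + vals.T) / 2
    np.fill_diagonal(vals, 0.0)
    labels = labels or [f"L{i:02d}" for i in range(n)]
    return hcsym.DistanceMatrix(labels, vals)


def random_tree(n: int, rng: np.random.Generator):
    """Average-linkage tree over a random distance matrix; returns (tree, dist)."""
    dist = random_distance_matrix(n, rng)
    return hcsym.cluster_average_linkage(dist), dist


@pytest.fixture
def rng():
    return np.random.default_rng(20260926)


@pytest.fixture
def two_leaf_dist():
    return hcsym.DistanceMatrix(["a", "b"], [[0.0, 0.4], [0.4, 0.0]])
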