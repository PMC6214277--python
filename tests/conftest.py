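from __future__ import annotations

import numpy as np
import pytest

from flowmotifs import (
    DirectedBinaryNetwork,
    PlantedStructure,
    generate_planted_weight_matrix,
)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def make_network(n, edges, labels=None) -> DirectedBinaryNetwork:
    adj = np.zeros((n, n), dtype=bool)
    for i, j in edges:
        adj[i, j] = True
    return DirectedBinaryNetwork(adjacency=adj, node_labels=labels)


def bidirectional_star(center, leaves, n) -> DirectedBinaryNetwork:
    edges = []
    for leaf in leaves:
        edges += [(center, leaf), (leaf, center)]
    return make_network(n, edges)


@pytest.fixture
def two_cluster_structure():
    """12 nodes, two clusters of 6, apex nodes 0 and 6."""
    assignment = np.array([1] * 6 + [2] * 6)
    return PlantedStructure(cluster_assignment=assignment, apex_nodes=frozenset({0, 6}))


@pytest.fixture
def planted_pte(two_cluster_structure):
    """Small-jitter planted matrix: distinct weights, auto interval valid."""
    return generate_planted_weight_matrix(
        12, two_cluster_structure, w_in=1.0, w_out=0.3, jitter_sd=0.02, seed=3
    )
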