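"""Independent brute-force oracles used to validate the package's fast paths.

These deliberately avoid the package implementations: connectivity comes from
networkx, motif ids from a string-based permutation minimization, census from
all-subsets enumeration, and conductance minimization from exhaustive
bipartition search.
"""

from __future__ import annotations

import itertools

import networkx as nx
import numpy as np


def oracle_canonical_id(adj3) -> int:
    """Min over relabelings of the row-major 9-bit adjacency reading."""
    a = np.asarray(adj3, dtype=int)
    best = None
    for p in itertools.permutations(range(3)):
        bits = "".join(str(a[p[i], p[j]]) for i in range(3) for j in range(3))
        v = int(bits, 2)
        if best is None or v < best:
            best = v
    return best


def oracle_census_counts(adjacency) -> dict:
    """Induced 3-subgraph census by enumerating every node subset."""
    a = np.asarray(adjacency).astype(int)
    n = a.shape[0]
    counts: dict[int, int] = {}
    for sub in itertools.combinations(range(n), 3):
        sa = a[np.ix_(sub, sub)]
        g = nx.from_numpy_array(sa, create_using=nx.DiGraph)
        if g.number_of_edges() and nx.is_weakly_connected(g):
            m = oracle_canonical_id(sa)
            counts[m] = counts.get(m, 0) + 1
    return counts


def oracle_motif_adjacency(instances, n) -> np.ndarray:
    w = np.zeros((n, n), dtype=int)
    for inst in instances:
        for i, j in itertools.combinations(sorted(inst), 2):
            w[i, j] += 1
            w[j, i] += 1
    return w


def oracle_conductance(w, set1, set2) -> float:
    w = np.asarray(w, dtype=float)
    s1, s2 = sorted(set1), sorted(set2)
    d = w.sum(axis=1)
    cut = w[np.ix_(s1, s2)].sum()
    return cut / min(d[s1].sum(), d[s2].sum())


def oracle_min_conductance(w) -> float:
    """Exhaustive minimum conductance over all bipartitions of participants."""
    w = np.asarray(w, dtype=float)
    d = w.sum(axis=1)
    nodes = np.flatnonzero(d > 0)
    m = nodes.size
    assert 2 <= m <= 20, "exhaustive search limited to small graphs"
    best = np.inf
    for mask in range(1, 2 ** (m - 1)):
        s1 = [int(nodes[i]) for i in range(m) if (mask >> i) & 1]
        s2 = [int(v) for v in nodes if v not in s1]
        if not s2:
            continue
        vol1, vol2 = d[s1].sum(), d[s2].sum()
        if min(vol1, vol2) <= 0:
            continue
        phi = w[np.ix_(s1, s2)].sum() / min(vol1, vol2)
        if phi < best:
            best = phi
    return float(best)


def oracle_tau_max(values) -> float:
    """Linear scan over all candidate thresholds for the connectivity bound."""
    v = np.asarray(values, dtype=float)
    offdiag = v[~np.eye(v.shape[0], dtype=bool)]
    candidates = np.unique(offdiag[offdiag > 0])
    best = None
    for tau in candidates:
        a = v > tau
        np.fill_diagonal(a, False)
        und = a | a.T
        if not und.any(axis=0).all():
            continue
        g = nx.from_numpy_array(und)
        if nx.is_connected(g):
            best = float(tau)
    return best


def random_digraph(n, p, rng) -> np.ndarray:
    a = rng.random((n, n)) < p
    np.fill_diagonal(a, False)
    return a
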