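"""Binary directed networks from PTE matrices and their summary properties.

A link i -> j exists iff PTE[i, j] > tau (strict).  A pair with both
directions above tau is a bi-directional link, stored as two opposing
directed links.  The principled interval [tau_min, tau_max] runs from the
nearest-rank 30th percentile of the (positive) off-diagonal PTE values up to
the largest threshold at which the network still has a single weakly
connected component and no isolated nodes.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components

from .pte import PTEMatrix
from .utils import pearson

__all__ = [
    "DirectedBinaryNetwork",
    "ThresholdInterval",
    "NetworkProperties",
    "threshold_network",
    "find_tau_min",
    "find_tau_max",
    "find_threshold_interval",
    "network_properties",
]


@dataclass
class DirectedBinaryNetwork:
    """Unweighted directed graph on labeled nodes, no self-loops."""

    adjacency: np.ndarray
    node_labels: list | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        a = np.asarray(self.adjacency)
        if a.ndim != 2 or a.shape[0] != a.shape[1]:
            raise ValueError("adjacency must be square")
        a = a.astype(bool)
        if np.any(np.diag(a)):
            raise ValueError("self-loops are not allowed")
        self.adjacency = a
        if self.node_labels is None:
            self.node_labels = [f"R{i:02d}" for i in range(a.shape[0])]
        else:
            self.node_labels = list(self.node_labels)
            if len(self.node_labels) != a.shape[0]:
                raise ValueError("node_labels length does not match adjacency")

    @property
    def n(self) -> int:
        return self.adjacency.shape[0]

    @property
    def n_links(self) -> int:
        """Directed link count (each bi-directional link counts as two)."""
        return int(self.adjacency.sum())

    def total_degrees(self) -> np.ndarray:
        """Incoming plus outgoing link count per node."""
        a = self.adjacency
        return a.sum(axis=0) + a.sum(axis=1)


@dataclass
class ThresholdInterval:
    tau_min: float
    tau_max: float
    percentile_used: float = 0.30

    def __post_init__(self):
        if not (self.tau_min < self.tau_max):
            raise ValueError(
                f"tau_min ({self.tau_min}) must be below tau_max ({self.tau_max})"
            )


@dataclass
class NetworkProperties:
    """Link counts and global statistics of one binary directed network."""

    n_uni: int
    n_bi: int
    avg_degree: float
    link_density: float
    assortativity: float


def threshold_network(pte: PTEMatrix, tau: float) -> DirectedBinaryNetwork:
    """Binarize at tau with strict inequality (links with PTE <= tau dropped)."""
    if not math.isfinite(tau):
        raise ValueError("tau must be finite")
    adj = pte.values > tau
    np.fill_diagonal(adj, False)
    return DirectedBinaryNetwork(
        adjacency=adj, node_labels=list(pte.region_labels), meta={"tau": float(tau)}
    )


def _positive_offdiag(pte: PTEMatrix) -> np.ndarray:
    vals = pte.off_diagonal()
    return vals[vals > 0]


def find_tau_min(pte: PTEMatrix, percentile: float = 0.30) -> float:
    """Nearest-rank percentile of the positive off-diagonal PTE values.

    The ceil(p*M)-th smallest of the M values; thresholding strictly above it
    retains the top (1-p) fraction of links.  percentile 0 returns a sentinel
    strictly below the minimum so the full graph is retained.
    """
    if not (0.0 <= percentile < 1.0):
        raise ValueError("percentile must lie in [0, 1)")
    vals = _positive_offdiag(pte)
    if vals.size < 2 or np.unique(vals).size < 2:
        raise ValueError("degenerate matrix: need >= 2 distinct off-diagonal values")
    k = math.ceil(percentile * vals.size)
    if k == 0:
        return float(np.nextafter(vals.min(), -np.inf))
    return float(np.partition(vals, k - 1)[k - 1])


def _network_ok(pte: PTEMatrix, tau: float) -> bool:
    """No isolated nodes and a single weakly connected component at tau."""
    adj = pte.values > tau
    np.fill_diagonal(adj, False)
    und = adj | adj.T
    if not und.any(axis=0).all():
        return False
    n_comp = connected_components(csr_matrix(und), directed=False)[0]
    return n_comp == 1


def find_tau_max(pte: PTEMatrix) -> float:
    """Largest distinct off-diagonal value whose network stays weakly connected.

    Candidates are the sorted distinct positive off-diagonal values; link
    removal is monotone in tau, so a binary search suffices.  Raises if even
    the weakest-link removal already isolates a node or disconnects the graph.
    """
    vals = np.unique(_positive_offdiag(pte))
    if vals.size == 0:
        raise ValueError("matrix has no positive off-diagonal values")
    below = float(np.nextafter(vals[0], -np.inf))
    if not _network_ok(pte, below):
        raise ValueError("full graph is not weakly connected")
    if not _network_ok(pte, float(vals[0])):
        raise ValueError("no valid threshold: the first link removal already "
                         "isolates a node or disconnects the network")
    lo, hi = 0, vals.size - 1
    if _network_ok(pte, float(vals[hi])):  # cannot happen for n >= 2, be safe
        return float(vals[hi])
    while lo + 1 < hi:
        mid = (lo + hi) // 2
        if _network_ok(pte, float(vals[mid])):
            lo = mid
        else:
            hi = mid
    return float(vals[lo])


def find_threshold_interval(pte: PTEMatrix, percentile: float = 0.30) -> ThresholdInterval:
    """[tau_min, tau_max] combining the percentile and connectivity rules."""
    return ThresholdInterval(
        tau_min=find_tau_min(pte, percentile),
        tau_max=find_tau_max(pte),
        percentile_used=percentile,
    )


def network_properties(
    net: DirectedBinaryNetwork, assortativity_mode: str = "total"
) -> NetworkProperties:
    """Uni/bi link counts, average degree, link density and assortativity.

    Directed link count = n_uni + 2*n_bi; avg_degree divides by N and
    link_density by N*(N-1).  Assortativity is the Pearson correlation of
    endpoint degrees over directed links: total degrees by default, or
    (out-degree of source, in-degree of target) with mode "out-in".  NaN for
    networks where it is undefined.
    """
    a = net.adjacency
    n = net.n
    mutual = a & a.T
    n_bi = int(mutual.sum()) // 2
    n_uni = int((a & ~a.T).sum())
    n_links = n_uni + 2 * n_bi
    avg_degree = n_links / n if n else 0.0
    link_density = n_links / (n * (n - 1)) if n > 1 else 0.0
    if n_links == 0:
        assort = float("nan")
    else:
        src, tgt = np.nonzero(a)
        if assortativity_mode == "total":
            deg = a.sum(axis=0) + a.sum(axis=1)
            assort = pearson(deg[src], deg[tgt])
        elif assortativity_mode == "out-in":
            assort = pearson(a.sum(axis=1)[src], a.sum(axis=0)[tgt])
        else:
            raise ValueError(f"unknown assortativity mode {assortativity_mode!r}")
    return NetworkProperties(
        n_uni=n_uni,
        n_bi=n_bi,
        avg_degree=avg_degree,
        link_density=link_density,
        assortativity=assort,
    )
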