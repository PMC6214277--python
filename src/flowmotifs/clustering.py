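"""Motif adjacency matrices, motif conductance and the spectral sweep cut.

The motif adjacency matrix W counts, for every node pair, the node-disjoint
motif instances the pair shares.  The sweep cut orders the participating
nodes by the eigenvector of the second smallest eigenvalue of the normalized
motif Laplacian I - D^{-1/2} W D^{-1/2} (scaled back by D^{-1/2}; the raw
ordering is evaluated too and the better split returned) and takes the
prefix split of minimum motif conductance, which is guaranteed to be within
4*sqrt(phi*) of the optimum phi*.

For threshold-interval aggregation, the link-resolved threshold set T holds
every distinct PTE value inside (tau_min, tau_max]; consecutive thresholds'
networks differ by exactly one directed link and the aggregated matrix is
the elementwise sum of the per-threshold motif adjacencies.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import scipy.linalg
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components
from scipy.sparse.linalg import eigsh

from .motifs import APEX_MOTIF, MotifCensus, census
from .netbuild import ThresholdInterval, find_tau_max, find_tau_min, threshold_network
from .pte import PTEMatrix

__all__ = [
    "MotifAdjacency",
    "Partition",
    "ThresholdSet",
    "NoMotifParticipationError",
    "motif_adjacency",
    "motif_conductance",
    "spectral_sweep",
    "link_resolved_thresholds",
    "aggregate_motif_adjacency",
    "cluster_pipeline",
]

_DENSE_EIG_LIMIT = 200


class NoMotifParticipationError(ValueError):
    """Raised when too few nodes participate in the motif to partition."""


@dataclass
class MotifAdjacency:
    """Symmetric nonnegative integer matrix of motif co-participation."""

    w: np.ndarray
    motif: int
    node_labels: list | None = None

    def __post_init__(self):
        w = np.asarray(self.w)
        if w.ndim != 2 or w.shape[0] != w.shape[1]:
            raise ValueError("motif adjacency must be square")
        if np.any(w < 0):
            raise ValueError("motif adjacency must be nonnegative")
        if np.any(w != w.T):
            raise ValueError("motif adjacency must be symmetric")
        if np.any(np.diag(w) != 0):
            raise ValueError("motif adjacency diagonal must be zero")
        self.w = w
        if self.node_labels is None:
            self.node_labels = [f"R{i:02d}" for i in range(w.shape[0])]
        else:
            self.node_labels = list(self.node_labels)
            if len(self.node_labels) != w.shape[0]:
                raise ValueError("node_labels length does not match matrix")

    @property
    def n(self) -> int:
        return self.w.shape[0]

    def degrees(self) -> np.ndarray:
        """Motif degree d_ii = row sums of W."""
        return self.w.sum(axis=1)


@dataclass
class Partition:
    """Two-way node partition plus the motif-degree-zero third group."""

    cluster1: list
    cluster2: list
    non_participants: list
    conductance: float
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        if not self.cluster1 or not self.cluster2:
            raise ValueError("both clusters must be non-empty")
        if set(self.cluster1) & set(self.cluster2):
            raise ValueError("clusters must be disjoint")

    def assignment(self) -> dict:
        """Map node label -> group ('1', '2' or 'none')."""
        out = {}
        for v in self.cluster1:
            out[v] = "1"
        for v in self.cluster2:
            out[v] = "2"
        for v in self.non_participants:
            out[v] = "none"
        return out


@dataclass
class ThresholdSet:
    """Ascending link-resolved thresholds within (tau_min, tau_max]."""

    thresholds: np.ndarray
    grouped_ties: bool = False

    def __post_init__(self):
        t = np.asarray(self.thresholds, dtype=float)
        if t.size and np.any(np.diff(t) <= 0):
            raise ValueError("thresholds must be strictly ascending")
        self.thresholds = t

    def __len__(self) -> int:
        return int(self.thresholds.size)


def motif_adjacency(
    cens: MotifCensus,
    motif: int = APEX_MOTIF,
    n: int | None = None,
    node_labels: list | None = None,
) -> MotifAdjacency:
    """w_ij = number of node-disjoint motif instances containing both i and j."""
    if cens.instances is None:
        raise ValueError("census was computed without instance lists")
    instances = cens.instances.get(motif, [])
    if n is None:
        if node_labels is not None:
            n = len(node_labels)
        elif instances:
            n = max(max(inst) for inst in instances) + 1
        else:
            raise ValueError("matrix size n is required for an empty census")
    w = np.zeros((n, n), dtype=np.int64)
    for inst in instances:
        for i, j in itertools.combinations(inst, 2):
            w[i, j] += 1
            w[j, i] += 1
    return MotifAdjacency(w=w, motif=motif, node_labels=node_labels)


def _as_w(w) -> tuple[np.ndarray, list]:
    if isinstance(w, MotifAdjacency):
        return w.w.astype(float), list(w.node_labels)
    w = np.asarray(w, dtype=float)
    return w, [f"R{i:02d}" for i in range(w.shape[0])]


def motif_conductance(w, set1, set2) -> float:
    """cut(set1, set2) / min(vol(set1), vol(set2)) on the motif adjacency.

    The sets must be disjoint, non-empty, and together cover every node with
    positive motif degree; set entries are node indices.
    """
    wm, _ = _as_w(w)
    s1 = sorted(int(v) for v in set1)
    s2 = sorted(int(v) for v in set2)
    if not s1 or not s2:
        raise ValueError("both sets must be non-empty")
    if set(s1) & set(s2):
        raise ValueError("sets must be disjoint")
    d = wm.sum(axis=1)
    participating = set(np.flatnonzero(d > 0).tolist())
    if not participating <= (set(s1) | set(s2)):
        raise ValueError("partition must cover all participating nodes")
    vol1 = float(d[s1].sum())
    vol2 = float(d[s2].sum())
    if min(vol1, vol2) <= 0:
        raise ValueError("minimum partition volume is zero")
    cut = float(wm[np.ix_(s1, s2)].sum())
    return cut / min(vol1, vol2)


def _fiedler_vector(lap: np.ndarray) -> tuple[float, np.ndarray]:
    m = lap.shape[0]
    lap = (lap + lap.T) / 2.0
    if m <= _DENSE_EIG_LIMIT:
        evals, evecs = scipy.linalg.eigh(lap)
        return float(evals[1]), evecs[:, 1]
    evals, evecs = eigsh(csr_matrix(lap), k=2, which="SA", tol=1e-9)
    order = np.argsort(evals)
    return float(evals[order[1]]), evecs[:, order[1]]


def _sweep_conductances(wp: np.ndarray, dp: np.ndarray, order: np.ndarray) -> np.ndarray:
    """phi of every prefix split of the ordering; entry k = prefix of size k+1."""
    m = order.size
    wo = wp[np.ix_(order, order)]
    do = dp[order]
    vol1 = np.cumsum(do)
    total = vol1[-1]
    phis = np.empty(m - 1, dtype=float)
    inside = 0.0  # 2 * weight inside the prefix block
    row_prefix = np.cumsum(wo, axis=1)
    for k in range(m - 1):
        if k > 0:
            inside += 2.0 * row_prefix[k, k - 1]
        cut = vol1[k] - inside
        phis[k] = cut / min(vol1[k], total - vol1[k])
    return phis


def _normalize_split(side_a: tuple, side_b: tuple) -> tuple[tuple, tuple]:
    a, b = tuple(sorted(side_a)), tuple(sorted(side_b))
    if (len(a), a) <= (len(b), b):
        return a, b
    return b, a


def spectral_sweep(wm: MotifAdjacency) -> Partition:
    """Minimum-conductance prefix split from the normalized motif Laplacian.

    Zero-motif-degree nodes are set aside as non-participants.  If the
    motif-weight graph on the participants is disconnected, the zero-cut
    split (largest component vs the rest) is returned and flagged.  Ties in
    eigenvector entries break by node index; ties in conductance prefer the
    smaller cluster1, then lexicographic order.
    """
    w = wm.w.astype(float)
    labels = list(wm.node_labels)
    d = w.sum(axis=1)
    part = np.flatnonzero(d > 0)
    non_part = [labels[i] for i in np.flatnonzero(d == 0)]
    if part.size < 3:
        raise NoMotifParticipationError(
            f"only {part.size} node(s) participate in motif {wm.motif} instances; "
            "need at least 3 to partition"
        )
    wp = w[np.ix_(part, part)]
    dp = wp.sum(axis=1)
    n_comp, comp = connected_components(csr_matrix(wp), directed=False)
    meta: dict = {"motif": wm.motif, "n_participants": int(part.size)}
    if n_comp > 1:
        sizes = np.bincount(comp)
        big = int(np.argmax(sizes))
        side1 = tuple(int(part[i]) for i in np.flatnonzero(comp == big))
        side2 = tuple(int(part[i]) for i in np.flatnonzero(comp != big))
        c1, c2 = _normalize_split(side1, side2)
        meta.update(flags=["motif_graph_disconnected"], n_components=int(n_comp))
        return Partition(
            cluster1=[labels[i] for i in c1],
            cluster2=[labels[i] for i in c2],
            non_participants=non_part,
            conductance=0.0,
            meta=meta,
        )
    m = part.size
    inv_sqrt = 1.0 / np.sqrt(dp)
    lap = np.eye(m) - inv_sqrt[:, None] * wp * inv_sqrt[None, :]
    lam2, vec = _fiedler_vector(lap)
    meta["lambda2"] = lam2
    best_key = None
    best_split = None
    for key_vals in (inv_sqrt * vec, vec):
        order = np.lexsort((np.arange(m), key_vals))
        phis = _sweep_conductances(wp, dp, order)
        for k in range(m - 1):
            prefix = tuple(int(part[i]) for i in order[: k + 1])
            suffix = tuple(int(part[i]) for i in order[k + 1 :])
            c1, c2 = _normalize_split(prefix, suffix)
            cand = (round(float(phis[k]), 12), len(c1), c1)
            if best_key is None or cand < best_key:
                best_key = cand
                best_split = (c1, c2, float(phis[k]))
    c1, c2, phi = best_split
    return Partition(
        cluster1=[labels[i] for i in c1],
        cluster2=[labels[i] for i in c2],
        non_participants=non_part,
        conductance=phi,
        meta=meta,
    )


def link_resolved_thresholds(
    pte: PTEMatrix, interval: ThresholdInterval, ties: str = "error"
) -> ThresholdSet:
    """Thresholds at which the network changes by exactly one directed link.

    These are the distinct off-diagonal PTE values inside
    (tau_min, tau_max] — each is the weight of the one link removed when tau
    reaches it.  Tied values violate the one-link guarantee: an error by
    default, grouped (one threshold removing several links) with
    ties="group".
    """
    if ties not in ("error", "group"):
        raise ValueError("ties must be 'error' or 'group'")
    vals = pte.off_diagonal()
    vals = vals[(vals > interval.tau_min) & (vals <= interval.tau_max)]
    uniq, counts = np.unique(vals, return_counts=True)
    grouped = bool(np.any(counts > 1))
    if grouped and ties == "error":
        raise ValueError(
            "tied PTE values inside the threshold interval violate the "
            "one-link-per-threshold construction; pass ties='group' to group them"
        )
    return ThresholdSet(thresholds=uniq, grouped_ties=grouped)


def aggregate_motif_adjacency(
    pte: PTEMatrix, t_set: ThresholdSet, motif: int = APEX_MOTIF
) -> MotifAdjacency:
    """Elementwise sum of motif adjacencies of G(tau) over tau in T.

    Motifs made of strong links survive more thresholds and therefore
    contribute to more summands.
    """
    if len(t_set) == 0:
        raise ValueError("threshold set is empty; nothing to aggregate")
    n = pte.n
    w = np.zeros((n, n), dtype=np.int64)
    for tau in t_set.thresholds:
        net = threshold_network(pte, float(tau))
        cens = census(net, collect_instances=True)
        w += motif_adjacency(cens, motif=motif, n=n).w
    return MotifAdjacency(w=w, motif=motif, node_labels=list(pte.region_labels))


def cluster_pipeline(
    pte: PTEMatrix,
    motif: int = APEX_MOTIF,
    percentile: float = 0.30,
    tau_min: float | None = None,
    tau_max: float | None = None,
    single_tau: float | None = None,
    ties: str = "error",
) -> Partition:
    """End-to-end partition: interval -> threshold set -> aggregation -> sweep.

    ``tau_min``/``tau_max`` override the automatic interval; ``single_tau``
    skips aggregation and clusters one thresholded network.  Nodes with zero
    aggregated motif degree form the non-participant third group.
    """
    if single_tau is not None:
        net = threshold_network(pte, single_tau)
        cens = census(net, collect_instances=True)
        w_agg = motif_adjacency(cens, motif=motif, n=pte.n)
        w_agg = MotifAdjacency(w=w_agg.w, motif=motif, node_labels=list(pte.region_labels))
        extra = {"single_tau": float(single_tau)}
    else:
        lo = find_tau_min(pte, percentile) if tau_min is None else float(tau_min)
        hi = find_tau_max(pte) if tau_max is None else float(tau_max)
        interval = ThresholdInterval(tau_min=lo, tau_max=hi, percentile_used=percentile)
        t_set = link_resolved_thresholds(pte, interval, ties=ties)
        if len(t_set) == 0:
            raise ValueError("threshold interval contains no link-resolved thresholds")
        w_agg = aggregate_motif_adjacency(pte, t_set, motif=motif)
        extra = {
            "tau_min": lo,
            "tau_max": hi,
            "n_thresholds": len(t_set),
            "grouped_ties": t_set.grouped_ties,
        }
    if not np.any(w_agg.w):
        raise NoMotifParticipationError(
            f"no node participates in any motif {motif} instance at the "
            "considered thresholds; nothing to partition"
        )
    partition = spectral_sweep(w_agg)
    partition.meta.update(extra)
    return partition
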