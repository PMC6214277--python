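"""3-node motif census, rewiring null model, overexpression calls, apex stats.

Motif identity follows the binary-adjacency encoding: a 3x3 adjacency matrix
read row-major as a 9-bit integer (a11 most significant), minimized over the
six simultaneous row/column permutations.  Under this encoding id 78 is the
bi-directional 2-hop path (a central "apex" node bidirectionally linked to
two otherwise disconnected nodes), and the 13 weakly connected classes are
{6, 12, 14, 36, 38, 46, 74, 78, 98, 102, 108, 110, 238}.

The census is induced: every 3-node subset is classified by its full induced
subgraph and counted at most once.  The null model rewires links while
preserving every node's in- and out-degree and the number of bi-directional
links, by swapping mutual dyads with mutual dyads and single arcs with single
arcs.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np

from .netbuild import DirectedBinaryNetwork
from .utils import pearson

__all__ = [
    "MotifCensus",
    "NullSummary",
    "MotifCall",
    "OverexpressionCall",
    "canonical_motif_id",
    "enumerate_3motifs",
    "census",
    "rewire_null",
    "null_distribution",
    "zscore",
    "call_overexpression",
    "apex_ratio",
    "high_degree_nodes",
    "degree_threshold",
    "apex_degree_correlation",
    "APEX_MOTIF",
]

APEX_MOTIF = 78

_PERMS3 = list(itertools.permutations(range(3)))
# off-diagonal cells of a 3x3 matrix in row-major order
_OFFDIAG3 = [(0, 1), (0, 2), (1, 0), (1, 2), (2, 0), (2, 1)]


def canonical_motif_id(adj3) -> int:
    """Canonical id: min over node relabelings of the 9-bit row-major reading."""
    a = np.asarray(adj3)
    if a.shape != (3, 3):
        raise ValueError("adjacency must be 3x3")
    if np.any(np.diag(a) != 0):
        raise ValueError("self-loops (nonzero diagonal) are not allowed")
    if not np.isin(a, (0, 1)).all():
        raise ValueError("adjacency must be binary")
    a = a.astype(int)
    best = 1 << 9
    for p in _PERMS3:
        v = 0
        for i in range(3):
            for j in range(3):
                v = (v << 1) | int(a[p[i], p[j]])
        if v < best:
            best = v
    return best


def _adj3_from_code(code: int) -> np.ndarray:
    a = np.zeros((3, 3), dtype=int)
    for k, (i, j) in enumerate(_OFFDIAG3):
        a[i, j] = (code >> (5 - k)) & 1
    return a


def _build_lut() -> np.ndarray:
    """Map each 6-bit off-diagonal code to its canonical id (0 = disconnected)."""
    lut = np.zeros(64, dtype=np.int64)
    for code in range(64):
        a = _adj3_from_code(code)
        und = a | a.T
        # a 3-node graph is weakly connected iff >= 2 of its 3 node pairs link
        if (np.triu(und, 1) != 0).sum() >= 2:
            lut[code] = canonical_motif_id(a)
    return lut


_LUT = _build_lut()


def enumerate_3motifs() -> list[int]:
    """All canonical ids of weakly connected 3-node digraphs, ascending."""
    return sorted({int(v) for v in _LUT if v > 0})


@dataclass
class MotifCensus:
    """Counts of distinct node sets per canonical motif id (induced census).

    ``instances`` lists the node-index triples per motif; it is None when the
    census was run in counts-only mode (e.g. inside the null model).
    """

    counts: dict
    instances: dict | None = None

    def __post_init__(self):
        if self.instances is not None:
            for m, c in self.counts.items():
                if len(self.instances.get(m, ())) != c:
                    raise ValueError(f"count/instances mismatch for motif {m}")

    def count(self, motif: int) -> int:
        return int(self.counts.get(motif, 0))

    def total(self) -> int:
        """Number of connected 3-node subsets."""
        return int(sum(self.counts.values()))


_TRIPLES_CACHE: dict[int, np.ndarray] = {}


def _all_triples(n: int) -> np.ndarray:
    tr = _TRIPLES_CACHE.get(n)
    if tr is None:
        tr = np.array(list(itertools.combinations(range(n), 3)), dtype=np.intp)
        if len(_TRIPLES_CACHE) > 8:
            _TRIPLES_CACHE.clear()
        _TRIPLES_CACHE[n] = tr
    return tr


def _triple_ids(a: np.ndarray, triples: np.ndarray) -> np.ndarray:
    i, j, k = triples[:, 0], triples[:, 1], triples[:, 2]
    code = (
        a[i, j] * 32
        + a[i, k] * 16
        + a[j, i] * 8
        + a[j, k] * 4
        + a[k, i] * 2
        + a[k, j]
    )
    return _LUT[code]


def census(net: DirectedBinaryNetwork, collect_instances: bool = True) -> MotifCensus:
    """Classify every connected induced 3-node subgraph by canonical id."""
    n = net.n
    counts: dict[int, int] = {}
    instances: dict[int, list] | None = {} if collect_instances else None
    if n >= 3 and net.n_links > 0:
        a = net.adjacency.astype(np.int64)
        triples = _all_triples(n)
        ids = _triple_ids(a, triples)
        sel = ids > 0
        if sel.any():
            bc = np.bincount(ids[sel])
            counts = {int(m): int(bc[m]) for m in np.nonzero(bc)[0]}
            if collect_instances:
                for row, m in zip(triples[sel], ids[sel]):
                    instances.setdefault(int(m), []).append(
                        (int(row[0]), int(row[1]), int(row[2]))
                    )
    return MotifCensus(counts=counts, instances=instances)


def _link_classes(a: np.ndarray):
    """Split directed links into mutual dyads (i<j) and single arcs."""
    mutual_mask = a & a.T
    iu, ju = np.nonzero(np.triu(mutual_mask, 1))
    mutual = list(zip(iu.tolist(), ju.tolist()))
    si, sj = np.nonzero(a & ~a.T)
    singles = list(zip(si.tolist(), sj.tolist()))
    return mutual, singles


def rewire_null(
    net: DirectedBinaryNetwork,
    switch_factor: int = 100,
    seed=None,
) -> DirectedBinaryNetwork:
    """Degree- and mutuality-preserving randomization by link switching.

    Performs switch_factor x (number of directed links) attempted swaps.
    Mutual dyads are swapped with mutual dyads, single arcs with single arcs;
    a swap is rejected if it would create a self-loop, duplicate a link, or
    convert between the classes.  Networks with no legal swap are returned
    unchanged with meta["rewire_unchanged"] = True.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    a = net.adjacency.copy()
    mutual, singles = _link_classes(a)
    n_directed = len(singles) + 2 * len(mutual)
    attempts = int(switch_factor) * n_directed
    accepted = 0
    n_single = len(singles)
    for _ in range(attempts):
        if rng.random() * n_directed < n_single:
            if n_single < 2:
                continue
            e1 = int(rng.integers(n_single))
            e2 = int(rng.integers(n_single))
            if e1 == e2:
                continue
            s, t = singles[e1]
            u, v = singles[e2]
            # candidate swap: (s,t),(u,v) -> (s,v),(u,t)
            if s == v or u == t:
                continue
            if a[s, v] or a[v, s] or a[u, t] or a[t, u]:
                continue
            a[s, t] = a[u, v] = False
            a[s, v] = a[u, t] = True
            singles[e1] = (s, v)
            singles[e2] = (u, t)
            accepted += 1
        else:
            n_mut = len(mutual)
            if n_mut < 2:
                continue
            e1 = int(rng.integers(n_mut))
            e2 = int(rng.integers(n_mut))
            if e1 == e2:
                continue
            s, t = mutual[e1]
            u, v = mutual[e2]
            if len({s, t, u, v}) < 4:
                continue
            if rng.random() < 0.5:
                p1, p2 = (s, u), (t, v)
            else:
                p1, p2 = (s, v), (t, u)
            (x1, y1), (x2, y2) = p1, p2
            if a[x1, y1] or a[y1, x1] or a[x2, y2] or a[y2, x2]:
                continue
            for x, y in ((s, t), (u, v)):
                a[x, y] = a[y, x] = False
            for x, y in (p1, p2):
                a[x, y] = a[y, x] = True
            mutual[e1] = (min(x1, y1), max(x1, y1))
            mutual[e2] = (min(x2, y2), max(x2, y2))
            accepted += 1
    meta = dict(net.meta)
    meta.update(
        rewire_attempts=attempts,
        rewire_accepted=accepted,
        rewire_unchanged=(accepted == 0),
    )
    return DirectedBinaryNetwork(adjacency=a, node_labels=list(net.node_labels), meta=meta)


@dataclass
class NullSummary:
    """Per-motif null statistics over a set of rewired networks."""

    motif_ids: list
    mean: dict
    sd: dict
    exceedance: dict  # empirical Pr[J_rand >= J_original]
    j_original: dict
    n_random: int

    def __post_init__(self):
        if self.n_random < 1:
            raise ValueError("n_random must be >= 1")
        for m, p in self.exceedance.items():
            if not (0.0 <= p <= 1.0):
                raise ValueError(f"exceedance probability out of range for motif {m}")


def null_distribution(
    net: DirectedBinaryNetwork,
    n_random: int = 1000,
    switch_factor: int = 100,
    seed: int = 0,
) -> NullSummary:
    """Census statistics over independently rewired copies of the network.

    The seed fans out to one substream per rewired network, so results do not
    depend on evaluation order.
    """
    ids = enumerate_3motifs()
    orig = census(net, collect_instances=False)
    j_orig = np.array([orig.count(m) for m in ids], dtype=float)
    counts = np.zeros((n_random, len(ids)), dtype=float)
    children = np.random.SeedSequence(seed).spawn(n_random)
    for r, child in enumerate(children):
        rnet = rewire_null(net, switch_factor=switch_factor, seed=np.random.default_rng(child))
        c = census(rnet, collect_instances=False)
        counts[r] = [c.count(m) for m in ids]
    mu = counts.mean(axis=0)
    sd = counts.std(axis=0, ddof=0)
    exceed = (counts >= j_orig[None, :]).mean(axis=0)
    return NullSummary(
        motif_ids=ids,
        mean={m: float(mu[k]) for k, m in enumerate(ids)},
        sd={m: float(sd[k]) for k, m in enumerate(ids)},
        exceedance={m: float(exceed[k]) for k, m in enumerate(ids)},
        j_original={m: int(j_orig[k]) for k, m in enumerate(ids)},
        n_random=n_random,
    )


def zscore(j_original: float, null: NullSummary, m: int) -> float:
    """(J_G,M - mu(J_rand,M)) / sigma(J_rand,M); NaN when sigma = 0."""
    sigma = null.sd[m]
    if sigma == 0.0:
        return float("nan")
    return (j_original - null.mean[m]) / sigma


@dataclass
class MotifCall:
    motif: int
    j: int
    mu: float
    sigma: float
    z: float
    p: float
    ratio: float
    passes_p: bool
    passes_count: bool
    passes_ratio: bool
    overexpressed: bool
    flags: list = field(default_factory=list)


@dataclass
class OverexpressionCall:
    """Overexpression decision per motif: all three criteria must pass."""

    calls: dict

    def overexpressed_ids(self) -> list[int]:
        return sorted(m for m, c in self.calls.items() if c.overexpressed)


def call_overexpression(
    cens: MotifCensus,
    null: NullSummary,
    p_threshold: float = 0.01,
    min_count: int = 4,
    min_ratio: float = 1.1,
) -> OverexpressionCall:
    """Apply the three overexpression criteria to every connected 3-motif.

    (i) empirical exceedance probability < 0.01, (ii) at least 4 instances
    with distinct node sets, (iii) J / mu(J_rand) >= 1.1.  A motif with
    mu = 0 but J > 0 passes the ratio criterion (flagged).
    """
    calls = {}
    for m in null.motif_ids:
        j = cens.count(m)
        mu = null.mean[m]
        sigma = null.sd[m]
        p = null.exceedance[m]
        flags = []
        z = zscore(j, null, m)
        if sigma == 0.0:
            flags.append("sigma_zero")
        if mu > 0:
            ratio = j / mu
            passes_ratio = ratio >= min_ratio
        elif j > 0:
            ratio = float("inf")
            passes_ratio = True
            flags.append("mu_zero")
        else:
            ratio = float("nan")
            passes_ratio = False
        passes_p = p < p_threshold
        passes_count = j >= min_count
        calls[m] = MotifCall(
            motif=m,
            j=j,
            mu=mu,
            sigma=sigma,
            z=z,
            p=p,
            ratio=ratio,
            passes_p=passes_p,
            passes_count=passes_count,
            passes_ratio=passes_ratio,
            overexpressed=passes_p and passes_count and passes_ratio,
            flags=flags,
        )
    return OverexpressionCall(calls=calls)


def apex_ratio(cens: MotifCensus, net: DirectedBinaryNetwork, motif: int = APEX_MOTIF) -> dict:
    """Fraction of a node's motif-78 participations spent at the apex position.

    Returns {node_index: ratio} for nodes in at least one instance; nodes in
    no instance are absent (undefined).
    """
    if motif != APEX_MOTIF:
        raise ValueError("only motif 78 has a distinguished apex position")
    if cens.instances is None:
        raise ValueError("census was computed without instance lists")
    a = net.adjacency
    participation: dict[int, int] = {}
    apex_counts: dict[int, int] = {}
    for inst in cens.instances.get(APEX_MOTIF, []):
        for node in inst:
            participation[node] = participation.get(node, 0) + 1
        for x in inst:
            others = [v for v in inst if v != x]
            y, z = others
            if a[x, y] and a[y, x] and a[x, z] and a[z, x]:
                apex_counts[x] = apex_counts.get(x, 0) + 1
                break
    return {
        node: apex_counts.get(node, 0) / part
        for node, part in participation.items()
    }


def degree_threshold(degrees, ddof: int = 0) -> float:
    """Hub cutoff: mean total degree plus one (population) standard deviation."""
    degrees = np.asarray(degrees, dtype=float)
    return float(degrees.mean() + degrees.std(ddof=ddof))


def high_degree_nodes(net: DirectedBinaryNetwork, ddof: int = 0) -> set[int]:
    """Nodes whose total degree is >= mean + 1 sd; empty network gives {}."""
    if net.n_links == 0:
        return set()
    deg = net.total_degrees()
    thr = degree_threshold(deg, ddof=ddof)
    return {int(i) for i in np.flatnonzero(deg >= thr)}


def apex_degree_correlation(ratios: dict, net: DirectedBinaryNetwork) -> float:
    """Pearson correlation of apex-ratio vs total degree, positive-ratio nodes.

    NaN (flagged undefined) for fewer than 3 qualifying nodes or zero
    variance.
    """
    nodes = sorted(node for node, r in ratios.items() if r > 0)
    if len(nodes) < 3:
        return float("nan")
    deg = net.total_degrees()
    return pearson([ratios[v] for v in nodes], [deg[v] for v in nodes])
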