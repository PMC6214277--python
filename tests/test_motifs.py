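from __future__ import annotations

import itertools
import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from flowmotifs import (
    DirectedBinaryNetwork,
    apex_degree_correlation,
    apex_ratio,
    call_overexpression,
    canonical_motif_id,
    census,
    enumerate_3motifs,
    high_degree_nodes,
    null_distribution,
    rewire_null,
    zscore,
)
from flowmotifs.motifs import NullSummary, degree_threshold
from conftest import bidirectional_star, make_network
from oracles import oracle_canonical_id, oracle_census_counts, random_digraph

ALL_13 = [6, 12, 14, 36, 38, 46, 74, 78, 98, 102, 108, 110, 238]


def _planted_78_rich_graph(n_leaves=7, n_uni=20, seed=0):
    """Two bidirectional stars plus cross-cluster leaf-to-leaf uni links."""
    n = 2 * (n_leaves + 1)
    hub2 = n_leaves + 1
    adj = np.zeros((n, n), dtype=bool)
    for hub, leaves in ((0, range(1, hub2)), (hub2, range(hub2 + 1, n))):
        for leaf in leaves:
            adj[hub, leaf] = adj[leaf, hub] = True
    rng = np.random.default_rng(seed)
    pairs = [(a, b) for a in range(1, hub2) for b in range(hub2 + 1, n)]
    rng.shuffle(pairs)
    for a, b in pairs[:n_uni]:
        adj[a, b] = True
    return DirectedBinaryNetwork(adjacency=adj)


def _hub_chain_graph(leaf_counts=(6, 4, 2)):
    """Mutually linked chain of hubs with decreasing leaf counts."""
    hubs = []
    edges = []
    node = 0
    for k in leaf_counts:
        hubs.append(node)
        for leaf in range(node + 1, node + 1 + k):
            edges += [(node, leaf), (leaf, node)]
        node += k + 1
    for h1, h2 in zip(hubs, hubs[1:]):
        edges += [(h1, h2), (h2, h1)]
    return make_network(node, edges)


class TestCanonicalId:
    def test_bidirectional_two_hop_path_is_78(self):
        a = np.zeros((3, 3), dtype=int)
        a[0, 2] = a[2, 0] = a[1, 2] = a[2, 1] = 1
        assert canonical_motif_id(a) == 78

    def test_chain_is_12(self):
        a = np.zeros((3, 3), dtype=int)
        a[0, 1] = a[1, 2] = 1
        assert canonical_motif_id(a) == 12

    def test_full_bidirectional_triangle_is_238(self):
        a = 1 - np.eye(3, dtype=int)
        assert canonical_motif_id(a) == 238

    def test_self_loop_rejected(self):
        with pytest.raises(ValueError, match="diagonal"):
            canonical_motif_id(np.eye(3, dtype=int))

    @given(st.integers(0, 63), st.integers(0, 5))
    @settings(max_examples=128, deadline=None)
    def test_invariant_under_relabeling_and_matches_oracle(self, code, perm_idx):
        from flowmotifs.motifs import _adj3_from_code

        a = _adj3_from_code(code)
        p = list(itertools.permutations(range(3)))[perm_idx]
        relabeled = a[np.ix_(p, p)]
        assert canonical_motif_id(relabeled) == canonical_motif_id(a)
        assert canonical_motif_id(a) == oracle_canonical_id(a)


class TestEnumerate:
    def test_thirteen_classes(self):
        assert len(enumerate_3motifs()) == 13

    def test_named_ids_present(self):
        ids = set(enumerate_3motifs())
        assert {6, 14, 74, 78, 102, 108} <= ids

    def test_full_set(self):
        assert enumerate_3motifs() == ALL_13

    def test_degenerate_forms_of_78(self):
        # removing one directed link from the bi-directional 2-hop path
        a = np.zeros((3, 3), dtype=int)
        a[0, 2] = a[2, 0] = a[1, 2] = a[2, 1] = 1
        ids = set()
        for i, j in ((0, 2), (2, 0), (1, 2), (2, 1)):
            b = a.copy()
            b[i, j] = 0
            ids.add(canonical_motif_id(b))
        assert ids == {14, 74}


class TestCensus:
    def test_single_instance_graph(self):
        net = make_network(3, [(0, 2), (2, 0), (1, 2), (2, 1)])
        assert census(net).counts == {78: 1}

    def test_bidirectional_star(self):
        net = bidirectional_star(2, [0, 1, 3], 4)
        assert census(net).counts == {78: 3}

    def test_empty_network(self):
        cens = census(make_network(5, []))
        assert cens.counts == {}
        assert cens.instances == {}

    def test_instances_match_counts(self, rng):
        a = random_digraph(10, 0.3, rng)
        cens = census(DirectedBinaryNetwork(adjacency=a))
        for m, c in cens.counts.items():
            assert len(cens.instances[m]) == c
            assert len(set(cens.instances[m])) == c  # distinct node sets

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_brute_force_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(4, 13))
        a = random_digraph(n, float(rng.uniform(0.1, 0.6)), rng)
        net = DirectedBinaryNetwork(adjacency=a)
        assert census(net, collect_instances=False).counts == oracle_census_counts(a)

    def test_total_counts_connected_subsets(self, rng):
        a = random_digraph(9, 0.4, rng)
        cens = census(DirectedBinaryNetwork(adjacency=a))
        assert cens.total() == sum(oracle_census_counts(a).values())


class TestRewireNull:
    def test_single_mutual_dyad_unchanged(self):
        net = make_network(4, [(0, 1), (1, 0)])
        out = rewire_null(net, seed=0)
        assert np.array_equal(out.adjacency, net.adjacency)
        assert out.meta["rewire_unchanged"]

    @pytest.mark.parametrize("seed", range(5))
    def test_preserves_degrees_and_mutual_dyads(self, seed):
        rng = np.random.default_rng(seed)
        a = random_digraph(15, 0.25, rng)
        net = DirectedBinaryNetwork(adjacency=a)
        out = rewire_null(net, switch_factor=20, seed=seed)
        b = out.adjacency
        assert np.array_equal(a.sum(axis=0), b.sum(axis=0))  # in-degrees
        assert np.array_equal(a.sum(axis=1), b.sum(axis=1))  # out-degrees
        assert (a & a.T).sum() == (b & b.T).sum()  # mutual dyads
        assert not np.any(np.diag(b))

    def test_actually_randomizes(self, rng):
        a = random_digraph(15, 0.3, rng)
        net = DirectedBinaryNetwork(adjacency=a)
        out = rewire_null(net, switch_factor=20, seed=1)
        assert not np.array_equal(a, out.adjacency)

    def test_seed_determinism(self, rng):
        a = random_digraph(12, 0.3, rng)
        net = DirectedBinaryNetwork(adjacency=a)
        o1 = rewire_null(net, seed=42)
        o2 = rewire_null(net, seed=42)
        assert np.array_equal(o1.adjacency, o2.adjacency)


class TestNullDistribution:
    def test_single_draw_mean_and_zero_sd(self, rng):
        a = random_digraph(10, 0.3, rng)
        net = DirectedBinaryNetwork(adjacency=a)
        null = null_distribution(net, n_random=1, switch_factor=5, seed=0)
        draw = census(rewire_null(net, 5, np.random.default_rng(
            np.random.SeedSequence(0).spawn(1)[0])), collect_instances=False)
        for m in null.motif_ids:
            assert null.mean[m] == draw.count(m)
            assert null.sd[m] == 0.0

    def test_absent_motif_exceedance_is_one(self):
        # graph with a single mutual dyad: every census (original and null)
        # is empty, so 0 >= 0 holds in every draw
        net = make_network(4, [(0, 1), (1, 0)])
        null = null_distribution(net, n_random=20, seed=1)
        assert null.exceedance[78] == 1.0

    def test_planted_78_rich_graph_significant(self):
        # two bidirectional 7-leaf stars plus cross-cluster uni links.  The
        # original is spoil-free (uni links never land inside a star), while
        # rewired uni links can destroy motif-78 instances, so the planted
        # count is significantly high.
        net = _planted_78_rich_graph()
        cens = census(net, collect_instances=False)
        null = null_distribution(net, n_random=1000, switch_factor=10, seed=2)
        assert null.exceedance[78] < 0.01
        calls = call_overexpression(cens, null)
        assert 78 in calls.overexpressed_ids()

    def test_order_independent_substreams(self, rng):
        a = random_digraph(10, 0.3, rng)
        net = DirectedBinaryNetwork(adjacency=a)
        n1 = null_distribution(net, n_random=10, switch_factor=5, seed=3)
        n2 = null_distribution(net, n_random=10, switch_factor=5, seed=3)
        assert n1.mean == n2.mean and n1.sd == n2.sd


class TestZscoreAndCalls:
    def _null(self, mu, sd, p, j, m=78):
        return NullSummary(
            motif_ids=[m],
            mean={m: mu},
            sd={m: sd},
            exceedance={m: p},
            j_original={m: j},
            n_random=1000,
        )

    def test_zscore_formula(self):
        assert zscore(110, self._null(100.0, 5.0, 0.5, 110), 78) == pytest.approx(2.0)

    def test_zscore_zero(self):
        assert zscore(100, self._null(100.0, 5.0, 0.5, 100), 78) == 0.0

    def test_zscore_sigma_zero_flagged_nan(self):
        assert math.isnan(zscore(5, self._null(5.0, 0.0, 1.0, 5), 78))

    def _census(self, j):
        from flowmotifs.motifs import MotifCensus

        return MotifCensus(counts={78: j} if j else {}, instances=None)

    def test_all_criteria_pass(self):
        calls = call_overexpression(self._census(10), self._null(10 / 1.2, 2.0, 0.005, 10))
        assert calls.calls[78].overexpressed

    def test_count_criterion_fails(self):
        calls = call_overexpression(self._census(3), self._null(1.5, 0.5, 0.005, 3))
        call = calls.calls[78]
        assert call.passes_p and call.passes_ratio and not call.passes_count
        assert not call.overexpressed

    def test_ratio_criterion_fails(self):
        calls = call_overexpression(self._census(10), self._null(10 / 1.05, 2.0, 0.005, 10))
        call = calls.calls[78]
        assert call.passes_p and call.passes_count and not call.passes_ratio
        assert not call.overexpressed

    def test_mu_zero_ratio_pass_flagged(self):
        calls = call_overexpression(self._census(6), self._null(0.0, 0.0, 0.0, 6))
        call = calls.calls[78]
        assert call.passes_ratio and "mu_zero" in call.flags


class TestApexRatio:
    def test_star_center_is_one_leaves_zero(self):
        net = bidirectional_star(2, [0, 1, 3], 4)
        ratios = apex_ratio(census(net), net)
        assert ratios[2] == 1.0
        assert ratios[0] == ratios[1] == ratios[3] == 0.0

    def test_isolated_node_undefined(self):
        net = bidirectional_star(0, [1, 2], 4)  # node 3 isolated
        ratios = apex_ratio(census(net), net)
        assert 3 not in ratios

    def test_only_motif_78_supported(self):
        net = bidirectional_star(0, [1, 2], 3)
        with pytest.raises(ValueError, match="apex"):
            apex_ratio(census(net), net, motif=108)

    def test_ratios_in_unit_interval(self, rng):
        a = random_digraph(12, 0.35, rng)
        net = DirectedBinaryNetwork(adjacency=a)
        for r in apex_ratio(census(net), net).values():
            assert 0.0 <= r <= 1.0


class TestHighDegree:
    def test_spec_arithmetic_case(self):
        # degrees [2,2,2,10]: mean 4, population sd ~3.464 -> only 10 qualifies
        degs = [2, 2, 2, 10]
        thr = degree_threshold(degs)
        assert thr == pytest.approx(4 + math.sqrt(12))
        assert [d >= thr for d in degs] == [False, False, False, True]

    def test_hub_graph(self):
        net = bidirectional_star(0, [1, 2, 3, 4, 5], 6)
        assert high_degree_nodes(net) == {0}

    def test_regular_network_all_qualify(self):
        # directed 4-cycle: every node has total degree 2
        net = make_network(4, [(0, 1), (1, 2), (2, 3), (3, 0)])
        assert high_degree_nodes(net) == {0, 1, 2, 3}

    def test_empty_network(self):
        assert high_degree_nodes(make_network(4, [])) == set()


class TestApexDegreeCorrelation:
    def test_too_few_nodes_nan(self):
        net = bidirectional_star(0, [1, 2], 3)
        assert math.isnan(apex_degree_correlation({0: 1.0, 1: 0.5}, net))

    def test_constant_ratios_nan(self):
        net = bidirectional_star(0, [1, 2, 3], 5)
        assert math.isnan(apex_degree_correlation({1: 0.5, 2: 0.5, 3: 0.5}, net))

    def test_perfect_linearity(self):
        # ratios proportional to degree over >= 3 qualifying nodes
        net = make_network(
            5, [(0, 1), (1, 0), (0, 2), (2, 0), (2, 3), (3, 2), (3, 4), (4, 3)]
        )
        deg = net.total_degrees()
        ratios = {i: deg[i] / 10.0 for i in range(5)}
        assert apex_degree_correlation(ratios, net) == pytest.approx(1.0)

    def test_planted_hub_graph_positive(self):
        # chain of hubs with decreasing leaf counts: bigger hubs spend a
        # larger share of their participations at the apex position
        net = _hub_chain_graph()
        ratios = apex_ratio(census(net), net)
        r = apex_degree_correlation(ratios, net)
        assert r > 0.0
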