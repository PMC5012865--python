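"""Traffic graphs: construction, chains, motifs, retrograde and sink stats."""

import itertools
from collections import Counter

import networkx as nx
import numpy as np
import pytest

from cisterna.boolean_core import run_to_orbit
from cisterna.network_analysis import (MotifCatalog, TrafficNetwork,
                                       _connected3_mask, _motif_code,
                                       build_network, canonical_code,
                                       connected_subsets, count_motifs,
                                       enumerate_motifs, find_chains,
                                       label_sinks, retrograde_stats,
                                       summarize)


@pytest.fixture(scope="module")
def catalog():
    return enumerate_motifs()


@pytest.fixture
def n2_net(n2_rules):
    return build_network(n2_rules, run_to_orbit(n2_rules, (1, 2)))


def simple_net(nodes, vesicle=(), creation=(), maturation=(), N=4):
    return TrafficNetwork(
        N=N, nodes=tuple(nodes),
        vesicle_edges={(a, b): frozenset(js) for a, b, js in vesicle},
        creation_edges=frozenset(creation),
        maturation_edges=dict(maturation))


class TestBuildNetwork:
    def test_worked_example(self, n2_net):
        assert n2_net.nodes == (1, 2)
        assert n2_net.vesicle_edges == {(1, 2): frozenset({1})}
        # the orphan X vesicle is budded by [10] itself: a self creation edge
        assert n2_net.creation_edges == {(2, 2)}
        assert n2_net.maturation_edges == {2: 1}
        assert n2_net.homotypic_types == {2}
        assert n2_net.stable_nodes == frozenset()
        assert n2_net.dissipating_nodes == {1}

    def test_transport_balance_self_edge(self, balanced_n1_rules):
        net = build_network(balanced_n1_rules, run_to_orbit(balanced_n1_rules, (1,)))
        assert net.nodes == (1,)
        assert net.vesicle_edges == {(1, 1): frozenset({1})}
        assert not net.creation_edges and not net.maturation_edges
        assert net.stable_nodes == {1}
        assert net.is_trivial()

    def test_rejects_non_homeostatic(self, period2_rules):
        orbit = run_to_orbit(period2_rules, (3,))
        with pytest.raises(ValueError):
            build_network(period2_rules, orbit)

    def test_maturation_self_edge_forbidden(self):
        with pytest.raises(ValueError):
            simple_net([1, 2], maturation=[(1, 1)])


class TestConnectedSubsets:
    def test_worked_example(self, n2_net):
        assert connected_subsets(n2_net) == [frozenset({1, 2})]

    def test_two_blocks(self):
        net = simple_net([1, 2, 4, 8], maturation=[(1, 2), (4, 8)])
        assert sorted(map(sorted, connected_subsets(net))) == [[1, 2], [4, 8]]

    def test_no_edges_all_singletons(self):
        net = simple_net([1, 2, 3])
        assert len(connected_subsets(net)) == 3
        assert net.is_trivial()


class TestChains:
    def test_worked_example(self, n2_net):
        chains, cycles = find_chains(n2_net)
        assert len(chains) == 1 and not cycles
        ch = chains[0]
        assert (ch.start, ch.length, ch.terminal_kind) == (2, 1, "fixed")
        assert ch.terminal == 1 and ch.dissipates is True

    def test_no_creation_no_chains(self):
        net = simple_net([1, 2], maturation=[(1, 2)])
        assert find_chains(net) == ([], [])

    def test_cycle_terminal(self):
        # creation feeds a 3-cycle of maturation edges
        net = simple_net([1, 2, 3, 4], creation=[(4, 1)],
                         maturation=[(1, 2), (2, 3), (3, 1)])
        chains, cycles = find_chains(net)
        assert chains[0].terminal_kind == "cycle"
        assert cycles == [(1, 2, 3)]

    def test_converging_chains_share_terminal(self):
        net = simple_net([1, 2, 3], creation=[(1, 1), (2, 2)],
                         maturation=[(1, 3), (2, 3)])
        chains, _ = find_chains(net)
        assert len(chains) == 2
        assert {c.terminal for c in chains} == {3}


class TestMotifCatalog:
    def test_labeled_space_and_class_count(self, catalog):
        assert len(catalog.canon) == 2 ** 18
        assert len(catalog) == 43700

    def test_single_edge_type_engine_matches_brute_force(self):
        cat1 = enumerate_motifs(edge_types=1)
        # independent canonicalizer over explicit edge lists
        seen = set()
        for code in range(1 << 9):
            edges = [(u, v) for u in range(3) for v in range(3)
                     if code >> (u * 3 + v) & 1]
            und = {frozenset(e) for e in edges if e[0] != e[1]}
            pairs = {frozenset(p) for p in itertools.combinations(range(3), 2)}
            linked = sum(1 for p in pairs if p in und)
            if linked < 2:
                continue
            best = min(
                sum(1 << (p[u] * 3 + p[v]) for u, v in edges)
                for p in itertools.permutations(range(3)))
            seen.add(best)
        assert len(seen) == len(cat1)

    def test_canonicalization_against_permutation_brute_force(self, catalog):
        rng = np.random.default_rng(0)
        for code in rng.integers(0, 1 << 18, size=1000):
            code = int(code)
            edges = [(t, u, v) for t in range(2) for u in range(3)
                     for v in range(3) if code >> (t * 9 + u * 3 + v) & 1]
            best = min(
                sum(1 << (t * 9 + p[u] * 3 + p[v]) for t, u, v in edges)
                for p in itertools.permutations(range(3)))
            assert int(catalog.canon[code]) == best
            assert canonical_code(code) == best

    def test_canonical_classes_are_isomorphism_classes(self, catalog):
        # networkx cross-check: same canonical code <=> isomorphic
        def to_nx(code):
            g = nx.MultiDiGraph()
            g.add_nodes_from(range(3))
            for t in range(2):
                for u in range(3):
                    for v in range(3):
                        if code >> (t * 9 + u * 3 + v) & 1:
                            g.add_edge(u, v, kind=t)
            return g

        rng = np.random.default_rng(1)
        codes = rng.integers(0, 1 << 18, size=30)
        for a, b in itertools.combinations(codes.tolist(), 2):
            iso = nx.is_isomorphic(
                to_nx(a), to_nx(b),
                edge_match=lambda x, y: Counter(d["kind"] for d in x.values())
                == Counter(d["kind"] for d in y.values()))
            assert iso == (catalog.canon[a] == catalog.canon[b])


class TestCountMotifs:
    def test_small_networks_have_no_motifs(self, catalog, n2_net):
        assert count_motifs(n2_net, catalog) == Counter()

    def test_three_node_chain_counts_once(self, catalog):
        net = simple_net([1, 2, 3], maturation=[(1, 2), (2, 3)])
        counts = count_motifs(net, catalog)
        assert sum(counts.values()) == 1
        code = _motif_code((1, 2, 3), [], [(1, 2), (2, 3)])
        assert counts == {catalog.index[int(catalog.canon[code])]: 1}

    def test_relabeling_invariance(self, catalog):
        net1 = simple_net([1, 2, 3, 5], creation=[(1, 2)],
                          maturation=[(2, 3), (3, 5)])
        net2 = simple_net([2, 4, 8, 9], creation=[(9, 4)],
                          maturation=[(4, 2), (2, 8)])
        assert count_motifs(net1, catalog) == count_motifs(net2, catalog)

    def test_disconnected_triples_excluded(self, catalog):
        net = simple_net([1, 2, 3, 4], maturation=[(1, 2), (3, 4)])
        counts = count_motifs(net, catalog)
        assert sum(counts.values()) == 0


class TestRetrograde:
    def test_caption_worked_example(self):
        # ten compartments, eight maturing pairs, six of them with a
        # retrograde vesicle, eight retrograde-bearing pairs in total
        nodes = list(range(1, 11))
        maturation = [(i, i + 1) for i in range(1, 9)]
        vesicle = [(i + 1, i, [1]) for i in range(1, 7)]
        vesicle += [(9, 1, [1]), (10, 1, [1])]
        net = simple_net(nodes, vesicle=vesicle, maturation=maturation)
        rs = retrograde_stats(net)
        assert rs.n_maturation_edges == 8
        assert rs.f_all == pytest.approx(8 / 90)
        assert rs.f_a_matures_to_b == pytest.approx(6 / 8)

    def test_no_vesicle_edges(self):
        net = simple_net([1, 2, 3], maturation=[(1, 2)])
        rs = retrograde_stats(net)
        assert rs.f_all == 0 and rs.f_a_matures_to_b == 0

    def test_complete_vesicle_digraph(self):
        nodes = [1, 2, 3]
        ves = [(a, b, [1]) for a in nodes for b in nodes if a != b]
        net = simple_net(nodes, vesicle=ves, maturation=[(1, 2)])
        rs = retrograde_stats(net)
        assert rs.f_all == 1 and rs.f_a_matures_to_b == 1

    def test_undefined_conditionals_are_none(self):
        net = simple_net([1, 2], vesicle=[(1, 2, [1])])
        rs = retrograde_stats(net)
        assert rs.f_b_matures_to_a is None and rs.f_a_matures_to_b is None

    def test_self_edges_excluded(self):
        net = simple_net([1, 2], vesicle=[(1, 1, [1])], maturation=[(1, 2)])
        assert retrograde_stats(net).f_all == 0


class TestLabelSinks:
    def test_minimal_sink(self):
        # label 0 of N=4 is bit 8; edge 1->2 carries it, nothing leaves 2
        net = simple_net([1, 2], vesicle=[(1, 2, [8])])
        assert label_sinks(net) == {0}

    def test_uncarried_label_no_sink(self):
        net = simple_net([1, 2], vesicle=[(1, 2, [8])])
        assert 3 not in label_sinks(net)

    def test_worked_example(self, n2_net):
        # Y (label 1) flows [01]->[10] and never leaves; X (label 0) only
        # cycles through the self creation edge, which is no sink
        assert label_sinks(n2_net) == {1}

    def test_cycling_label_no_sink(self):
        net = simple_net([1, 2], vesicle=[(1, 2, [8]), (2, 1, [8])])
        assert label_sinks(net) == frozenset()


class TestSummarize:
    def test_worked_example(self, n2_net):
        row = summarize([n2_net]).iloc[0]
        assert row["n_compartments"] == 2
        assert row["n_vesicle_types"] == 2
        assert row["n_stable"] == 0
        assert row["n_chains"] == 1 and row["max_chain_length"] == 1
        assert not row["trivial"]

    def test_balanced_network(self, balanced_n1_rules):
        net = build_network(balanced_n1_rules,
                            run_to_orbit(balanced_n1_rules, (1,)))
        row = summarize([net]).iloc[0]
        assert row["maturation_fraction"] == 0
        assert row["n_stable"] == 1 and row["trivial"]


def test_chain_lengths_geometric(networks_n7):
    """Chain lengths pooled over the sweep decay like a geometric law:
    monotone decreasing with roughly constant successive ratios."""
    lengths = Counter()
    for net in networks_n7:
        for ch in find_chains(net)[0]:
            if ch.length >= 1:
                lengths[ch.length] += 1
    counts = [lengths[k] for k in range(1, 7)]
    assert all(a >= b for a, b in zip(counts, counts[1:]))
    ratios = [b / a for a, b in zip(counts, counts[1:]) if a > 50]
    assert max(ratios) - min(ratios) < 0.35
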