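"""Median-joining network construction and its structural guarantees."""

from itertools import combinations

import networkx as nx
import numpy as np
import pytest

from mitopop import haplotypes as hap
from mitopop import mj_network as mj
from mitopop.io_formats import AlignedSequenceSet


def _aln(*rows):
    return AlignedSequenceSet.from_records(
        [(f"s{i+1}", r) for i, r in enumerate(rows)]
    )


def _net(*rows, epsilon=0):
    table = hap.collapse_haplotypes(_aln(*rows))
    return mj.median_joining(table, mj.NetworkParams(epsilon=epsilon)), table


class TestCondense:
    def test_monomorphic_empty_matrix(self):
        table = hap.collapse_haplotypes(_aln("ACGT", "ACGT"))
        patterns, sites = mj.condense_characters(table)
        assert patterns == [""] and sites == ()

    def test_positions_retained(self):
        table = hap.collapse_haplotypes(_aln("ACGTA", "AAGTC", "ACGTC"))
        patterns, sites = mj.condense_characters(table)
        assert sites == (2, 5)
        assert patterns == ["CA", "AC", "CC"]

    def test_duplicate_columns_kept_separately(self):
        table = hap.collapse_haplotypes(_aln("AA", "CC"))
        patterns, sites = mj.condense_characters(table)
        assert sites == (1, 2)
        assert patterns == ["AA", "CC"]


class TestQuasiMedians:
    def test_majority_per_site(self):
        assert mj.quasi_medians("AAA", "CCA", "CAC") == ["CAA"]

    def test_three_way_tie_generates_all(self):
        meds = mj.quasi_medians("A", "C", "G")
        assert sorted(meds) == ["A", "C", "G"]

    def test_cap_enforced(self):
        u, v, w = "A" * 11, "C" * 11, "G" * 11
        with pytest.raises(ValueError):
            mj.quasi_medians(u, v, w, cap=2 ** 10)


class TestMedianJoining:
    def test_chain_is_path_without_medians(self):
        net, _ = _net("AAA", "CAA", "CCA", "CCC")
        s = mj.network_summary(net)
        assert (s["n_observed"], s["n_median_vectors"], s["n_edges"]) == (4, 0, 3)
        labels = sorted(
            tuple(d["positions"]) for _, _, d in net.graph.edges(data=True)
        )
        assert labels == [(1,), (2,), (3,)]

    def test_star_center_degree_four(self):
        net, _ = _net("AAAA", "CAAA", "ACAA", "AACA", "AAAC")
        s = mj.network_summary(net)
        assert (s["n_observed"], s["n_median_vectors"]) == (5, 0)
        assert dict(net.graph.degree())["H1"] == 4

    def test_triplet_creates_single_median_vector(self):
        """000/110/101 (binary coded as A/C) yields the quasi-median 100
        adjacent to all three observed nodes at one step each."""
        net, _ = _net("AAA", "CCA", "CAC")
        s = mj.network_summary(net)
        assert (s["n_observed"], s["n_median_vectors"], s["n_edges"]) == (3, 1, 3)
        mv = net.median_vectors[0]
        assert net.graph.nodes[mv]["pattern"] == "CAA"
        assert all(net.graph.has_edge(mv, h) for h in ("H1", "H2", "H3"))
        assert all(
            len(net.graph.edges[mv, h]["positions"]) == 1 for h in ("H1", "H2", "H3")
        )

    def test_single_haplotype_trivial_network(self):
        net, _ = _net("ACGT", "ACGT", "ACGT")
        s = mj.network_summary(net)
        assert s == {
            "n_observed": 1,
            "n_median_vectors": 0,
            "n_edges": 0,
            "max_frequency_node": "H1",
        }
        assert net.graph.nodes["H1"]["frequency"] == 3

    def test_duplicate_individual_changes_size_only(self):
        net_a, _ = _net("AAA", "CAA", "CCA")
        net_b, _ = _net("AAA", "AAA", "CAA", "CCA")
        assert nx.is_isomorphic(
            net_a.graph,
            net_b.graph,
            node_match=lambda a, b: a["pattern"] == b["pattern"],
        )
        assert net_b.graph.nodes["H1"]["frequency"] == 2

    def test_frequencies_conserved_from_table(self):
        net, table = _net("AAA", "CAA", "AAA", "CCA", "AAA")
        for i, h in enumerate(table.haplotypes):
            assert net.graph.nodes[f"H{i+1}"]["frequency"] == h.count

    def test_edge_labels_equal_hamming_distance(self):
        rng = np.random.default_rng(83)
        for _ in range(20):
            rows = [
                "".join(rng.choice(["A", "C"], 6)) for _ in range(int(rng.integers(2, 6)))
            ]
            rows = list(dict.fromkeys(rows)) or ["AAAAAA"]
            if len(rows) < 2:
                continue
            net, _ = _net(*rows)
            for a, b, data in net.graph.edges(data=True):
                pa = net.graph.nodes[a]["pattern"]
                pb = net.graph.nodes[b]["pattern"]
                ham = sum(x != y for x, y in zip(pa, pb))
                assert len(data["positions"]) == ham == data["weight"]

    def test_tree_like_data_equals_mst(self):
        """With epsilon 0 and homoplasy-free characters the network is the
        unique minimum spanning tree (multi-site edges as single links)."""
        # perfect phylogeny: ((s1,s2),(s3,s4)) with unique sites per edge
        rows = ["AAAAA", "CAAAA", "AACCA", "AACCC"]
        net, _ = _net(*rows)
        g = net.graph
        assert net.median_vectors == []
        assert g.number_of_edges() == 3  # a tree on 4 observed nodes
        assert nx.is_connected(g)
        # distances along the network equal Hamming distances
        dist = dict(nx.all_pairs_dijkstra_path_length(g, weight="weight"))
        for a, b in combinations(g.nodes, 2):
            pa, pb = g.nodes[a]["pattern"], g.nodes[b]["pattern"]
            assert dist[a][b] == sum(x != y for x, y in zip(pa, pb))

    def test_exhaustive_small_binary_instances(self):
        """Exhaustive sweep over all 2-5 subsets of the 3-cube.

        At epsilon 0: the network is connected, observed-pair network
        distance never undercuts the Hamming distance, every median vector
        lies on a minimal observed-observed path — and on homoplasy-free
        subsets (four-gamete-compatible, where a perfect phylogeny exists)
        the network realizes the Hamming distance exactly, the brute-force
        minimal-network criterion.  At epsilon 3 (full relaxation) every
        subset realizes Hamming distances exactly."""
        from itertools import product

        def four_gamete_compatible(subset):
            L = len(subset[0])
            for i, j in combinations(range(L), 2):
                if len({(r[i], r[j]) for r in subset}) == 4:
                    return False
            return True

        cube = ["".join(p) for p in product("AC", repeat=3)]
        checked = 0
        for k in range(2, 6):
            for subset in combinations(cube, k):
                for eps in (0, 3):
                    net, _ = _net(*subset, epsilon=eps)
                    g = net.graph
                    assert nx.is_connected(g)
                    dist = dict(nx.all_pairs_dijkstra_path_length(g, weight="weight"))
                    obs = net.observed
                    exact = eps == 3 or four_gamete_compatible(subset)
                    for a, b in combinations(obs, 2):
                        pa, pb = g.nodes[a]["pattern"], g.nodes[b]["pattern"]
                        ham = sum(x != y for x, y in zip(pa, pb))
                        if exact:
                            assert dist[a][b] == ham
                        else:
                            assert dist[a][b] >= ham
                    for mv in net.median_vectors:
                        assert any(
                            abs(dist[a][mv] + dist[mv][b] - dist[a][b]) < 1e-9
                            for a, b in combinations(obs, 2)
                        )
                checked += 1
        assert checked == sum(
            __import__("math").comb(8, k) for k in range(2, 6)
        )


class TestNetworkParams:
    def test_negative_epsilon_rejected(self):
        with pytest.raises(ValueError):
            mj.NetworkParams(epsilon=-1)

    def test_epsilon_relaxation_adds_links(self):
        """A larger epsilon can only add feasible links, never remove."""
        rows = ["AAAA", "CCAA", "AACC", "CCCC"]
        net0, _ = _net(*rows, epsilon=0)
        net2, _ = _net(*rows, epsilon=2)
        edges0 = {
            frozenset((net0.graph.nodes[a]["pattern"], net0.graph.nodes[b]["pattern"]))
            for a, b in net0.graph.edges
        }
        edges2 = {
            frozenset((net2.graph.nodes[a]["pattern"], net2.graph.nodes[b]["pattern"]))
            for a, b in net2.graph.edges
        }
        obs0 = {net0.graph.nodes[n]["pattern"] for n in net0.observed}
        # every epsilon-0 link between still-present nodes survives relaxation
        surviving = {
            e for e in edges0 if all(p in {net2.graph.nodes[n]["pattern"] for n in net2.graph} for p in e)
        }
        assert surviving <= edges2
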