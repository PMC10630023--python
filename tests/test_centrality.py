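import math
import random

import networkx as nx
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from conftest import build_network
from netmarker.centrality import (
    SelectionResult,
    betweenness_centrality,
    consensus_candidates,
    degree_centrality,
    hub_bottlenecks,
    hub_threshold,
    read_centrality_table,
    select_bottlenecks,
    select_hubs,
    select_network,
    write_selection_table,
)
from netmarker.network import Network
from oracles import brute_betweenness

MERGED_HUBS = {"APOA1", "TF", "GC", "HP", "FGG", "FGB", "FGA", "APOB"}
MERGED_BOTTLENECKS = {
    "CDC20", "FBXO5", "NUP107", "TF", "APOA1", "SEH1L", "GC", "TUBB3", "HP",
    "KRT1", "ARHGEF7",
}


def random_network(n, p, seed):
    g = nx.gnp_random_graph(n, p, seed=seed)
    net = Network(nodes={str(v) for v in g.nodes()})
    for a, b in g.edges():
        net.add_edge(str(a), str(b), source="r")
    return net


class TestDegreeCentrality:
    def test_k4(self, k4):
        assert set(degree_centrality(k4).values()) == {3}

    def test_isolated_node(self):
        net = build_network([("A", "B")], nodes=["Z"])
        assert degree_centrality(net)["Z"] == 0

    def test_path5(self, path5):
        deg = degree_centrality(path5)
        assert [deg[v] for v in "ABCDE"] == [1, 2, 2, 2, 1]

    def test_degree_sum_is_twice_edges(self, k4):
        assert sum(degree_centrality(k4).values()) == 2 * k4.n_edges


class TestBetweenness:
    def test_three_node_path(self):
        net = build_network([("A", "B"), ("B", "C")])
        bc = betweenness_centrality(net)
        assert bc == {"A": 0.0, "B": 1.0, "C": 0.0}

    def test_k4_all_zero(self, k4):
        assert set(betweenness_centrality(k4).values()) == {0.0}

    def test_small_graph_convention(self):
        net = build_network([("A", "B")])
        assert set(betweenness_centrality(net).values()) == {0.0}

    def test_random_8_node_matches_oracle(self):
        net = random_network(8, 0.4, seed=123)
        bc = betweenness_centrality(net)
        oracle = brute_betweenness(net)
        for v in net.nodes:
            assert bc[v] == pytest.approx(oracle[v], abs=1e-9)

    def test_matches_oracle_on_many_small_graphs(self):
        rng = random.Random(0)
        for trial in range(50):
            n = rng.randint(3, 9)
            net = random_network(n, rng.uniform(0.2, 0.8), seed=trial)
            bc = betweenness_centrality(net)
            oracle = brute_betweenness(net)
            for v in net.nodes:
                assert bc[v] == pytest.approx(oracle[v], abs=1e-9), (trial, v)

    def test_disconnected_normalized_per_component(self):
        # two disjoint 3-paths: each middle node mediates its own component
        net = build_network([("A", "B"), ("B", "C"), ("X", "Y"), ("Y", "Z")])
        bc = betweenness_centrality(net)
        assert bc["B"] == pytest.approx(1.0)
        assert bc["Y"] == pytest.approx(1.0)

    def test_raw_mode(self):
        net = build_network([("A", "B"), ("B", "C")])
        assert betweenness_centrality(net, normalized=False)["B"] == pytest.approx(1.0)


class TestHubThreshold:
    def test_all_equal(self):
        assert hub_threshold({"a": 5, "b": 5, "c": 5}) == pytest.approx(5.0)

    def test_hand_computed_sample_sd(self):
        # degrees (1,1,1,1,10): mean 2.8, sample SD sqrt(16.2)
        thr = hub_threshold({c: d for c, d in zip("abcde", (1, 1, 1, 1, 10))})
        assert thr == pytest.approx(2.8 + 2 * math.sqrt(16.2), abs=1e-9)

    def test_hand_computed_small(self):
        assert hub_threshold({"a": 0, "b": 2, "c": 4}) == pytest.approx(6.0)

    def test_population_sd_switch(self):
        thr = hub_threshold({"a": 0, "b": 2, "c": 4}, ddof=0)
        assert thr == pytest.approx(2 + 2 * math.sqrt(8.0 / 3.0))

    def test_single_node_rejected(self):
        with pytest.raises(ValueError):
            hub_threshold({"a": 3})


class TestSelectHubs:
    def test_demo_degrees_at_cutoff_14(self, demo_selection):
        records, _ = demo_selection
        degrees = {r.node: r.degree for r in records}
        assert select_hubs(degrees, 14) == MERGED_HUBS

    def test_above_max_empty(self):
        assert select_hubs({"a": 3, "b": 5}, 10) == set()

    def test_zero_threshold_selects_all(self):
        assert select_hubs({"a": 0, "b": 5}, 0) == {"a", "b"}

    @settings(max_examples=50, deadline=None)
    @given(
        st.dictionaries(st.text("abcdef", min_size=1, max_size=3),
                        st.integers(0, 50), min_size=1),
        st.floats(0, 50), st.floats(0, 50),
    )
    def test_monotone_in_threshold(self, degrees, t1, t2):
        lo, hi = min(t1, t2), max(t1, t2)
        assert select_hubs(degrees, hi) <= select_hubs(degrees, lo)


class TestSelectBottlenecks:
    def test_top_decile_of_110(self):
        bc = {f"n{i}": i / 110.0 for i in range(110)}
        picked = select_bottlenecks(bc, 0.10)
        assert len(picked) == 11
        assert picked == {f"n{i}" for i in range(99, 110)}

    def test_all_ties_resolved_by_policy(self):
        bc = {c: 0.5 for c in "abcdefghij"}
        deg = {c: 1 for c in "abcdefghij"}
        deg["d"] = 9
        assert select_bottlenecks(bc, 0.10, degrees=deg) == {"d"}

    def test_lexicographic_fallback(self):
        bc = {c: 0.5 for c in "abcdefghij"}
        assert select_bottlenecks(bc, 0.10) == {"a"}

    def test_fraction_one_selects_all(self):
        bc = {"a": 0.1, "b": 0.2}
        assert select_bottlenecks(bc, 1.0) == {"a", "b"}

    def test_invalid_fraction(self):
        with pytest.raises(ValueError):
            select_bottlenecks({"a": 0.1}, 0.0)


class TestHubBottlenecks:
    def test_printed_worked_example(self):
        sel = SelectionResult(hubs=set(MERGED_HUBS), bottlenecks=set(MERGED_BOTTLENECKS))
        assert hub_bottlenecks(sel) == {"APOA1", "TF", "GC", "HP"}

    def test_disjoint(self):
        sel = SelectionResult(hubs={"a"}, bottlenecks={"b"})
        assert hub_bottlenecks(sel) == set()

    def test_hubs_subset_of_bottlenecks(self):
        sel = SelectionResult(hubs={"a", "b"}, bottlenecks={"a", "b", "c"})
        assert hub_bottlenecks(sel) == {"a", "b"}

    def test_always_subset_of_both(self, demo_selection):
        _, sel = demo_selection
        assert sel.hub_bottlenecks <= sel.hubs
        assert sel.hub_bottlenecks <= sel.bottlenecks


class TestConsensus:
    QUERY = {"APOA1", "TF", "GC", "HP", "KRT1", "FGB", "FGG"}

    def test_two_network_consensus(self):
        merged = SelectionResult(hub_bottlenecks_override={"TF", "APOA1", "GC", "HP"})
        hprd = SelectionResult(hub_bottlenecks_override={"TF", "APOA1", "GC", "KRT1"})
        assert consensus_candidates([merged, hprd], self.QUERY) == {"TF", "APOA1", "GC"}

    def test_single_selection(self):
        sel = SelectionResult(hub_bottlenecks_override={"TF", "ZZZ"})
        assert consensus_candidates([sel], self.QUERY) == {"TF"}

    def test_empty_selection_gives_empty(self):
        a = SelectionResult(hub_bottlenecks_override={"TF"})
        b = SelectionResult(hub_bottlenecks_override=set())
        assert consensus_candidates([a, b], self.QUERY) == set()

    def test_no_selections_rejected(self):
        with pytest.raises(ValueError):
            consensus_candidates([], self.QUERY)


class TestSelectNetwork:
    def test_planted_hubs_recovered(self):
        from netmarker.synthetic import gen_ppi_network

        net, truth = gen_ppi_network(300, 1, seed=9, n_planted_hubs=2, hub_degree=60)
        selection, _ = select_network(net)
        assert truth.planted_hub_nodes <= selection.hubs

    def test_bottleneck_count_matches_ceil(self):
        net = random_network(50, 0.1, seed=5)
        selection, _ = select_network(net, bottleneck_fraction=0.10)
        assert len(selection.bottlenecks) == 5

    def test_override_threshold_recorded(self, k4):
        selection, _ = select_network(k4, hub_threshold_override=2)
        assert selection.hub_threshold == 2.0
        assert selection.hubs == k4.nodes


class TestSelectionTableIO:
    def test_round_trip(self, tmp_path, demo_selection):
        records, sel = demo_selection
        path = tmp_path / "sel.tsv"
        write_selection_table(records, sel, path)
        text = path.read_text()
        assert "APOA1" in text and "hub_bottleneck" in text

    def test_read_centrality_table_threshold(self, demo_selection):
        _, sel = demo_selection
        assert sel.hub_threshold == 14.0
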