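"""Background-network loading, shortest-path local networks, statistics,
export round-trips and the background overlay."""

import itertools
from collections import deque

import networkx as nx
import numpy as np
import pandas as pd
import pytest

import treking as tk
from treking.netgen import annotate_functionality, packaged_kinome

TOY_TSV = """Kinase-substrate dataset
some preamble line

GENE\tKIN_ORGANISM\tSUB_GENE\tSUB_ORGANISM\tSUB_MOD_RSD
MAPK14\thuman\tMAPKAPK2\thuman\tT334
MAPK14\thuman\tMAPKAPK2\thuman\tT222
MAP2K3\thuman\tMAPK14\thuman\tT180
MAP2K3\tmouse\tMAPK14\tmouse\tT180
SRC\thuman\tGAPDH\thuman\tY94
PRKACA\thuman\tPRKACA\thuman\tS338
"""

KINOME = ["MAPK14", "MAPKAPK2", "MAP2K3", "SRC", "PRKACA"]


def bfs_all_shortest_union(G, members):
    """Independent oracle: BFS per ordered pair, union of all shortest paths."""
    edges, nodes = set(), set()
    for a, b in itertools.permutations(sorted(members), 2):
        if a not in G or b not in G:
            continue
        # BFS distances from a
        dist = {a: 0}
        q = deque([a])
        while q:
            u = q.popleft()
            for v in G.successors(u):
                if v not in dist:
                    dist[v] = dist[u] + 1
                    q.append(v)
        if b not in dist:
            continue
        # walk back from b along decreasing distance
        on_path_edges = set()
        frontier = {b}
        while frontier:
            nxt = set()
            for v in frontier:
                for u in G.predecessors(v):
                    if u in dist and dist[u] + 1 == dist[v]:
                        on_path_edges.add((u, v))
                        if dist[u] > 0:
                            nxt.add(u)
            frontier = nxt
        edges |= on_path_edges
        nodes |= {n for e in on_path_edges for n in e}
    return nodes, edges


class TestLoadKinaseSubstrate:
    def test_filters_and_dedup(self, tmp_path):
        p = tmp_path / "ks.tsv"
        p.write_text(TOY_TSV)
        net = tk.load_kinase_substrate(p, organism="human", kinome=KINOME)
        # 2 phosphosites on one edge dedup to 1; mouse row and the
        # non-kinase substrate (GAPDH) drop; self-loop retained
        assert set(net.graph.edges) == {
            ("MAPK14", "MAPKAPK2"), ("MAP2K3", "MAPK14"), ("PRKACA", "PRKACA")}
        assert net.graph.has_edge("PRKACA", "PRKACA")
        assert net.provenance["rows_kept"] == 4

    def test_missing_columns(self, tmp_path):
        p = tmp_path / "bad.tsv"
        p.write_text("GENE\tSUB_GENE\nA\tB\n")
        with pytest.raises(ValueError, match="KIN_ORGANISM"):
            tk.load_kinase_substrate(p, kinome=["A", "B"])

    def test_empty_after_filters_warns(self, tmp_path):
        p = tmp_path / "ks.tsv"
        p.write_text(TOY_TSV)
        net = tk.load_kinase_substrate(p, organism="rat", kinome=KINOME)
        assert net.n_edges == 0

    def test_packaged_kinome_is_nonempty_symbol_list(self):
        ks = packaged_kinome()
        assert len(ks) > 200
        assert "MAPK14" in ks and "MAPKAPK2" in ks
        assert all(k == k.strip() and k for k in ks)


class TestLocalNetwork:
    def test_chain_with_inferred_intermediate(self, chain_background):
        L = tk.build_local_network({"A", "C"}, chain_background)
        assert set(L.graph.nodes) == {"A", "B", "C"}
        assert set(L.graph.edges) == {("A", "B"), ("B", "C")}
        assert L.graph.nodes["B"]["role"] == "inferred"
        assert L.graph.nodes["A"]["role"] == "predicted"

    def test_diamond_includes_both_paths(self):
        G = nx.DiGraph([("A", "B"), ("B", "D"), ("A", "C"), ("C", "D")])
        bg = tk.BackgroundNetwork(graph=G)
        L = tk.build_local_network({"A", "D"}, bg)
        assert L.graph.number_of_nodes() == 4
        assert L.graph.number_of_edges() == 4

    def test_unconnected_members_give_none(self, chain_background):
        assert tk.build_local_network({"A", "X2"}, chain_background) is None

    def test_singleton_without_self_loop_gives_none(self, chain_background):
        assert tk.build_local_network({"A"}, chain_background) is None

    def test_singleton_with_autophosphorylation(self, chain_background):
        L = tk.build_local_network({"X"}, chain_background)
        assert set(L.graph.edges) == {("X", "X")}

    def test_empty_members_rejected(self, chain_background):
        with pytest.raises(ValueError):
            tk.build_local_network(set(), chain_background)

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_bfs_oracle(self, seed):
        rng = np.random.default_rng(seed)
        for rep in range(20):
            n = int(rng.integers(4, 13))
            G = nx.DiGraph()
            G.add_nodes_from(f"n{i}" for i in range(n))
            for u in range(n):
                for v in range(n):
                    if u != v and rng.random() < 0.25:
                        G.add_edge(f"n{u}", f"n{v}")
            bg = tk.BackgroundNetwork(graph=G)
            members = set(rng.choice([f"n{i}" for i in range(n)],
                                     size=int(rng.integers(2, min(n, 5) + 1)),
                                     replace=False))
            L = tk.build_local_network(members, bg)
            nodes, edges = bfs_all_shortest_union(G, members)
            if not edges:
                assert L is None
            else:
                assert set(L.graph.edges) == edges
                assert set(L.graph.nodes) == nodes

    def test_inferred_nodes_lie_inside_paths(self):
        rng = np.random.default_rng(99)
        G = nx.gnp_random_graph(10, 0.3, directed=True, seed=3)
        G = nx.relabel_nodes(G, {i: f"n{i}" for i in range(10)})
        bg = tk.BackgroundNetwork(graph=G)
        L = tk.build_local_network({"n0", "n5", "n9"}, bg)
        if L is not None:
            for node in L.inferred:
                assert L.graph.in_degree(node) >= 1
                assert L.graph.out_degree(node) >= 1

    def test_adding_member_never_removes_edges(self, chain_background):
        L1 = tk.build_local_network({"A", "C"}, chain_background)
        L2 = tk.build_local_network({"A", "C", "D"}, chain_background)
        assert set(L1.graph.edges) <= set(L2.graph.edges)


class TestComposite:
    def _assignment(self, members_by_neuron):
        from treking.som import SOMConfig, TrainedSOM
        som = TrainedSOM(np.zeros((6, 6, 2)), SOMConfig(), 0, 0)
        k2n = {k: n for n, ms in members_by_neuron.items() for k in ms}
        return tk.NeuronAssignment(kinase_to_neuron=k2n,
                                   members=members_by_neuron, som=som)

    def test_two_neurons_span_graph(self, chain_background):
        assign = self._assignment({(0, 0): ["A"], (0, 1): ["C"]})
        L = tk.composite_network([(0, 0), (0, 1)], assign, chain_background)
        assert set(L.graph.nodes) == {"A", "B", "C"}

    def test_single_neuron_identity(self, chain_background):
        assign = self._assignment({(0, 0): ["A", "C"]})
        Lc = tk.composite_network([(0, 0)], assign, chain_background)
        L = tk.build_local_network({"A", "C"}, chain_background)
        assert set(Lc.graph.edges) == set(L.graph.edges)

    def test_unreachable_pool_gives_none(self, chain_background):
        assign = self._assignment({(0, 0): ["D"], (0, 1): ["A2"]})
        assert tk.composite_network([(0, 0), (0, 1)], assign,
                                    chain_background) is None

    def test_all_empty_neurons_rejected(self, chain_background):
        assign = self._assignment({})
        with pytest.raises(ValueError):
            tk.composite_network([(0, 0)], assign, chain_background)


class TestNetworkStats:
    def test_chain_of_three(self, chain_background):
        L = tk.build_local_network({"A", "C"}, chain_background)
        assert tk.network_stats(L)["max_path_nodes"] == 3

    def test_single_self_loop_node(self, chain_background):
        L = tk.build_local_network({"X"}, chain_background)
        assert tk.network_stats(L)["max_path_nodes"] == 1

    def test_matches_all_pairs_bfs(self):
        rng = np.random.default_rng(13)
        G = nx.DiGraph()
        nodes = [f"n{i}" for i in range(10)]
        G.add_nodes_from(nodes)
        for u in nodes:
            for v in nodes:
                if u < v and rng.random() < 0.3:
                    G.add_edge(u, v)   # DAG by name ordering
        L = tk.LocalNetwork(graph=G, members=set(nodes))
        best = 1
        for a in nodes:
            lengths = nx.single_source_shortest_path_length(G, a)
            for b, h in lengths.items():
                if a != b:
                    best = max(best, h + 1)
        assert tk.network_stats(L)["max_path_nodes"] == best

    def test_simple_path_scores_its_node_count(self):
        for n in (2, 4, 7):
            G = nx.path_graph(n, create_using=nx.DiGraph)
            L = tk.LocalNetwork(graph=G, members=set(G.nodes))
            assert tk.network_stats(L)["max_path_nodes"] == n


class TestExport:
    def _network(self, chain_background):
        L = tk.build_local_network({"A", "C"}, chain_background)
        m = tk.FunctionalityMatrix(pd.DataFrame(
            {2.5: [1, -1]}, index=["A", "C"]))
        return annotate_functionality(L, m)

    def test_sif_two_lines(self, chain_background, tmp_path):
        L = self._network(chain_background)
        p = tmp_path / "net.sif"
        tk.export_network(L, p, fmt="sif")
        lines = p.read_text().strip().splitlines()
        assert lines == ["A\tphosphorylates\tB", "B\tphosphorylates\tC"]

    def test_graphml_round_trip(self, chain_background, tmp_path):
        L = self._network(chain_background)
        p = tmp_path / "net.graphml"
        tk.export_network(L, p, fmt="graphml")
        back = tk.import_network(p, fmt="graphml")
        assert nx.is_isomorphic(
            L.graph, back,
            node_match=lambda a, b: a.get("role") == b.get("role"))
        assert back.nodes["B"]["role"] == "inferred"

    def test_csv_round_trip_with_sidecar(self, chain_background, tmp_path):
        L = self._network(chain_background)
        p = tmp_path / "net.csv"
        tk.export_network(L, p, fmt="csv")
        back = tk.import_network(p, fmt="csv")
        assert set(back.edges) == set(L.graph.edges)
        assert back.nodes["B"]["role"] == "inferred"

    def test_unknown_format(self, chain_background, tmp_path):
        with pytest.raises(ValueError, match="format"):
            tk.export_network(self._network(chain_background),
                              tmp_path / "x", fmt="gexf")


class TestOverlay:
    def _matrix(self, rows, index):
        return tk.FunctionalityMatrix(
            pd.DataFrame(rows, index=index, columns=[2.5, 7.5, 12.5]))

    def test_node_classes_from_phase(self, chain_background):
        m = self._matrix([[-1, -1, 0], [0, 1, 0], [-1, 0, 1]],
                         ["A", "B", "C"])
        H = tk.overlay_background(chain_background, {"c": m}, [], (0, 2))
        assert H.nodes["A"]["functionality"] == "weakening"
        assert H.nodes["B"]["functionality"] == "strengthening"
        assert H.nodes["C"]["functionality"] == "both"
        assert H.nodes["D"]["functionality"] == "unclassified"

    def test_edge_class_both_signs(self, chain_background):
        m = self._matrix([[-1, 0, 0], [0, 0, 0], [1, 0, 0]], ["A", "B", "C"])
        Lw = tk.build_local_network({"A", "B"}, chain_background)
        annotate_functionality(Lw, self._matrix([[-1, 0, 0]], ["A"]))
        Ls = tk.build_local_network({"A", "B"}, chain_background)
        annotate_functionality(Ls, self._matrix([[1, 0, 0]], ["A"]))
        H = tk.overlay_background(chain_background, {"c": m}, [Lw, Ls], (0, 2))
        assert H.edges[("A", "B")]["functionality"] == "both"

    def test_empty_phase_leaves_background_unclassified(self, chain_background):
        m = self._matrix([[0, 0, -1]], ["A"])
        H = tk.overlay_background(chain_background, {"c": m}, [], (0, 1))
        assert all(d["functionality"] == "unclassified"
                   for _, d in H.nodes(data=True))
        assert H.number_of_edges() == chain_background.graph.number_of_edges()

    def test_phase_outside_grid(self, chain_background):
        m = self._matrix([[0, 0, 0]], ["A"])
        with pytest.raises(ValueError, match="phase"):
            tk.overlay_background(chain_background, {"c": m}, [], (0, 9))


class TestSynonyms:
    def test_mapping_applied_before_search(self, tmp_path):
        from treking.netgen import apply_synonyms, read_synonym_table
        p = tmp_path / "syn.csv"
        p.write_text("panel_name,network_name\np38a,MAPK14\nMK2,MAPKAPK2\n")
        syn = read_synonym_table(p)
        assert apply_synonyms({"p38a", "MK2", "SRC"}, syn) == {
            "MAPK14", "MAPKAPK2", "SRC"}

    def test_bad_synonym_header(self, tmp_path):
        from treking.netgen import read_synonym_table
        p = tmp_path / "syn.csv"
        p.write_text("a,b\nx,y\n")
        with pytest.raises(ValueError, match="panel_name"):
            read_synonym_table(p)
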