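import numpy as np
import networkx as nx
import pandas as pd
import pytest

from oracle_utils import components_oracle
from ssnmine.align import align_local, alignment_score
from ssnmine.seqio import AMINO20, SeqRecord
from ssnmine.ssn import (
    EdgeTable,
    build_network,
    clade_cluster_table,
    compute_edges,
    export_graphml,
    export_node_edge_tsv,
    summarize_clusters,
)


def _random_records(rng, n, length=40):
    base = "".join(AMINO20[i] for i in rng.integers(0, 20, size=length))
    out = []
    for i in range(n):
        seq = list(base)
        for pos in rng.integers(0, length, size=rng.integers(0, length // 2)):
            seq[pos] = AMINO20[int(rng.integers(0, 20))]
        out.append(SeqRecord(f"r{i:02d}", "".join(seq)))
    return out


def _edge_table(n_nodes, edges_with_scores):
    rows = [
        {"id_a": f"n{a:02d}", "id_b": f"n{b:02d}", "alignment_score": s,
         "percent_identity": 50.0}
        for a, b, s in edges_with_scores
    ]
    frame = pd.DataFrame(rows, columns=["id_a", "id_b", "alignment_score", "percent_identity"])
    return EdgeTable(frame=frame, roster=[f"n{i:02d}" for i in range(n_nodes)])


class TestComputeEdges:
    def test_three_identical_sequences(self, scheme):
        recs = [SeqRecord(f"s{i}", "MWCYCRLMKVEDRH" * 3) for i in range(3)]
        table = compute_edges(recs, scheme)
        assert len(table.frame) == 3
        assert table.frame["alignment_score"].nunique() == 1
        assert (table.frame["percent_identity"] == 100.0).all()

    def test_single_record_empty_table_roster_one(self, scheme):
        table = compute_edges([SeqRecord("only", "MKVWEDRH" * 5)], scheme)
        assert len(table.frame) == 0
        assert table.roster == ["only"]

    def test_rows_match_pairwise_oracle_replay(self, scheme):
        rng = np.random.default_rng(2)
        recs = _random_records(rng, 6)
        table = compute_edges(recs, scheme)
        by_id = {r.id: r for r in recs}
        expected_rows = 0
        for i, a in enumerate(recs):
            for b in recs[i + 1:]:
                res = align_local(a, b, scheme)
                score = alignment_score(res)
                if score > 0:
                    expected_rows += 1
                    ia, ib = sorted([a.id, b.id])
                    row = table.frame[(table.frame.id_a == ia) & (table.frame.id_b == ib)]
                    assert len(row) == 1
                    assert row["alignment_score"].iloc[0] == pytest.approx(score)
        assert len(table.frame) == expected_rows

    def test_rows_sorted_lexicographically(self, scheme):
        rng = np.random.default_rng(3)
        table = compute_edges(_random_records(rng, 5), scheme)
        pairs = list(zip(table.frame.id_a, table.frame.id_b))
        assert pairs == sorted(pairs)


class TestEdgeTableInvariants:
    def test_self_pairs_rejected(self):
        with pytest.raises(ValueError, match="id_a < id_b"):
            _edge_table(2, [(0, 0, 5.0)])

    def test_duplicate_pairs_rejected(self):
        with pytest.raises(ValueError, match="duplicate"):
            _edge_table(3, [(0, 1, 5.0), (0, 1, 6.0)])

    def test_negative_scores_rejected(self):
        with pytest.raises(ValueError, match=">= 0"):
            _edge_table(3, [(0, 1, -1.0)])

    def test_edge_ids_must_be_in_roster(self):
        frame = pd.DataFrame(
            [{"id_a": "a", "id_b": "b", "alignment_score": 1.0, "percent_identity": 1.0}])
        with pytest.raises(ValueError, match="roster"):
            EdgeTable(frame=frame, roster=["a"])

    def test_tsv_round_trip(self, tmp_path, scheme):
        rng = np.random.default_rng(4)
        table = compute_edges(_random_records(rng, 5), scheme)
        p = tmp_path / "edges.tsv"
        table.to_tsv(p)
        back = EdgeTable.from_tsv(p, roster=table.roster)
        pd.testing.assert_frame_equal(
            back.frame.reset_index(drop=True), table.frame.reset_index(drop=True),
            check_exact=False, rtol=1e-5)


class TestBuildNetwork:
    def test_threshold_zero_keeps_all_positive_edges(self):
        table = _edge_table(4, [(0, 1, 1.0), (2, 3, 0.5)])
        net = build_network(table, 0.0)
        assert net.n_edges == 2

    def test_threshold_above_max_isolates_everything(self):
        table = _edge_table(4, [(0, 1, 10.0), (2, 3, 9.0)])
        net = build_network(table, 11.0)
        assert len(net.components) == 4
        assert len(net.singletons) == 4

    def test_components_match_transitive_closure_oracle(self):
        rng = np.random.default_rng(99)
        for _ in range(200):
            n = int(rng.integers(2, 13))
            density = rng.uniform(0, 0.5)
            edges = [
                (a, b, 1.0)
                for a in range(n) for b in range(a + 1, n)
                if rng.random() < density
            ]
            table = _edge_table(n, edges)
            net = build_network(table, 0.5)
            got = {frozenset(c) for c in net.components}
            want = {
                frozenset(f"n{i:02d}" for i in comp)
                for comp in components_oracle(n, [(a, b) for a, b, _ in edges])
            }
            assert got == want

    def test_partition_validity_and_threshold_monotonicity(self):
        rng = np.random.default_rng(10)
        edges = [
            (a, b, float(rng.uniform(0, 100)))
            for a in range(15) for b in range(a + 1, 15) if rng.random() < 0.3
        ]
        table = _edge_table(15, edges)
        prev = None
        for t in np.linspace(0, 110, 23):
            net = build_network(table, float(t))
            all_nodes = sorted(n for c in net.components for n in c)
            assert all_nodes == sorted(table.roster)  # exact partition
            for a, b in net.graph.edges:
                comp = next(c for c in net.components if a in c)
                assert b in comp
            if prev is not None:
                assert len(net.components) >= len(prev.components)
                assert len(net.singletons) >= len(prev.singletons)
                assert net.n_edges <= prev.n_edges
            prev = net

    def test_negative_threshold_rejected(self):
        with pytest.raises(ValueError):
            build_network(_edge_table(2, []), -1.0)


class TestSummaries:
    def _net(self):
        # components: {0,1,2,3,4,5,6} (sizes 4 and 3) and 3 singletons
        table = _edge_table(
            10,
            [(0, 1, 9.0), (1, 2, 9.0), (2, 3, 9.0), (4, 5, 9.0), (5, 6, 9.0)],
        )
        return build_network(table, 1.0)

    def _records(self, labels):
        return [
            SeqRecord(f"n{i:02d}", "MKVW", label=labels.get(i),
                      clade="angiosperms" if i % 2 == 0 else "bryophytes")
            for i in range(10)
        ]

    def test_purity_of_uniform_component(self):
        net = self._net()
        recs = self._records({0: "sterol", 1: "sterol"})
        summaries, _ = summarize_clusters(net, recs)
        top = summaries[0]
        assert top.size == 4
        assert top.purity == 1.0
        assert top.label_composition == {"sterol": 2}

    def test_purity_of_mixed_component(self):
        net = self._net()
        recs = self._records({0: "sterol", 1: "pentacyclic"})
        summaries, _ = summarize_clusters(net, recs)
        assert summaries[0].purity == 0.5

    def test_global_coverage_statistics(self):
        # 10 nodes; largest 2 components hold 7 nodes and 4 of 5 references
        net = self._net()
        recs = self._records({0: "a", 1: "a", 4: "b", 5: "b", 7: "c"})
        _, stats = summarize_clusters(net, recs, top_k=2)
        assert stats["frac_nodes_in_top_clusters"] == pytest.approx(0.7)
        assert stats["frac_references_in_top_clusters"] == pytest.approx(0.8)
        assert stats["n_singletons"] == 3

    def test_purity_absent_without_references(self):
        net = self._net()
        recs = self._records({})
        summaries, _ = summarize_clusters(net, recs)
        assert all(s.purity is None for s in summaries)

    def test_clade_cluster_table_counts_conserved(self):
        net = self._net()
        recs = self._records({0: "a"})
        table = clade_cluster_table(net, recs)
        assert table["count"].sum() == 10


class TestExports:
    def test_graphml_round_trip(self, tmp_path):
        net = TestSummaries()._net()
        recs = TestSummaries()._records({0: "sterol"})
        p = tmp_path / "net.graphml"
        export_graphml(net, recs, p)
        back = nx.read_graphml(p)
        assert set(back.nodes) == set(net.graph.nodes)
        assert back.number_of_edges() == net.n_edges
        assert back.nodes["n00"]["label"] == "sterol"

    def test_node_edge_tsv_export(self, tmp_path):
        net = TestSummaries()._net()
        recs = TestSummaries()._records({})
        export_node_edge_tsv(net, recs, tmp_path / "nodes.tsv", tmp_path / "edges.tsv")
        nodes = pd.read_csv(tmp_path / "nodes.tsv", sep="\t")
        edges = pd.read_csv(tmp_path / "edges.tsv", sep="\t")
        assert len(nodes) == 10
        assert len(edges) == net.n_edges
        assert nodes[nodes.degree == 0].shape[0] == 3
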