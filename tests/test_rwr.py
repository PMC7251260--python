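"""Random walk with restart: normalization, seeding, propagation, selection."""

import numpy as np
import networkx as nx
import pytest

from conftest import random_connected_graph
from walkhub import io, rwr
from walkhub.de import ValidationError


def _graph(edges):
    g = nx.Graph()
    g.add_edges_from(edges)
    return g


class TestLoadNetwork:
    def test_score_400_dropped(self, tmp_path):
        """combined_score exactly 400 fails the strict confidence > 0.400 filter."""
        path = tmp_path / "edges.tsv"
        path.write_text(
            "protein1\tprotein2\tcombined_score\nA\tB\t400\nB\tC\t401\nA\tC\t500\n"
        )
        net = rwr.load_network(path)
        assert set(net.edges) == {("B", "C"), ("A", "C")}

    def test_all_high_scores_kept(self, tmp_path):
        path = tmp_path / "edges.tsv"
        path.write_text(
            "protein1\tprotein2\tcombined_score\nA\tB\t999\nB\tC\t999\nC\tA\t999\n"
        )
        net = rwr.load_network(path)
        assert net.number_of_nodes() == 3 and net.number_of_edges() == 3

    def test_largest_component_retained(self, tmp_path):
        path = tmp_path / "edges.tsv"
        rows = ["A\tB\t900", "B\tC\t900", "C\tA\t900", "W\tX\t900", "X\tY\t900",
                "Y\tW\t900", "Y\tZ\t900"]
        path.write_text("protein1\tprotein2\tcombined_score\n" + "\n".join(rows) + "\n")
        net = rwr.load_network(path)
        assert set(net.nodes) == {"W", "X", "Y", "Z"}

    def test_malformed_row_reports_line_number(self, tmp_path):
        path = tmp_path / "edges.tsv"
        path.write_text("protein1\tprotein2\tcombined_score\nA\tB\t900\nA\tC\tbad\n")
        with pytest.raises(ValidationError, match=":3"):
            rwr.load_network(path)

    def test_empty_after_filter_raises(self, tmp_path):
        path = tmp_path / "edges.tsv"
        path.write_text("protein1\tprotein2\tcombined_score\nA\tB\t100\n")
        with pytest.raises(ValidationError):
            rwr.load_network(path)


class TestColumnNormalize:
    def test_path_graph_by_hand(self):
        """A-B-C: B's column splits 1/2, 1/2; A and C put all mass on B."""
        t = rwr.column_normalize(_graph([("A", "B"), ("B", "C")]))
        dense = t.matrix.toarray()
        i = t.index
        assert dense[i["A"], i["B"]] == pytest.approx(0.5)
        assert dense[i["C"], i["B"]] == pytest.approx(0.5)
        assert dense[i["B"], i["A"]] == pytest.approx(1.0)
        assert dense[i["B"], i["C"]] == pytest.approx(1.0)
        assert dense[i["A"], i["C"]] == 0.0

    def test_complete_graph_entries(self):
        t = rwr.column_normalize(nx.complete_graph(["A", "B", "C", "D"]))
        dense = t.matrix.toarray()
        off = dense[~np.eye(4, dtype=bool)]
        assert np.allclose(off, 1.0 / 3.0)

    def test_column_sums_one(self):
        rng = np.random.default_rng(0)
        for n in (10, 47, 120):
            g = random_connected_graph(rng, n)
            t = rwr.column_normalize(g)
            sums = np.asarray(t.matrix.sum(axis=0)).ravel()
            assert np.allclose(sums, 1.0, atol=1e-12)

    def test_sparsity_pattern_matches_adjacency(self):
        g = random_connected_graph(np.random.default_rng(3), 30)
        t = rwr.column_normalize(g)
        adj = nx.to_scipy_sparse_array(g, nodelist=t.nodes, weight=None)
        assert (t.matrix != 0).astype(int).toarray().tolist() == (
            adj != 0
        ).astype(int).toarray().tolist()


class TestSeedVector:
    def test_uniform_quarter_mass(self):
        t = rwr.column_normalize(nx.complete_graph([f"N{i}" for i in range(6)]))
        p0 = rwr.make_seed_vector({"N0", "N1", "N2", "N3"}, t)
        assert sorted(p0) == pytest.approx([0, 0, 0.25, 0.25, 0.25, 0.25])

    def test_single_seed_indicator(self):
        t = rwr.column_normalize(nx.complete_graph(["A", "B", "C"]))
        p0 = rwr.make_seed_vector({"B"}, t)
        assert p0[t.index["B"]] == 1.0 and p0.sum() == 1.0

    def test_absent_seeds_dropped_and_renormalized(self, caplog):
        t = rwr.column_normalize(nx.complete_graph(["A", "B", "C", "D"]))
        with caplog.at_level("WARNING"):
            p0 = rwr.make_seed_vector({"A", "B", "C", "X", "Y"}, t)
        assert np.isclose(p0.sum(), 1.0)
        assert sorted(p0)[-3:] == pytest.approx([1 / 3] * 3)
        assert "X" in caplog.text and "Y" in caplog.text

    def test_no_overlap_errors_with_seed_names(self):
        t = rwr.column_normalize(nx.complete_graph(["A", "B", "C"]))
        with pytest.raises(ValidationError, match="Q1"):
            rwr.make_seed_vector({"Q1", "Q2"}, t)


class TestPropagate:
    def test_restart_one_returns_seed_distribution(self):
        t = rwr.column_normalize(nx.complete_graph(["A", "B", "C"]))
        p0 = rwr.make_seed_vector({"A"}, t)
        res = rwr.propagate(t, p0, restart=1.0)
        assert np.array_equal(res.probabilities.to_numpy(), p0)
        assert res.converged

    def test_two_node_closed_form(self):
        """A-B with seed {A}, r=0.5: fixed point is (2/3, 1/3)."""
        t = rwr.column_normalize(_graph([("A", "B")]))
        p0 = rwr.make_seed_vector({"A"}, t)
        res = rwr.propagate(t, p0, restart=0.5, tolerance=1e-12)
        assert res.probabilities["A"] == pytest.approx(2 / 3, abs=1e-9)
        assert res.probabilities["B"] == pytest.approx(1 / 3, abs=1e-9)

    def test_star_leaves_symmetric(self):
        star = nx.star_graph(8)
        t = rwr.column_normalize(star)
        res = rwr.propagate(t, rwr.make_seed_vector({0}, t))
        leaves = res.probabilities.drop(index=0)
        assert np.ptp(leaves.to_numpy()) < 1e-12

    def test_probability_sums_conserved_each_iteration(self):
        g = random_connected_graph(np.random.default_rng(11), 60)
        t = rwr.column_normalize(g)
        res = rwr.propagate(t, rwr.make_seed_vector(set(list(g)[:5]), t))
        assert np.allclose(res.probability_sums, 1.0, atol=1e-9)

    def test_contraction_and_iteration_bound(self):
        """Successive L1 differences shrink geometrically with ratio <= 1-r."""
        g = random_connected_graph(np.random.default_rng(4), 80)
        t = rwr.column_normalize(g)
        for r in (0.3, 0.7):
            res = rwr.propagate(t, rwr.make_seed_vector({t.nodes[0]}, t), restart=r)
            deltas = np.array(res.differences)
            assert np.all(deltas[1:] <= deltas[:-1] * (1 - r) + 1e-15)
            bound = int(np.ceil(np.log(res.tolerance) / np.log(1 - r))) + 1
            assert res.iterations <= bound

    def test_limit_r_to_one(self):
        g = random_connected_graph(np.random.default_rng(9), 40)
        t = rwr.column_normalize(g)
        p0 = rwr.make_seed_vector({t.nodes[0], t.nodes[1]}, t)
        dists = []
        for r in (0.99, 0.999, 0.9999):
            res = rwr.propagate(t, p0, restart=r, tolerance=1e-12)
            dists.append(np.abs(res.probabilities.to_numpy() - p0).sum())
        assert dists[0] > dists[1] > dists[2]

    def test_nonconvergence_warns_not_silent(self):
        g = random_connected_graph(np.random.default_rng(2), 50)
        t = rwr.column_normalize(g)
        p0 = rwr.make_seed_vector({t.nodes[0]}, t)
        with pytest.warns(RuntimeWarning, match="did not converge"):
            res = rwr.propagate(t, p0, max_iterations=1, tolerance=1e-12)
        assert not res.converged

    def test_invalid_restart_rejected(self):
        t = rwr.column_normalize(_graph([("A", "B")]))
        p0 = rwr.make_seed_vector({"A"}, t)
        for bad in (0.0, 1.5, -0.1):
            with pytest.raises(ValidationError):
                rwr.propagate(t, p0, restart=bad)


class TestClosedFormOracle:
    def test_agrees_with_iteration_on_random_graphs(self):
        rng = np.random.default_rng(17)
        for _ in range(10):
            n = int(rng.integers(10, 60))
            g = random_connected_graph(rng, n)
            t = rwr.column_normalize(g)
            seeds = set(list(g)[: max(1, n // 10)])
            p0 = rwr.make_seed_vector(seeds, t)
            res = rwr.propagate(t, p0, tolerance=1e-5)
            exact = rwr.closed_form_oracle(t, p0, 0.7)
            assert np.abs(res.probabilities.to_numpy() - exact).sum() < 1e-4

    def test_r_one_returns_p0(self):
        t = rwr.column_normalize(_graph([("A", "B"), ("B", "C")]))
        p0 = rwr.make_seed_vector({"A"}, t)
        assert np.allclose(rwr.closed_form_oracle(t, p0, 1.0), p0)

    def test_solution_is_a_distribution(self):
        g = random_connected_graph(np.random.default_rng(23), 35)
        t = rwr.column_normalize(g)
        p0 = rwr.make_seed_vector({t.nodes[3]}, t)
        exact = rwr.closed_form_oracle(t, p0, 0.4)
        assert exact.sum() == pytest.approx(1.0, abs=1e-9)
        assert np.all(exact >= -1e-15)


class TestSelectCandidates:
    def _result(self):
        t = rwr.column_normalize(nx.complete_graph([f"N{i}" for i in range(8)]))
        seeds = {"N0", "N1"}
        return rwr.rwr_from_seeds(t, seeds), seeds

    def test_top_k_zero_returns_seeds(self):
        res, seeds = self._result()
        assert rwr.select_candidates(res, seeds, 0) == seeds

    def test_top_k_all_returns_network(self):
        res, seeds = self._result()
        assert rwr.select_candidates(res, seeds, 6) == {f"N{i}" for i in range(8)}

    def test_oversized_top_k_warns_and_caps(self, caplog):
        res, seeds = self._result()
        with caplog.at_level("WARNING"):
            out = rwr.select_candidates(res, seeds, 100)
        assert out == {f"N{i}" for i in range(8)}
        assert "top_k" in caplog.text

    def test_ties_break_lexicographically(self):
        # complete graph: all non-seeds tie, so selection is the lexicographic head
        res, seeds = self._result()
        assert rwr.select_candidates(res, seeds, 2) == seeds | {"N2", "N3"}

    def test_weighted_normalization_variant(self):
        g = _graph([("A", "B"), ("B", "C")])
        g["A"]["B"]["confidence"] = 0.9
        g["B"]["C"]["confidence"] = 0.5
        t = rwr.column_normalize(g, weighted=True)
        dense = t.matrix.toarray()
        assert dense[t.index["A"], t.index["B"]] == pytest.approx(0.9 / 1.4)
        sums = np.asarray(t.matrix.sum(axis=0)).ravel()
        assert np.allclose(sums, 1.0)


def test_ranking_table_round_trip(tmp_path):
    g = nx.complete_graph(["A", "B", "C", "D"])
    t = rwr.column_normalize(g)
    seeds = {"A"}
    res = rwr.rwr_from_seeds(t, seeds)
    table = rwr.ranking_table(res, seeds)
    assert list(table["rank"]) == [1, 2, 3, 4]
    assert table.iloc[0].name == "A" and bool(table.iloc[0]["is_seed"])
    io.write_gene_list(seeds, tmp_path / "seeds.txt")
    assert io.read_gene_list(tmp_path / "seeds.txt") == ["A"]
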