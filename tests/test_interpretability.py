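import itertools

import numpy as np
import pytest

from plkd.data_io import GeneSetCollection
from plkd.interpretability import (GeneGraph, attribute_cells,
                                   build_gene_graph, centrality_scores,
                                   consensus_genes, enrich_gene_set,
                                   extract_pattern_gene_set, q_aggregate,
                                   rank_patterns_by_type, shap_attribution,
                                   top_shap_genes)
from plkd.student_model import StudentParams


class TestPatternGeneSet:
    def test_mean_threshold_selection(self):
        W = np.array([[5.0], [1.0], [0.0]])  # row sums (5,1,0), mean 2
        ps = extract_pattern_gene_set(W, ["a", "b", "c"])
        assert ps.genes == ["a"]
        assert ps.threshold == 2.0

    def test_uniform_rows_empty_with_warning(self):
        W = np.ones((3, 2))
        with pytest.warns(UserWarning, match="empty"):
            ps = extract_pattern_gene_set(W, ["a", "b", "c"])
        assert ps.genes == []

    def test_masked_rows_never_selected(self):
        W = np.array([[0.0, 0.0], [3.0, 1.0], [2.0, 2.0]])  # row 0 masked
        ps = extract_pattern_gene_set(W, ["masked", "b", "c"])
        assert "masked" not in ps.genes


class TestEnrichment:
    def test_exact_hypergeometric_tail(self):
        universe = [f"g{i}" for i in range(10)]
        pw = set(universe[:5])
        c = GeneSetCollection(sets={"PW": pw, "OTHER": set(universe[5:])})
        rows = enrich_gene_set(pw, c, universe)
        assert rows[0]["pathway"] == "PW"
        np.testing.assert_allclose(rows[0]["p_value"], 1 / 252, rtol=1e-9)

    def test_zero_overlap_p_one(self):
        universe = ["a", "b", "c", "d"]
        c = GeneSetCollection(sets={"PW": {"c", "d"}})
        rows = enrich_gene_set({"a", "b"}, c, universe)
        assert rows[0]["p_value"] == pytest.approx(1.0)

    def test_p_values_valid_and_bh_attached(self):
        rng = np.random.default_rng(0)
        universe = [f"g{i}" for i in range(50)]
        c = GeneSetCollection(
            sets={f"PW{j}": set(rng.choice(universe, 8, replace=False))
                  for j in range(6)})
        rows = enrich_gene_set(set(universe[:10]), c, universe)
        for r in rows:
            assert 0 <= r["p_value"] <= 1
            assert 0 <= r["q_value"] <= 1

    def test_empty_query_rejected(self):
        c = GeneSetCollection(sets={"PW": {"a"}})
        with pytest.raises(ValueError, match="empty"):
            enrich_gene_set(set(), c, ["a"])


class TestRankPatterns:
    def test_planted_pattern_ranks_first(self):
        rng = np.random.default_rng(1)
        tokens = rng.normal(size=(60, 4, 3))
        labels = np.array(["A"] * 30 + ["B"] * 30)
        tokens[:30, 2, :] += 5.0  # pattern 2 active only in type A
        ranked = rank_patterns_by_type(tokens, labels)
        assert ranked["A"][0]["pattern"] == 2

    def test_returns_all_when_m_below_top(self):
        rng = np.random.default_rng(2)
        tokens = rng.normal(size=(20, 4, 3))
        labels = np.array(["A", "B"] * 10)
        ranked = rank_patterns_by_type(tokens, labels)
        assert len(ranked["A"]) == 4

    def test_deterministic(self):
        rng = np.random.default_rng(3)
        tokens = rng.normal(size=(30, 5, 2))
        labels = np.array(["A", "B", "C"] * 10)
        assert rank_patterns_by_type(tokens, labels) == \
            rank_patterns_by_type(tokens, labels)

    def test_tiny_type_skipped_with_warning(self):
        tokens = np.zeros((12, 3, 2))
        labels = np.array(["A"] * 10 + ["B"] * 2)
        with pytest.warns(UserWarning, match="fewer than 3"):
            ranked = rank_patterns_by_type(tokens, labels)
        assert "B" not in ranked


class TestGeneGraph:
    def test_top2_genes_per_pattern_max_20_nodes(self, small_trained):
        graph = build_gene_graph(small_trained["teacher"], list(range(8)))
        assert len(graph.genes) <= 16  # 8 patterns x 2 genes
        for i, j, _ in graph.edges:
            assert i != j

    def test_threshold_one_gives_edgeless_graph(self, small_trained):
        graph = build_gene_graph(small_trained["teacher"], list(range(8)),
                                 cosine_threshold=1.0)
        assert graph.edges == []

    def test_centralities_on_path_graph(self):
        g = GeneGraph(genes=["a", "b", "c"], embeddings=np.eye(3),
                      edges=[(0, 1, 1.0), (1, 2, 1.0)])
        s = centrality_scores(g)
        assert [s[v]["betweenness"] for v in "abc"] == [0.0, 1.0, 0.0]
        assert s["b"]["degree"] == 2

    def test_centralities_on_triangle(self):
        g = GeneGraph(genes=["a", "b", "c"], embeddings=np.eye(3),
                      edges=[(0, 1, 1.0), (1, 2, 1.0), (0, 2, 1.0)])
        s = centrality_scores(g)
        for v in "abc":
            assert s[v]["degree"] == 2
            np.testing.assert_allclose(s[v]["pagerank"], 1 / 3, atol=1e-6)

    def test_pagerank_sums_to_one(self, small_trained):
        graph = build_gene_graph(small_trained["teacher"], list(range(8)),
                                 cosine_threshold=0.0)
        s = centrality_scores(graph)
        np.testing.assert_allclose(sum(v["pagerank"] for v in s.values()), 1.0,
                                   atol=1e-9)


class TestQAggregate:
    def test_best_everywhere_gets_q_one(self):
        scores = {"win": {k: 10.0 for k in
                          ("degree", "betweenness", "eigenvector", "pagerank",
                           "closeness")},
                  "lose": {k: 1.0 for k in
                           ("degree", "betweenness", "eigenvector", "pagerank",
                            "closeness")}}
        ranked = q_aggregate(scores)
        assert ranked[0] == ("win", 1.0)

    def test_ties_share_average_rank(self):
        keys = ("degree", "betweenness", "eigenvector", "pagerank", "closeness")
        scores = {g: {k: 5.0 for k in keys} for g in ("a", "b")}
        ranked = q_aggregate(scores)
        assert ranked[0][1] == ranked[1][1] == 1.5

    def test_q_in_rank_bounds(self):
        rng = np.random.default_rng(4)
        keys = ("degree", "betweenness", "eigenvector", "pagerank", "closeness")
        scores = {f"g{i}": {k: float(rng.random()) for k in keys}
                  for i in range(7)}
        for _, q in q_aggregate(scores):
            assert 1.0 <= q <= 7.0


def exact_shapley_mean_imputation(forward, x, bg_mean, target):
    """Brute-force Shapley values: enumerate all coalitions, absent features
    imputed with the background mean."""
    n = x.size
    phi = np.zeros(n)
    feats = list(range(n))
    import math

    for j in feats:
        rest = [f for f in feats if f != j]
        for r in range(n):
            for S in itertools.combinations(rest, r):
                w = math.factorial(len(S)) * math.factorial(n - len(S) - 1) \
                    / math.factorial(n)
                z_with, z_without = bg_mean.copy(), bg_mean.copy()
                for f in S:
                    z_with[f] = x[f]
                    z_without[f] = x[f]
                z_with[j] = x[j]
                phi[j] += w * (forward(z_with)[target] - forward(z_without)[target])
    return phi


class TestShapAttribution:
    def test_linear_layer_closed_form(self):
        rng = np.random.default_rng(5)
        W = rng.normal(size=(4, 3))
        student = StudentParams(weights=[W], biases=[rng.normal(size=3)])
        bg = rng.normal(size=(10, 4))
        x = rng.normal(size=4)
        phi = shap_attribution(student, bg, x, target_class=1)
        np.testing.assert_allclose(phi, W[:, 1] * (x - bg.mean(0)), atol=1e-10)

    def test_completeness_on_linear_net(self):
        from plkd.student_model import student_forward

        rng = np.random.default_rng(6)
        student = StudentParams(weights=[rng.normal(size=(5, 2))],
                                biases=[rng.normal(size=2)])
        bg = rng.normal(size=(8, 5))
        x = rng.normal(size=5)
        phi = shap_attribution(student, bg, x, 0)
        delta = (student_forward(x, student)[0]
                 - student_forward(bg.mean(0), student)[0])
        np.testing.assert_allclose(phi.sum(), delta, atol=1e-6)

    @pytest.mark.parametrize("seed", [7, 17, 27])
    def test_rank_agreement_with_exact_shapley_on_relu_net(self, seed):
        from scipy.stats import spearmanr

        from plkd.student_model import init_student, student_forward

        rng = np.random.default_rng(seed)
        student = init_student(5, 3, hidden=(6,), seed=seed)
        bg = rng.normal(size=(20, 5))
        x = rng.normal(size=5) * 2
        phi = shap_attribution(student, bg, x, target_class=2)
        exact = exact_shapley_mean_imputation(
            lambda z: student_forward(z, student), x, bg.mean(0), 2)
        rho = spearmanr(phi, exact).statistic
        # with 5 features rho is granular; 0.9 = one adjacent swap
        assert rho >= 0.9 - 1e-9

    def test_dummy_gene_gets_zero(self):
        rng = np.random.default_rng(8)
        W1 = rng.normal(size=(4, 5))
        W1[2, :] = 0.0  # gene 2 disconnected
        W2 = rng.normal(size=(5, 3))
        student = StudentParams(weights=[W1, W2],
                                biases=[np.zeros(5), np.zeros(3)])
        phi = shap_attribution(student, rng.normal(size=(6, 4)),
                               rng.normal(size=4), 0)
        assert phi[2] == 0.0

    def test_linearity_over_summed_linear_heads(self):
        rng = np.random.default_rng(9)
        W1, W2 = rng.normal(size=(4, 2)), rng.normal(size=(4, 2))
        bg = rng.normal(size=(5, 4))
        x = rng.normal(size=4)
        phi1 = shap_attribution(StudentParams(weights=[W1], biases=[np.zeros(2)]),
                                bg, x, 0)
        phi2 = shap_attribution(StudentParams(weights=[W2], biases=[np.zeros(2)]),
                                bg, x, 0)
        phi_sum = shap_attribution(StudentParams(weights=[W1 + W2],
                                                 biases=[np.zeros(2)]), bg, x, 0)
        np.testing.assert_allclose(phi_sum, phi1 + phi2, atol=1e-10)


class TestTopGenesConsensus:
    def test_single_cell_ranking_is_own_abs_order(self):
        rng = np.random.default_rng(10)
        W = rng.normal(size=(6, 2))
        student = StudentParams(weights=[W], biases=[np.zeros(2)])
        bg = np.zeros((1, 6))
        x = rng.normal(size=6)
        attr = attribute_cells(student, bg, x[None], 0)
        top = top_shap_genes(attr, [f"g{i}" for i in range(6)])
        expected = np.argsort(-np.abs(W[:, 0] * x))
        assert [g for g, _ in top] == [f"g{i}" for i in expected]

    def test_dominant_planted_weight_ranks_first(self):
        W = np.full((5, 2), 0.01)
        W[3, 0] = 10.0
        student = StudentParams(weights=[W], biases=[np.zeros(2)])
        rng = np.random.default_rng(11)
        X = rng.normal(size=(20, 5)) + 1.0
        attr = attribute_cells(student, np.zeros((1, 5)), X, 0)
        top = top_shap_genes(attr, [f"g{i}" for i in range(5)])
        assert top[0][0] == "g3"

    def test_truncation_below_ten(self):
        student = StudentParams(weights=[np.ones((3, 2))], biases=[np.zeros(2)])
        attr = attribute_cells(student, np.zeros((1, 3)), np.ones((2, 3)), 0)
        assert len(top_shap_genes(attr, ["a", "b", "c"])) == 3

    def test_consensus_rules(self):
        student_top = [("a", 3.0), ("b", 2.0), ("c", 1.0)]
        assert consensus_genes({"b", "a"}, student_top) == [("a", 3.0), ("b", 2.0)]
        assert consensus_genes({"a", "b", "c", "z"}, student_top) == student_top
        with pytest.warns(UserWarning, match="intersect"):
            assert consensus_genes({"z"}, student_top) == []
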