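import numpy as np
import pytest

from plkd import objectives as ob


def finite_diff(f, X, eps=1e-6):
    g = np.zeros_like(X)
    it = np.nditer(X, flags=["multi_index"])
    for _ in it:
        i = it.multi_index
        Xp, Xm = X.copy(), X.copy()
        Xp[i] += eps
        Xm[i] -= eps
        g[i] = (f(Xp) - f(Xm)) / (2 * eps)
    return g


class TestSimilarityMatrix:
    def test_identical_embeddings_all_ones(self):
        S = ob.similarity_matrix(np.ones((4, 3)))
        np.testing.assert_allclose(S, 1.0)

    def test_unit_distance_hand_value(self):
        S = ob.similarity_matrix(np.array([[0.0], [1.0]]))
        np.testing.assert_allclose(S[0, 1], np.exp(-1.0), atol=1e-12)

    def test_symmetric_unit_diagonal(self):
        C = np.random.default_rng(0).normal(size=(6, 4))
        S = ob.similarity_matrix(C)
        np.testing.assert_array_equal(S, S.T)
        np.testing.assert_allclose(np.diag(S), 1.0)
        assert np.all(S > 0) and np.all(S <= 1)

    def test_euclidean_mode_softer_than_squared(self):
        C = np.array([[0.0], [2.0]])
        assert (ob.similarity_matrix(C, squared=False)[0, 1]
                > ob.similarity_matrix(C, squared=True)[0, 1])


class TestClusteringDivergence:
    def test_orthogonal_hard_assignments_zero(self):
        Y = np.array([[1.0, 0.0], [0.0, 1.0]])
        assert ob.clustering_divergence_loss(Y, np.eye(2)) == 0.0

    @pytest.mark.parametrize("k", [2, 3, 5])
    def test_identical_assignments_closed_form(self, k):
        rng = np.random.default_rng(k)
        Y = np.tile(rng.random((6, 1)) + 0.1, (1, k))
        S = ob.similarity_matrix(rng.normal(size=(6, 3)))
        # every pairwise cosine = 1 -> loss = (k-1)/2
        np.testing.assert_allclose(
            ob.clustering_divergence_loss(Y, S), (k - 1) / 2, atol=1e-9)

    def test_relabeling_invariance(self):
        rng = np.random.default_rng(1)
        Y = rng.random((5, 4))
        S = ob.similarity_matrix(rng.normal(size=(5, 3)))
        perm = rng.permutation(4)
        np.testing.assert_allclose(ob.clustering_divergence_loss(Y, S),
                                   ob.clustering_divergence_loss(Y[:, perm], S))

    def test_separated_clusters_score_lower_than_merged(self):
        # two tight, far-apart embedding clusters
        emb = np.vstack([np.zeros((5, 2)), 10.0 + np.zeros((5, 2))])
        S = ob.similarity_matrix(emb)
        distinct = np.vstack([np.tile([1.0, 0.0], (5, 1)),
                              np.tile([0.0, 1.0], (5, 1))])
        merged = np.tile([1.0, 0.0], (10, 1)) + 1e-3
        assert (ob.clustering_divergence_loss(distinct, S)
                < ob.clustering_divergence_loss(merged, S))

    def test_raw_denominator_flag(self):
        rng = np.random.default_rng(2)
        Y = rng.random((4, 2)) + 0.5
        S = np.eye(4)
        sqrt_form = ob.clustering_divergence_loss(Y, S)
        raw_form = ob.clustering_divergence_loss(Y, S, raw_denominator=True)
        C = Y.T @ S @ Y
        np.testing.assert_allclose(raw_form, C[0, 1] / (C[0, 0] * C[1, 1]) / 2)
        assert not np.isclose(sqrt_form, raw_form)

    def test_zero_class_guard_warns(self):
        Y = np.array([[1.0, 0.0], [1.0, 0.0]])
        with pytest.warns(UserWarning, match="epsilon"):
            out = ob.clustering_divergence_loss(Y, np.eye(2))
        assert np.isfinite(out)


class TestCrossEntropy:
    def test_uniform_two_class_is_ln2(self):
        val = ob.cross_entropy_loss(np.zeros((1, 2)), np.array([[1.0, 0.0]]))
        np.testing.assert_allclose(val, np.log(2), atol=1e-9)

    def test_confident_correct_tends_to_zero(self):
        onehot = np.array([[1.0, 0.0]])
        v10 = ob.cross_entropy_loss(np.array([[10.0, 0.0]]), onehot)
        v30 = ob.cross_entropy_loss(np.array([[30.0, 0.0]]), onehot)
        assert v30 < v10 < 1e-4

    def test_nonnegative_on_random_inputs(self):
        rng = np.random.default_rng(3)
        for _ in range(20):
            logits = rng.normal(size=(8, 4)) * 5
            onehot = np.eye(4)[rng.integers(0, 4, 8)]
            assert ob.cross_entropy_loss(logits, onehot) >= 0


class TestDistillation:
    def test_matched_logits_zero(self):
        logits = np.random.default_rng(4).normal(size=(6, 3))
        assert ob.distillation_loss(logits, logits.copy()) == pytest.approx(0, abs=1e-12)

    def test_hand_value_t1(self):
        p = ob._softmax(np.array([[1.0, 0.0]]))[0]
        q = p[::-1]
        expected = float((p * np.log(p / q)).sum())
        got = ob.distillation_loss(np.array([[0.0, 1.0]]),
                                   np.array([[1.0, 0.0]]), T=1.0)
        np.testing.assert_allclose(got, expected, atol=1e-9)
        np.testing.assert_allclose(got, 0.462, atol=5e-4)

    def test_high_temperature_flattens_to_zero(self):
        rng = np.random.default_rng(5)
        s, t = rng.normal(size=(4, 3)), rng.normal(size=(4, 3))
        vals = [ob.distillation_loss(s, t, T=T) for T in (1, 10, 100, 1000)]
        assert vals[-1] < 1e-5
        assert all(a >= b for a, b in zip(vals, vals[1:]))

    def test_invalid_temperature(self):
        with pytest.raises(ValueError, match="positive"):
            ob.distillation_loss(np.zeros((1, 2)), np.zeros((1, 2)), T=0)


class TestSelfEntropy:
    def test_zero_mean_logits_zero_loss(self):
        assert ob.self_entropy_loss(np.zeros((5, 3))) == 0.0

    def test_hand_value(self):
        np.testing.assert_allclose(
            ob.self_entropy_loss(np.array([[1.0, 0.0]])), 0.15663, atol=1e-5)

    def test_cell_order_invariance(self):
        rng = np.random.default_rng(6)
        X = rng.normal(size=(7, 4))
        perm = rng.permutation(7)
        for mode in ("literal", "shannon"):
            np.testing.assert_allclose(ob.self_entropy_loss(X, mode),
                                       ob.self_entropy_loss(X[perm], mode))

    def test_shannon_mode_bounded(self):
        X = np.array([[-100.0, 0.0, 0.0]])
        assert 0 <= ob.self_entropy_loss(X, "shannon") <= np.log(3) + 1e-9


class TestGradients:
    """Analytic gradients vs central finite differences (5 cells, 3 classes)."""

    def setup_method(self):
        self.rng = np.random.default_rng(42)
        self.Y = self.rng.random((5, 3)) + 0.1
        self.logits = self.rng.normal(size=(5, 3))
        self.emb = self.rng.normal(size=(5, 4))

    def test_l1_grads(self):
        S = ob.similarity_matrix(self.emb)
        _, dY, dS = ob.clustering_divergence_loss(self.Y, S, return_grads=True)
        np.testing.assert_allclose(
            dY, finite_diff(lambda Y: ob.clustering_divergence_loss(Y, S), self.Y),
            rtol=1e-4, atol=1e-8)
        dE = ob.similarity_backward(self.emb, S, dS)
        np.testing.assert_allclose(
            dE, finite_diff(lambda E: ob.clustering_divergence_loss(
                self.Y, ob.similarity_matrix(E)), self.emb),
            rtol=1e-4, atol=1e-8)

    def test_l2_grad(self):
        onehot = np.eye(3)[self.rng.integers(0, 3, 5)]
        _, d = ob.cross_entropy_loss(self.logits, onehot, return_grads=True)
        np.testing.assert_allclose(
            d, finite_diff(lambda L: ob.cross_entropy_loss(L, onehot), self.logits),
            rtol=1e-4, atol=1e-8)

    def test_l3_grad(self):
        t = self.rng.normal(size=(5, 3))
        _, d = ob.distillation_loss(self.logits, t, T=3.0, return_grads=True)
        np.testing.assert_allclose(
            d, finite_diff(lambda L: ob.distillation_loss(L, t, T=3.0), self.logits),
            rtol=1e-4, atol=1e-8)

    @pytest.mark.parametrize("mode", ["literal", "shannon"])
    def test_l4_grad(self, mode):
        _, d = ob.self_entropy_loss(self.logits, mode, return_grads=True)
        np.testing.assert_allclose(
            d, finite_diff(lambda L: ob.self_entropy_loss(L, mode), self.logits),
            rtol=1e-4, atol=1e-8)
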