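"""Objective evaluation, multiplicative updates and the fit loop."""

import numpy as np
import pytest

from scmnmf.dataset import MultiOmicsDataset
from scmnmf.model import (
    FactorModel,
    Hyperparameters,
    ScMNMF,
    assign_clusters,
    evaluate_objective,
    initialize_factors,
    objective_terms,
    update_b,
    update_f,
    update_h,
    update_w,
)
from scmnmf.simulate import SyntheticSpec, simulate

from conftest import random_graph, random_instance


def scalar_loop_objective(model, blocks, graph, hp):
    """Direct elementwise summation of every objective term."""
    lam = hp.lambda_per_block(len(blocks))
    total = 0.0
    for X, H, lk in zip(blocks, model.H, lam):
        R = X - model.W @ H
        total += sum(R[i, j] ** 2 for i in range(R.shape[0]) for j in range(R.shape[1]))
        total += lk * sum(abs(h) for h in H.ravel())
    total += hp.mu * sum(abs(w) for w in model.W.ravel())
    C = model.W - model.B @ model.F
    total += hp.coupling * sum(c ** 2 for c in C.ravel())
    if graph is not None and hp.alpha:
        A = graph.A.toarray()
        n = A.shape[0]
        total += hp.alpha * 0.5 * sum(
            A[i, j] * np.sum((model.B[i] - model.B[j]) ** 2)
            for i in range(n)
            for j in range(n)
        )
    return total


class TestObjective:
    def test_exact_factorization_scores_zero(self, rng):
        W = rng.random((6, 3))
        H = [rng.random((3, 4))]
        B = rng.random((6, 2))
        F = rng.random((2, 3))
        model = FactorModel(W=B @ F, H=H, B=B, F=F)
        blocks = [model.W @ H[0]]
        hp = Hyperparameters(k1=2, p=3, lambda_h=0.0, mu=0.0, alpha=0.0)
        assert evaluate_objective(model, blocks, None, hp) == pytest.approx(0.0, abs=1e-20)

    def test_matches_scalar_loop_on_toy_instance(self, rng):
        # 3 cells, 2 blocks, all-ones factors plus a graph term
        model = FactorModel(
            W=np.ones((3, 2)), H=[np.ones((2, 4)), np.ones((2, 2))],
            B=np.ones((3, 2)) * np.array([[1.0], [2.0], [0.5]]), F=np.ones((2, 2)),
        )
        blocks = [rng.random((3, 4)), rng.random((3, 2))]
        g = random_graph(rng, 3)
        hp = Hyperparameters(k1=2, p=2, lambda_h=[0.3, 0.7], mu=0.2, alpha=1.5)
        assert evaluate_objective(model, blocks, g, hp) == pytest.approx(
            scalar_loop_objective(model, blocks, g, hp), rel=1e-12
        )

    def test_linear_in_alpha(self, rng):
        data, hp, model = random_instance(3)
        g = random_graph(rng, data.n_cells)
        o1 = evaluate_objective(model, data.blocks, g, hp)
        hp2 = Hyperparameters(**{**hp.to_dict(), "alpha": hp.alpha + 2.0})
        o2 = evaluate_objective(model, data.blocks, g, hp2)
        from scmnmf.graph import graph_penalty

        assert o2 - o1 == pytest.approx(2.0 * graph_penalty(model.B, g), rel=1e-9)

    def test_r_q_decomposition(self, rng):
        data, hp, model = random_instance(4)
        g = random_graph(rng, data.n_cells)
        t = objective_terms(model, data.blocks, g, hp)
        assert t["R"] == pytest.approx(t["reconstruction"] + t["l1_H"] + t["l1_W"])
        assert t["Q"] == pytest.approx(t["coupling"] + t["graph"])
        assert evaluate_objective(model, data.blocks, g, hp) == pytest.approx(t["R"] + t["Q"])

    def test_shape_mismatch_rejected(self, rng):
        data, hp, model = random_instance(5)
        bad = model.copy()
        bad.W = bad.W[:-1]
        with pytest.raises(ValueError):
            evaluate_objective(bad, data.blocks, None, hp)

    def test_negative_factor_rejected(self, rng):
        data, hp, model = random_instance(6)
        bad = model.copy()
        bad.B[0, 0] = -0.1
        with pytest.raises(ValueError, match="negative"):
            evaluate_objective(bad, data.blocks, None, hp)


class TestUpdates:
    def test_w_unchanged_at_stationary_point(self):
        # construct num == den entrywise: X = W H, W = B F, mu = 0
        rng = np.random.default_rng(0)
        B = rng.random((8, 2)) + 0.1
        F = rng.random((2, 4)) + 0.1
        W = B @ F
        H = [rng.random((4, 6)) + 0.1]
        blocks = [W @ H[0]]
        hp = Hyperparameters(k1=2, p=4, lambda_h=0.0, mu=0.0, alpha=0.0)
        model = FactorModel(W=W, H=H, B=B, F=F)
        out = update_w(model, blocks, hp)
        np.testing.assert_allclose(out.W, W, rtol=1e-12)

    def test_h_fixed_point_with_orthonormal_w(self):
        rng = np.random.default_rng(1)
        # orthonormal non-negative basis: disjoint supports
        W = np.zeros((9, 3))
        W[0:3, 0], W[3:6, 1], W[6:9, 2] = 1 / np.sqrt(3), 1 / np.sqrt(3), 1 / np.sqrt(3)
        X = rng.random((9, 5))
        H = [W.T @ X]
        hp = Hyperparameters(k1=2, p=3, lambda_h=0.0, mu=0.0, alpha=0.0)
        model = FactorModel(W=W, H=H, B=np.ones((9, 2)), F=np.ones((2, 3)))
        out = update_h(model, [X], hp, 0)
        np.testing.assert_allclose(out.H[0], H[0], rtol=1e-12)

    def test_f_unchanged_at_zero_residual(self):
        rng = np.random.default_rng(2)
        B = rng.random((7, 2)) + 0.1
        F = rng.random((2, 4)) + 0.1
        model = FactorModel(W=B @ F, H=[np.ones((4, 3))], B=B, F=F)
        hp = Hyperparameters(k1=2, p=4)
        out = update_f(model, hp)
        np.testing.assert_allclose(out.F, F, rtol=1e-12)

    def test_f_row_for_zero_b_column_is_unchanged(self):
        rng = np.random.default_rng(3)
        B = rng.random((6, 3))
        B[:, 1] = 0.0
        F = rng.random((3, 4))
        model = FactorModel(W=rng.random((6, 4)), H=[np.ones((4, 2))], B=B, F=F)
        out = update_f(model, Hyperparameters(k1=3, p=4))
        np.testing.assert_allclose(out.F[1], F[1], rtol=1e-12)

    @pytest.mark.parametrize("seed", range(5))
    def test_each_update_monotone_in_its_subobjective(self, seed):
        rng = np.random.default_rng(seed)
        data, hp, model = random_instance(seed)
        g = random_graph(rng, data.n_cells)
        before = evaluate_objective(model, data.blocks, g, hp)
        after_w = evaluate_objective(update_w(model, data.blocks, hp), data.blocks, g, hp)
        assert after_w <= before * (1 + 1e-10)
        m = update_w(model, data.blocks, hp)
        for k in range(len(data.blocks)):
            before_h = evaluate_objective(m, data.blocks, g, hp)
            m = update_h(m, data.blocks, hp, k)
            assert evaluate_objective(m, data.blocks, g, hp) <= before_h * (1 + 1e-10)
        before_b = evaluate_objective(m, data.blocks, g, hp)
        m = update_b(m, g, hp)
        assert evaluate_objective(m, data.blocks, g, hp) <= before_b * (1 + 1e-10)
        before_f = evaluate_objective(m, data.blocks, g, hp)
        m = update_f(m, hp)
        assert evaluate_objective(m, data.blocks, g, hp) <= before_f * (1 + 1e-10)

    def test_nonnegativity_preserved(self, rng):
        data, hp, model = random_instance(11)
        g = random_graph(rng, data.n_cells)
        m = update_w(model, data.blocks, hp)
        m = update_h(m, data.blocks, hp, 0)
        m = update_b(m, g, hp)
        m = update_f(m, hp)
        for arr in [m.W, m.B, m.F, *m.H]:
            assert arr.min() >= 0

    def test_large_mu_shrinks_w_monotonically(self):
        data, _, model = random_instance(13)
        prev = None
        for mu in [0.0, 1.0, 100.0, 1e4]:
            hp = Hyperparameters(k1=3, p=5, mu=mu)
            out = update_w(model, data.blocks, hp)
            if prev is not None:
                assert np.all(out.W <= prev + 1e-12)
            prev = out.W

    def test_large_lambda_drives_h_toward_zero(self):
        data, _, model = random_instance(14)
        hp = Hyperparameters(k1=3, p=5, lambda_h=1e6)
        out = model
        for _ in range(20):
            out = update_h(out, data.blocks, hp, 0)
        assert out.H[0].max() < 1e-3 * model.H[0].max()

    def test_b_update_without_graph_matches_plain_rule(self):
        data, _, model = random_instance(15)
        hp = Hyperparameters(k1=3, p=5, alpha=0.0)
        out = update_b(model, None, hp)
        num = model.W @ model.F.T
        den = model.B @ (model.F @ model.F.T)
        expected = model.B * ((num + hp.eps) / (den + hp.eps))
        np.testing.assert_allclose(out.B, expected, rtol=1e-12)

    def test_huge_alpha_on_complete_graph_collapses_b_rows(self, rng):
        import scipy.sparse as sp

        from scmnmf.graph import AffinityGraph

        data, _, model = random_instance(16, n=12)
        A = np.ones((12, 12)) - np.eye(12)
        g = AffinityGraph(A=sp.csr_matrix(A), n_neighbors=11, sigma=1.0)
        hp = Hyperparameters(k1=3, p=5, alpha=1e6)
        m = model
        var0 = model.B.var(axis=0).sum()
        for _ in range(200):
            m = update_b(m, g, hp)
        assert m.B.var(axis=0).sum() < 1e-6 * var0

    def test_invalid_block_index(self):
        data, hp, model = random_instance(17)
        with pytest.raises(IndexError):
            update_h(model, data.blocks, hp, 5)


class TestInitialize:
    def test_seeded_determinism_and_positivity(self, rng):
        data, hp, _ = random_instance(21)
        a = initialize_factors(data.blocks, hp, 5, seed=42)
        b = initialize_factors(data.blocks, hp, 5, seed=42)
        for x, y in [(a.W, b.W), (a.B, b.B), (a.F, b.F), (a.H[0], b.H[0])]:
            np.testing.assert_array_equal(x, y)
            assert x.min() > 0

    def test_reconstruction_scale_near_data_scale(self, rng):
        blocks = [rng.random((30, 20)) * 50, rng.random((30, 10)) * 0.1]
        hp = Hyperparameters(k1=3, p=6)
        m = initialize_factors(blocks, hp, 6, seed=0)
        for X, H in zip(blocks, m.H):
            ratio = (m.W @ H).mean() / X.mean()
            assert 0.1 < ratio < 10


class TestAssignClusters:
    def test_one_hot_rows(self):
        B = np.eye(3)[[0, 1, 2, 1, 0]]
        labels, method = assign_clusters(B)
        np.testing.assert_array_equal(labels, [1, 2, 3, 2, 1])
        assert method == "argmax"

    def test_all_zero_row_gets_label_one(self):
        B = np.array([[0.0, 0.0], [0.0, 1.0]])
        labels, _ = assign_clusters(B)
        assert labels[0] == 1

    def test_matches_row_argmax_when_no_empty_cluster(self, rng):
        B = rng.random((30, 4))
        labels, method = assign_clusters(B)
        expected = [int(np.argmax(row / row.sum())) + 1 for row in B]
        np.testing.assert_array_equal(labels, expected)
        assert method == "argmax"

    def test_empty_cluster_falls_back_to_kmeans(self, rng):
        B = np.abs(rng.random((20, 3)))
        B[:, 2] += 10.0  # argmax would put everything in cluster 3
        labels, method = assign_clusters(B, n_clusters=3, seed=0)
        assert method == "kmeans"
        assert set(np.unique(labels)) <= {1, 2, 3}

    def test_negative_b_rejected(self):
        with pytest.raises(ValueError):
            assign_clusters(np.array([[1.0, -0.5]]))


class TestFit:
    def test_trace_monotone_and_deterministic(self):
        spec = SyntheticSpec(n_cells=80, k_types=3, block_features=[60, 40], seed=5)
        data = simulate(spec)
        model = ScMNMF(data, n_clusters=3, p=10, max_iter=40, tol=1e-8)
        r1 = model.fit(seed=5)
        r2 = ScMNMF(data, n_clusters=3, p=10, max_iter=40, tol=1e-8).fit(seed=5)
        np.testing.assert_array_equal(r1.labels, r2.labels)
        np.testing.assert_array_equal(r1.objective_trace, r2.objective_trace)
        tr = r1.objective_trace
        assert np.all(tr[1:] <= tr[:-1] * (1 + 1e-8))
        assert set(np.unique(r1.labels)) <= set(range(1, 4))

    def test_recovers_planted_clusters(self):
        aris = []
        for seed in range(3):
            spec = SyntheticSpec(n_cells=300, k_types=3, block_features=[500, 800], seed=seed)
            res = ScMNMF(simulate(spec), n_clusters=3, p=20, max_iter=150, tol=1e-5).fit(seed=seed)
            aris.append(res.score().ari)
        assert np.median(aris) >= 0.9

    def test_reduces_to_classical_nmf_without_penalties(self):
        from sklearn.decomposition import NMF

        rng = np.random.default_rng(30)
        X = rng.random((40, 25))
        hp = Hyperparameters(k1=2, p=6, lambda_h=0.0, mu=0.0, alpha=0.0, coupling=0.0)
        model = initialize_factors([X], hp, 6, seed=7)
        W0, H0 = model.W.copy(), model.H[0].copy()
        m = model
        for _ in range(200):
            m = update_w(m, [X], hp)
            m = update_h(m, [X], hp, 0)
        err_ours = np.linalg.norm(X - m.W @ m.H[0])

        ref = NMF(
            n_components=6, init="custom", solver="mu", beta_loss="frobenius",
            max_iter=200, tol=0.0,
        )
        with np.errstate(all="ignore"):
            Wr = ref.fit_transform(X, W=W0.copy(), H=H0.copy())
        err_ref = np.linalg.norm(X - Wr @ ref.components_)
        assert err_ours == pytest.approx(err_ref, rel=0.05)

    def test_summary_and_embedding(self):
        spec = SyntheticSpec(n_cells=60, k_types=2, block_features=[40, 30], seed=9)
        res = ScMNMF(simulate(spec), n_clusters=2, p=6, max_iter=20, tol=1e-8).fit(seed=9)
        text = res.summary()
        assert "clusters k1:        2" in text
        assert res.embedding.shape == (60, 2)
        assert sum(res.cluster_sizes().values()) == 60

    def test_invalid_hyperparameters(self):
        with pytest.raises(ValueError):
            Hyperparameters(k1=1)
        with pytest.raises(ValueError):
            Hyperparameters(k1=3, p=2)
        with pytest.raises(ValueError):
            Hyperparameters(k1=2, p=5, mu=-0.1)

    def test_from_dataframes(self, rng):
        import pandas as pd

        cells = [f"c{i}" for i in range(25)]
        frames = {
            "rna": pd.DataFrame(rng.random((25, 12)), index=cells),
            "adt": pd.DataFrame(rng.random((25, 6)), index=cells),
        }
        model = ScMNMF.from_dataframes(frames, n_clusters=2, p=4, max_iter=10)
        res = model.fit(seed=0)
        assert res.dataset.block_names == ["rna", "adt"]
        assert len(res.labels) == 25
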