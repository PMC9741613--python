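"""Joint autoencoder / VGAE / classifier model."""

import numpy as np
import pytest
import scipy.sparse as sp

from spatype import (
    GcnConfig,
    JointModel,
    annotate,
    autoencoder_forward,
    build_spatial_graph,
    reconstruct_adjacency,
    total_loss,
    train_stage2,
    vgae_encode,
)
from spatype.transfer import ProbabilityTable


def _graph(n, seed=0, **kw):
    rng = np.random.default_rng(seed)
    return build_spatial_graph(rng.uniform(0, 100, (n, 2)), n_neighbors=5, **kw)


def _pseudo(n, k, seed=0):
    rng = np.random.default_rng(seed)
    probs = rng.dirichlet(np.ones(k), size=n)
    return ProbabilityTable(cells=[f"c{i}" for i in range(n)],
                            types=[f"t{j}" for j in range(k)],
                            probs=probs, logits=np.log(probs))


def _dataset(n, g, seed=0):
    from spatype.datasets import ExpressionDataset

    rng = np.random.default_rng(seed)
    X = rng.random((n, g))
    X /= np.linalg.norm(X, axis=1, keepdims=True)
    return ExpressionDataset(
        cells=[f"c{i}" for i in range(n)], genes=[f"g{j}" for j in range(g)],
        counts=X, coords=rng.uniform(0, 100, (n, 2)), state="normalized")


class TestAutoencoderForward:
    def test_eval_mode_deterministic(self):
        model = JointModel(20, 3, GcnConfig(ae_hidden=(16, 8), seed=0))
        I = np.random.default_rng(1).random((10, 20))
        a = autoencoder_forward(I, model)
        b = autoencoder_forward(I, model)
        np.testing.assert_array_equal(a[0], b[0])
        np.testing.assert_array_equal(a[1], b[1])

    def test_latent_shape_independent_of_gene_count(self):
        for g in (15, 40):
            model = JointModel(g, 3, GcnConfig(ae_hidden=(16, 8), seed=0))
            X, I_prime = autoencoder_forward(np.zeros((7, g)), model)
            assert X.shape == (7, 8)
            assert I_prime.shape == (7, g)

    def test_reconstruction_after_training(self):
        # 50-cell fixture with low-rank structure trained ae-only:
        # MSE < 0.1 * variance of I
        from spatype.datasets import ExpressionDataset

        rng = np.random.default_rng(2)
        latent = rng.normal(size=(50, 4))
        basis = rng.normal(size=(4, 20))
        X = latent @ basis + 0.05 * rng.normal(size=(50, 20))
        ds = ExpressionDataset(
            cells=[f"c{i}" for i in range(50)], genes=[f"g{j}" for j in range(20)],
            counts=X, coords=rng.uniform(0, 100, (50, 2)), state="normalized")
        graph = build_spatial_graph(ds.coords, n_neighbors=5)
        pl = _pseudo(50, 3, seed=2)
        cfg = GcnConfig(ae_hidden=(32, 8), spatial=False,
                        weights=(1.0, 0.0, 0.0, 0.0), epochs=400, lr=3e-3, seed=2)
        model = train_stage2(ds, graph, pl, cfg)
        X, I_prime = autoencoder_forward(ds.counts, model)
        mse = np.mean((ds.counts - I_prime) ** 2)
        assert mse < 0.1 * ds.counts.var()

    def test_dimension_mismatch(self):
        from spatype.datasets import ValidationError

        model = JointModel(20, 3, GcnConfig(ae_hidden=(16, 8)))
        with pytest.raises(ValidationError, match="features"):
            autoencoder_forward(np.zeros((5, 21)), model)


class TestVgaeEncode:
    def test_zero_noise_gives_mean_embedding(self):
        model = JointModel(12, 3, GcnConfig(ae_hidden=(8, 4), seed=1))
        graph = _graph(30, seed=1)
        X = np.random.default_rng(2).normal(size=(30, 4))
        state = vgae_encode(X, graph, model, tau=np.zeros((30, 4)))
        np.testing.assert_array_equal(state.S, state.mu)
        np.testing.assert_array_equal(state.Z, state.X + state.S)

    def test_unit_variance_when_log_var_zero(self):
        # zero the log-variance head: S - mu = tau exactly, so the sample
        # variance per dimension over 10^4 cells is within 5% of 1
        model = JointModel(6, 2, GcnConfig(ae_hidden=(6, 4), seed=3))
        model.gc_lv.W[...] = 0.0
        model.gc_lv.b[...] = 0.0
        n = 10_000
        graph = _graph(n, seed=3)
        X = np.random.default_rng(4).normal(size=(n, 4))
        state = vgae_encode(X, graph, model, rng=np.random.default_rng(5))
        np.testing.assert_array_equal(state.log_var, 0.0)
        resid = state.S - state.mu
        np.testing.assert_allclose(resid.var(axis=0), 1.0, rtol=0.05)

    def test_seeded_noise_reproducible(self):
        model = JointModel(6, 2, GcnConfig(ae_hidden=(6, 4), seed=3))
        graph = _graph(25, seed=6)
        X = np.random.default_rng(7).normal(size=(25, 4))
        a = vgae_encode(X, graph, model, rng=np.random.default_rng(8))
        b = vgae_encode(X, graph, model, rng=np.random.default_rng(8))
        np.testing.assert_array_equal(a.S, b.S)

    def test_graph_size_mismatch(self):
        from spatype.datasets import ValidationError

        model = JointModel(6, 2, GcnConfig(ae_hidden=(6, 4)))
        with pytest.raises(ValidationError, match="cells"):
            vgae_encode(np.zeros((10, 4)), _graph(11), model)


class TestReconstructAdjacency:
    def test_zero_latent_gives_half_everywhere(self):
        A = reconstruct_adjacency(np.zeros((6, 3)))
        np.testing.assert_allclose(A, 0.5, atol=1e-12)

    def test_orthonormal_rows(self):
        A = reconstruct_adjacency(np.eye(4))
        expit1 = 1.0 / (1.0 + np.exp(-1.0))
        np.testing.assert_allclose(np.diag(A), expit1, atol=1e-12)
        off = A[~np.eye(4, dtype=bool)]
        np.testing.assert_allclose(off, 0.5, atol=1e-12)

    def test_scaling_increases_diagonal(self):
        rng = np.random.default_rng(9)
        Z = rng.normal(size=(8, 5))
        diags = [np.diag(reconstruct_adjacency(c * Z)) for c in (0.5, 1.0, 2.0)]
        assert np.all(diags[1] > diags[0]) and np.all(diags[2] > diags[1])

    def test_nonfinite_rejected(self):
        with pytest.raises(ValueError, match="finite"):
            reconstruct_adjacency(np.array([[np.inf]]))


class TestTotalLoss:
    def test_kl_zero_at_prior(self):
        n, d, g = 5, 3, 4
        I = np.zeros((n, g))
        A = sp.identity(n, format="csr")
        L = np.full((n, 2), 0.5)
        _, terms = total_loss(I, I, A, np.full((n, n), 0.5),
                              np.zeros((n, d)), np.zeros((n, d)), L, L)
        assert terms["kl"] == pytest.approx(0.0, abs=1e-12)

    def test_perfect_reconstruction_on_four_cell_graph(self):
        # I' = I and A' = binarized A: MSE 0, BCE at the entropy floor 0
        n, g = 4, 3
        rng = np.random.default_rng(10)
        I = rng.random((n, g))
        A = sp.csr_matrix(np.array([
            [1, 0.8, 0, 0], [0.8, 1, 0.5, 0], [0, 0.5, 1, 0], [0, 0, 0, 1.0]]))
        target = (A.toarray() > 0).astype(float)
        A_prime = np.clip(target, 1e-12, 1 - 1e-12)
        L = np.full((n, 2), 0.5)
        _, terms = total_loss(I, I, A, A_prime, np.zeros((n, 2)),
                              np.zeros((n, 2)), L, L)
        assert terms["ae"] == 0.0
        assert terms["graph"] == pytest.approx(0.0, abs=1e-9)

    def test_bce_matches_brute_force_loop(self):
        n = 4
        rng = np.random.default_rng(11)
        A = sp.csr_matrix((np.array([0.9, 0.9, 0.4, 0.4]),
                           (np.array([0, 1, 2, 3]), np.array([1, 0, 3, 2]))),
                          shape=(n, n))
        A_prime = rng.uniform(0.1, 0.9, (n, n))
        L = np.full((n, 2), 0.5)
        _, terms = total_loss(np.zeros((n, 1)), np.zeros((n, 1)), A, A_prime,
                              np.zeros((n, 2)), np.zeros((n, 2)), L, L)
        target = (A.toarray() > 0).astype(float)
        pos_w = (target.size - target.sum()) / target.sum()
        acc = 0.0
        for i in range(n):
            for j in range(n):
                p = A_prime[i, j]
                acc += (pos_w * target[i, j] * -np.log(p)
                        + (1 - target[i, j]) * -np.log(1 - p))
        assert terms["graph"] == pytest.approx(acc / target.size, abs=1e-9)

    def test_kl_matches_brute_force_loop(self):
        rng = np.random.default_rng(12)
        n, d = 7, 4
        mu = rng.normal(size=(n, d))
        lv = rng.normal(size=(n, d))
        L = np.full((n, 2), 0.5)
        _, terms = total_loss(np.zeros((n, 1)), np.zeros((n, 1)),
                              sp.identity(n, format="csr"), np.full((n, n), 0.5),
                              mu, lv, L, L)
        acc = 0.0
        for i in range(n):
            for j in range(d):
                acc += 1 + lv[i, j] - mu[i, j] ** 2 - np.exp(lv[i, j])
        assert terms["kl"] == pytest.approx(-0.5 * acc / n, abs=1e-9)

    def test_classifier_term_zero_for_matching_one_hot(self):
        n = 6
        L = np.zeros((n, 3)); L[np.arange(n) % 3 == 0, 0] = 1
        L[np.arange(n) % 3 == 1, 1] = 1; L[np.arange(n) % 3 == 2, 2] = 1
        _, terms = total_loss(np.zeros((n, 1)), np.zeros((n, 1)),
                              sp.identity(n, format="csr"), np.full((n, n), 0.5),
                              np.zeros((n, 2)), np.zeros((n, 2)), L, L)
        assert terms["cls"] == pytest.approx(0.0, abs=1e-9)

    def test_soft_target_ce_matches_brute_force(self):
        rng = np.random.default_rng(13)
        n, k = 9, 4
        L = rng.dirichlet(np.ones(k), n)
        Q = rng.dirichlet(np.ones(k), n)
        _, terms = total_loss(np.zeros((n, 1)), np.zeros((n, 1)),
                              sp.identity(n, format="csr"), np.full((n, n), 0.5),
                              np.zeros((n, 2)), np.zeros((n, 2)), L, Q)
        acc = -sum(L[i, c] * np.log(Q[i, c]) for i in range(n) for c in range(k))
        assert terms["cls"] == pytest.approx(acc / n, abs=1e-9)


class TestTrainStage2:
    @pytest.fixture(scope="class")
    def small_problem(self):
        ds = _dataset(60, 15, seed=20)
        graph = build_spatial_graph(ds.coords, n_neighbors=5)
        pl = _pseudo(60, 3, seed=20)
        return ds, graph, pl

    def test_zero_epochs_is_initialization(self, small_problem):
        ds, graph, pl = small_problem
        cfg = GcnConfig(ae_hidden=(16, 8), vgae_hidden=6, epochs=0, seed=21)
        a = train_stage2(ds, graph, pl, cfg)
        b = JointModel(ds.n_genes, 3, cfg)
        for pa, pb in zip(a.params(), b.params()):
            np.testing.assert_array_equal(pa, pb)

    def test_checkpoint_no_worse_than_first_epoch(self, small_problem):
        ds, graph, pl = small_problem
        cfg = GcnConfig(ae_hidden=(16, 8), vgae_hidden=6, epochs=30, seed=22)
        model = train_stage2(ds, graph, pl, cfg)
        totals = [t["total"] for t in model.loss_log]
        assert min(totals) <= totals[0]

    def test_same_seed_identical_final_loss(self, small_problem):
        ds, graph, pl = small_problem
        cfg = GcnConfig(ae_hidden=(16, 8), vgae_hidden=6, epochs=10, seed=23)
        a = train_stage2(ds, graph, pl, cfg)
        b = train_stage2(ds, graph, pl, cfg)
        assert a.loss_log[-1]["total"] == pytest.approx(b.loss_log[-1]["total"], abs=1e-6)

    def test_label_count_mismatch(self, small_problem):
        ds, graph, _ = small_problem
        from spatype.datasets import ValidationError

        with pytest.raises(ValidationError, match="cells"):
            train_stage2(ds, graph, _pseudo(59, 3), GcnConfig(epochs=1))

    def test_latent_identity_z_equals_x_plus_s(self, small_problem):
        ds, graph, pl = small_problem
        cfg = GcnConfig(ae_hidden=(16, 8), vgae_hidden=6, epochs=5, seed=24)
        model = train_stage2(ds, graph, pl, cfg)
        X = model.encode_expression(ds.counts)
        state = model.encode_graph(X, graph, tau=np.random.default_rng(0).normal(size=X.shape))
        np.testing.assert_array_equal(state.Z, state.X + state.S)
        np.testing.assert_array_equal(state.S,
                                      state.mu + np.exp(0.5 * state.log_var) * state.tau)

    def test_training_log_tsv(self, small_problem, tmp_path):
        ds, graph, pl = small_problem
        cfg = GcnConfig(ae_hidden=(16, 8), vgae_hidden=6, epochs=3, seed=25)
        path = tmp_path / "log.tsv"
        train_stage2(ds, graph, pl, cfg, log_path=str(path))
        import pandas as pd

        log = pd.read_csv(path, sep="\t", index_col=0)
        assert len(log) == 3 and {"ae", "graph", "kl", "cls", "total"} <= set(log.columns)


class TestAnnotate:
    @pytest.fixture(scope="class")
    def trained(self):
        ds = _dataset(60, 15, seed=30)
        graph = build_spatial_graph(ds.coords, n_neighbors=5)
        pl = _pseudo(60, 4, seed=30)
        cfg = GcnConfig(ae_hidden=(16, 8), vgae_hidden=6, epochs=10, seed=31)
        return train_stage2(ds, graph, pl, cfg), ds, graph

    def test_every_cell_gets_a_taxonomy_type(self, trained):
        model, ds, graph = trained
        res = annotate(model, ds, graph)
        assert len(res.predicted) == ds.n_cells
        assert set(res.predicted) <= set(model.taxonomy)

    def test_repeated_annotation_identical(self, trained):
        model, ds, graph = trained
        a = annotate(model, ds, graph)
        b = annotate(model, ds, graph)
        assert a.predicted == b.predicted
        np.testing.assert_array_equal(a.probs, b.probs)

    def test_checkpoint_round_trip(self, trained, tmp_path):
        model, ds, graph = trained
        path = str(tmp_path / "joint.npz")
        model.save(path)
        back = JointModel.load(path)
        a = annotate(model, ds, graph)
        b = annotate(back, ds, graph)
        assert a.predicted == b.predicted

    def test_incompatible_genes_rejected(self, trained):
        model, ds, graph = trained
        from dataclasses import replace
        from spatype.datasets import ValidationError

        wrong = replace(ds, genes=[g + "_y" for g in ds.genes])
        with pytest.raises(ValidationError, match="incompatible"):
            annotate(model, wrong, graph)
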