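import dataclasses

import numpy as np
import pytest
import scipy.sparse as sp
from sklearn.cluster import KMeans

from biotypegcn import (
    TrainingConfig,
    deep_kmeans_loss,
    diagnostic_ce_loss,
    gcn_layer,
    reconstruction_loss,
    total_loss,
    train,
)
from biotypegcn.exceptions import (
    ConfigurationError,
    DataShapeError,
    EmptyClusterError,
)
from biotypegcn.graph import normalize_adjacency
from biotypegcn.model import (
    BiotypeModel,
    _Adam,
    _forward,
    _init_params,
    _losses_and_grads,
    assign_biotypes,
    farthest_point_seeds,
    nearest_centroid_labels,
)
from conftest import make_config, planted_cohort


class TestGCNLayer:
    def test_identity_propagation_and_weights(self):
        h = np.random.default_rng(0).standard_normal((4, 3))
        out = gcn_layer(h, np.eye(4), np.eye(3), activation="linear")
        assert np.allclose(out, h)

    def test_zero_weights(self):
        h = np.random.default_rng(0).standard_normal((4, 3))
        assert np.allclose(gcn_layer(h, np.eye(4), np.zeros((3, 2)), "relu"), 0.0)

    def test_path_graph_matches_dense_product(self):
        a = np.array([[0, 1, 0], [1, 0, 1], [0, 1, 0]], dtype=float)
        a_hat = normalize_adjacency(a)
        h = np.array([[1.0, 2.0], [3.0, -1.0], [0.5, 0.0]])
        w = np.array([[1.0, -2.0], [0.5, 1.0]])
        expected = np.maximum(a_hat @ h @ w, 0.0)
        assert np.allclose(gcn_layer(h, a_hat, w, "relu"), expected)

    def test_shape_mismatch(self):
        with pytest.raises(DataShapeError):
            gcn_layer(np.ones((3, 2)), np.eye(3), np.ones((3, 2)))


class TestLosses:
    def test_reconstruction_zero_iff_equal(self):
        x = np.random.default_rng(0).standard_normal((4, 6))
        assert reconstruction_loss(x, x) == 0.0
        assert reconstruction_loss(np.zeros((2, 2)), np.ones((2, 2))) == pytest.approx(1.0)

    def test_reconstruction_matches_elementwise_oracle(self):
        rng = np.random.default_rng(1)
        x, xh = rng.standard_normal((4, 6)), rng.standard_normal((4, 6))
        oracle = sum((x[i, j] - xh[i, j]) ** 2 for i in range(4) for j in range(6)) / 24
        assert reconstruction_loss(x, xh) == pytest.approx(oracle)

    def test_ce_all_zero_logits_is_ln2(self):
        logits = np.zeros(5)
        y = np.array([1, 0, 1, 1, 0], dtype=float)
        assert diagnostic_ce_loss(logits, y) == pytest.approx(np.log(2.0))

    def test_ce_confident_correct_limit(self):
        y = np.array([1.0, 0.0])
        assert diagnostic_ce_loss(np.array([30.0, -30.0]), y) < 1e-12

    def test_ce_matches_summation_oracle_and_mask(self):
        logits = np.array([0.3, -1.2, 2.0, 0.0, -0.5])
        y = np.array([1.0, 0.0, 1.0, 0.0, 1.0])
        mask = np.array([True, True, False, True, True])
        p = 1 / (1 + np.exp(-logits[mask]))
        oracle = -np.mean(y[mask] * np.log(p) + (1 - y[mask]) * np.log(1 - p))
        assert diagnostic_ce_loss(logits, y, mask) == pytest.approx(oracle)
        with pytest.raises(DataShapeError):
            diagnostic_ce_loss(logits, y, np.zeros(5, dtype=bool))

    def test_deep_kmeans_zero_on_centroids(self):
        mu = np.array([[0.0, 0.0], [5.0, 5.0]])
        z = mu[[0, 1, 0, 1]]
        assert deep_kmeans_loss(z, mu, alpha=3.0) == pytest.approx(0.0)

    def test_deep_kmeans_single_centroid_arithmetic(self):
        z = np.array([[1.0, 0.0], [-1.0, 0.0]])
        mu = np.zeros((1, 2))
        assert deep_kmeans_loss(z, mu, alpha=7.0) == pytest.approx(1.0)

    def test_deep_kmeans_hard_limit_matches_nearest_centroid_oracle(self):
        rng = np.random.default_rng(2)
        z = rng.standard_normal((6, 3))
        mu = rng.standard_normal((2, 3))
        d2 = ((z[:, None] - mu[None]) ** 2).sum(axis=2)
        oracle = d2.min(axis=1).mean()
        assert deep_kmeans_loss(z, mu, alpha=1000.0) == pytest.approx(oracle, abs=1e-6)

    def test_total_loss_weighting(self):
        cfg = TrainingConfig(K=2)
        parts = total_loss(1.0, 1.0, 1.0, cfg)
        assert parts.total == pytest.approx(0.12)
        assert total_loss(0.0, 0.0, 0.0, cfg).total == 0.0
        cfg2 = dataclasses.replace(cfg, gamma_rec=1.0, gamma_ce=0.0, gamma_cluster=0.0)
        assert total_loss(0.7, 3.0, 9.0, cfg2).total == pytest.approx(0.7)

    def test_negative_weight_rejected(self):
        with pytest.raises(ConfigurationError):
            TrainingConfig(K=2, gamma_rec=-0.1)


class TestGradients:
    def test_analytic_gradients_match_finite_differences(self):
        rng = np.random.default_rng(0)
        n, d = 7, 5
        cfg = TrainingConfig(K=2, hidden_dims=(4,), embedding_dim=3, seed=0)
        a = rng.random((n, n))
        a = (a + a.T) / 2
        np.fill_diagonal(a, 0.0)
        a_hat = sp.csr_matrix(normalize_adjacency(a))
        x = rng.standard_normal((n, d))
        y = (rng.random(n) < 0.6).astype(float)
        mask = np.ones(n, dtype=bool)
        cluster_idx = np.flatnonzero(y == 1)
        params = _init_params(d, cfg, rng)
        params["centroids"] = rng.standard_normal((2, 3))

        def loss():
            fwd = _forward(x, a_hat, params, 2, 2, embed_norm=True)
            parts, _ = _losses_and_grads(
                x, y, a_hat, params, fwd, cfg, mask, cluster_idx,
                alpha=2.0, with_cluster=True,
            )
            return parts.total

        fwd = _forward(x, a_hat, params, 2, 2, embed_norm=True)
        _, grads = _losses_and_grads(
            x, y, a_hat, params, fwd, cfg, mask, cluster_idx,
            alpha=2.0, with_cluster=True,
        )
        eps = 1e-6
        for key in params:
            if key == "enc_b_1":
                # embedding-layer bias is cancelled by the normalization
                # layer; its true gradient is identically zero
                assert np.abs(grads[key]).max() < 1e-10
                continue
            flat = params[key].reshape(-1)
            g = np.asarray(grads[key]).reshape(-1)
            for idx in range(0, flat.size, max(1, flat.size // 5)):
                orig = flat[idx]
                flat[idx] = orig + eps
                lp = loss()
                flat[idx] = orig - eps
                lm = loss()
                flat[idx] = orig
                num = (lp - lm) / (2 * eps)
                assert num == pytest.approx(g[idx], rel=1e-4, abs=1e-9), key


class TestTraining:
    def test_loss_decomposition_identity_every_epoch(self, model_seed1):
        cfg = model_seed1.config
        for h in model_seed1.loss_history:
            expected = (
                cfg.gamma_rec * h.l_rec
                + cfg.gamma_ce * h.l_ce
                + cfg.gamma_cluster * h.l_cluster
            )
            assert h.total == pytest.approx(expected, abs=1e-9)
            assert min(h.l_rec, h.l_ce, h.l_cluster) >= 0

    def test_same_seed_reproduces_assignments_bitwise(self, cohort_seed1):
        _, _, _, graph, _ = cohort_seed1
        cfg = make_config(1, pretrain_epochs=15, joint_epochs=25)
        m1 = train(graph, cfg)
        m2 = train(graph, cfg)
        assert np.array_equal(m1.assignments, m2.assignments)
        assert np.array_equal(m1.embeddings, m2.embeddings)

    def test_zero_weight_ce_inert_under_label_shuffle(self):
        # with gamma_ce = 0 the gradients (hence the whole clustering
        # trajectory) are identical whichever diagnosis labels are supplied
        rng = np.random.default_rng(0)
        n, d = 9, 6
        cfg = TrainingConfig(K=2, gamma_ce=0.0, hidden_dims=(4,), embedding_dim=3)
        a = rng.random((n, n))
        a = (a + a.T) / 2
        np.fill_diagonal(a, 0.0)
        a_hat = sp.csr_matrix(normalize_adjacency(a))
        x = rng.standard_normal((n, d))
        mask = np.ones(n, dtype=bool)
        cluster_idx = np.arange(4)
        params = _init_params(d, cfg, rng)
        params["centroids"] = rng.standard_normal((2, 3))
        y1 = (rng.random(n) < 0.5).astype(float)
        y2 = rng.permutation(y1)
        grads = []
        for y in (y1, y2):
            fwd = _forward(x, a_hat, params, 2, 2, embed_norm=True)
            _, g = _losses_and_grads(
                x, y, a_hat, params, fwd, cfg, mask, cluster_idx,
                alpha=2.0, with_cluster=True,
            )
            grads.append(g)
        for key in grads[0]:
            if key.startswith("clf"):
                continue  # the head itself still sees the labels
            assert np.array_equal(grads[0][key], grads[1][key]), key

    def test_smoothed_loss_non_increasing_after_burn_in(self, model_seed1):
        totals = np.array([h.total for h in model_seed1.loss_history])
        pre = model_seed1.config.pretrain_epochs
        smooth = np.convolve(totals[:pre], np.ones(5) / 5, mode="valid")
        assert np.all(np.diff(smooth[5:]) <= 1e-3)

    def test_permutation_equivariance_of_assignments(self):
        _, subjects, fnc, graph, _ = planted_cohort(3)
        from biotypegcn.graph import build_graph

        cfg = make_config(3, pretrain_epochs=15, joint_epochs=25)
        m1 = train(graph, cfg)
        rng = np.random.default_rng(0)
        perm = rng.permutation(len(subjects))
        g2 = build_graph([subjects[i] for i in perm], fnc[perm])
        m2 = train(g2, cfg)
        # map: patient positions in permuted graph -> original patient ids
        lab1 = dict(zip(m1.patient_ids, m1.assignments))
        lab2 = dict(zip(m2.patient_ids, m2.assignments))
        agreement = np.mean([lab1[i] == lab2[i] for i in lab1])
        assert agreement > 0.95

    def test_k_exceeding_patients_rejected(self):
        _, _, _, graph, _ = planted_cohort(4)
        with pytest.raises(ConfigurationError):
            train(graph, make_config(0, K=500, pretrain_epochs=2, joint_epochs=2))


class TestAssignment:
    def _toy_model(self, z, centroids, x=None):
        n = z.shape[0]
        from biotypegcn.graph import PopulationGraph

        x = np.random.default_rng(0).standard_normal((n, 4)) if x is None else x
        g = PopulationGraph(
            X=x, A=np.zeros((n, n)), labels=np.ones(n, dtype=int),
            ids=[f"S{i}" for i in range(n)], patient_mask=np.ones(n, dtype=bool),
        )
        return BiotypeModel(
            params={"centroids": centroids}, embeddings=z, centroids=centroids,
            assignments=np.empty(0, int), patient_index=np.arange(n),
            cluster_index=np.arange(n), patient_ids=g.ids,
            templates=np.empty((0, 4)), config=TrainingConfig(K=centroids.shape[0]),
            loss_history=[], graph=g,
        )

    def test_nearest_centroid_oracle(self):
        rng = np.random.default_rng(1)
        z = rng.standard_normal((6, 2))
        mu = rng.standard_normal((2, 2))
        model = self._toy_model(z, mu)
        assignments, _ = assign_biotypes(model)
        d2 = ((z[:, None] - mu[None]) ** 2).sum(axis=2)
        hard = d2.argmin(axis=1)
        # up to the size-based relabeling, groupings must agree
        for k in range(2):
            members = assignments[hard == k]
            assert len(set(members)) == 1

    def test_biotype_one_is_largest_cluster(self):
        z = np.vstack([np.zeros((30, 2)), np.ones((10, 2)) * 5])
        mu = np.array([[5.0, 5.0], [0.0, 0.0]])
        model = self._toy_model(z, mu)
        assignments, templates = assign_biotypes(model)
        assert (assignments == 1).sum() == 30
        assert (assignments == 2).sum() == 10

    def test_templates_are_raw_fnc_means(self):
        z = np.vstack([np.zeros((3, 2)), np.ones((2, 2)) * 9])
        mu = np.array([[0.0, 0.0], [9.0, 9.0]])
        x = np.arange(20, dtype=float).reshape(5, 4)
        model = self._toy_model(z, mu, x=x)
        _, templates = assign_biotypes(model)
        assert np.allclose(templates[0], x[:3].mean(axis=0))
        assert np.allclose(templates[1], x[3:].mean(axis=0))

    def test_empty_cluster_raises(self):
        z = np.zeros((5, 2))
        mu = np.array([[0.0, 0.0], [50.0, 50.0]])
        with pytest.raises(EmptyClusterError):
            assign_biotypes(self._toy_model(z, mu))

    def test_nearest_centroid_labels_helper(self):
        pts = np.array([[0.0, 0.0], [10.0, 0.0]])
        mu = np.array([[1.0, 0.0], [9.0, 0.0]])
        assert nearest_centroid_labels(pts, mu).tolist() == [1, 2]


class TestDeepKMeansReducesToClassical:
    def test_centroid_only_optimization_matches_kmeans(self):
        # gamma_rec = gamma_ce = 0 and alpha -> inf on fixed embeddings:
        # optimizing centroids alone recovers the classical K-means objective
        rng = np.random.default_rng(3)
        z = np.vstack([rng.normal(c, 0.6, (14, 3)) for c in (0.0, 4.0, 8.0)])
        params = {"centroids": farthest_point_seeds(z, 3)}
        opt = _Adam(0.05)
        for step in range(800):
            # geometric annealing 1 -> 1000, as in joint training
            alpha = 1.0 * (1000.0 ** (step / 799))
            d2 = ((z[:, None, :] - params["centroids"][None]) ** 2).sum(axis=2)
            m = -alpha * d2
            m -= m.max(axis=1, keepdims=True)
            s = np.exp(m)
            s /= s.sum(axis=1, keepdims=True)
            inner = (s * d2).sum(axis=1, keepdims=True)
            coef = (1 / len(z)) * s * (1 - alpha * (d2 - inner))
            diff = z[:, None, :] - params["centroids"][None]
            opt.step(params, {"centroids": -2 * (coef[:, :, None] * diff).sum(axis=0)})
        final = deep_kmeans_loss(z, params["centroids"], 1e6)
        best = min(
            KMeans(3, n_init=1, random_state=s_).fit(z).inertia_ / len(z)
            for s_ in range(50)
        )
        assert final <= best * 1.02
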