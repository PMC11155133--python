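"""DEC algebra, spatial regularizer and the two-stage optimization loop."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra.numpy import arrays
from scipy.stats import spearmanr

import hyperspot as hs
from hyperspot.exceptions import ConfigError
from hyperspot.model import forward_pass, init_params
from hyperspot.training import (
    Adam,
    TrainConfig,
    dec_loss,
    fit,
    kmeans_init,
    pretrain,
    soft_assignment,
    spatial_regularization,
    target_distribution,
    total_loss,
)
from hyperspot.utils import stage_seed


class TestSoftAssignment:
    def test_closed_form_two_centroids(self):
        H = np.array([[0.0, 0.0]])
        cents = np.array([[0.0, 0.0], [np.sqrt(3.0), 0.0]])  # squared dists 0 and 3
        np.testing.assert_allclose(soft_assignment(H, cents), [[0.8, 0.2]], atol=1e-12)

    def test_equidistant_gives_uniform(self):
        H = np.array([[0.0, 0.0]])
        cents = np.array([[1.0, 0.0], [-1.0, 0.0], [0.0, 1.0], [0.0, -1.0]])
        np.testing.assert_allclose(soft_assignment(H, cents), [[0.25] * 4], atol=1e-12)

    def test_matches_formula_oracle(self, rng):
        H = rng.normal(size=(7, 3))
        cents = rng.normal(size=(4, 3))
        Q = soft_assignment(H, cents)
        ref = np.zeros((7, 4))
        for i in range(7):
            for k in range(4):
                ref[i, k] = 1.0 / (1.0 + np.sum((H[i] - cents[k]) ** 2))
            ref[i] /= ref[i].sum()
        np.testing.assert_allclose(Q, ref, atol=1e-8)
        np.testing.assert_allclose(Q.sum(axis=1), 1.0, atol=1e-6)


class TestTargetDistribution:
    def test_one_hot_is_fixed_point(self):
        Q = np.array([[1.0, 0.0], [0.0, 1.0], [1.0, 0.0]])
        np.testing.assert_allclose(target_distribution(Q), Q, atol=1e-9)

    def test_single_spot_is_fixed_point(self):
        Q = np.array([[0.3, 0.5, 0.2]])
        np.testing.assert_allclose(target_distribution(Q), Q, atol=1e-12)

    def test_hand_derived_case(self):
        Q = np.array([[0.9, 0.1], [0.6, 0.4]])
        T = target_distribution(Q)
        np.testing.assert_allclose(T, [[0.9643, 0.0357], [0.4286, 0.5714]], atol=5e-5)
        np.testing.assert_allclose(T.sum(axis=1), 1.0, atol=1e-12)


class TestDecLoss:
    def test_zero_when_equal(self):
        Q = np.array([[0.7, 0.3], [0.4, 0.6]])
        assert dec_loss(Q, Q) == pytest.approx(0.0, abs=1e-12)

    def test_hand_derived_value(self):
        Q = np.array([[0.9, 0.1], [0.6, 0.4]])
        T = target_distribution(Q)
        ref = float(np.sum(T * np.log(T / Q)))  # literal double-sum oracle
        assert dec_loss(T, Q) == pytest.approx(ref, abs=1e-10)
        assert dec_loss(T, Q) == pytest.approx(0.089, abs=1e-3)

    @settings(max_examples=200, deadline=None, derandomize=True)
    @given(
        arrays(np.float64, (6, 4), elements=st.floats(0.01, 1.0)),
        arrays(np.float64, (6, 4), elements=st.floats(0.01, 1.0)),
    )
    def test_nonnegativity(self, a, b):
        T = a / a.sum(axis=1, keepdims=True)
        Q = b / b.sum(axis=1, keepdims=True)
        assert dec_loss(T, Q) >= -1e-12

    def test_shape_mismatch_raises(self):
        with pytest.raises(ConfigError):
            dec_loss(np.ones((2, 2)) / 2, np.ones((2, 3)) / 3)


class TestSpatialRegularization:
    def test_maximal_embedding_distances_give_zero(self):
        # two spots: normalized embedding distance is 1 off-diagonal,
        # diagonal pairs have zero spatial distance -> loss exactly 0
        S = np.array([[0.0, 0.0], [3.0, 0.0]])
        H = np.array([[0.0], [5.0]])
        assert spatial_regularization(S, H) == pytest.approx(0.0, abs=1e-12)

    def test_constant_embedding_gives_mean_spatial_distance(self, rng):
        S = rng.uniform(size=(10, 2))
        H = np.ones((10, 3))
        D = np.linalg.norm(S[:, None] - S[None, :], axis=2)
        expected = (D / D.max()).mean()
        assert spatial_regularization(S, H) == pytest.approx(expected, abs=1e-12)

    def test_literal_double_loop_oracle(self, rng):
        S = rng.uniform(size=(6, 2))
        H = rng.normal(size=(6, 4))
        Ds = np.array([[np.linalg.norm(S[i] - S[j]) for j in range(6)] for i in range(6)])
        Dh = np.array([[np.linalg.norm(H[i] - H[j]) for j in range(6)] for i in range(6)])
        Ds /= Ds.max()
        Dh /= Dh.max()
        ref = sum(
            Ds[i, j] * (1 - Dh[i, j]) for i in range(6) for j in range(6)
        ) / 36.0
        assert spatial_regularization(S, H) == pytest.approx(ref, abs=1e-8)

    def test_chunked_equals_unchunked(self, rng):
        S = rng.uniform(size=(50, 2))
        H = rng.normal(size=(50, 5))
        full = spatial_regularization(S, H, chunk=4096)
        chunked = spatial_regularization(S, H, chunk=7)
        assert chunked == pytest.approx(full, abs=1e-12)

    def test_sampled_estimator_within_monte_carlo_error(self, rng):
        S = rng.uniform(size=(40, 2))
        H = rng.normal(size=(40, 5))
        exact = spatial_regularization(S, H)
        Ds = np.linalg.norm(S[:, None] - S[None, :], axis=2)
        Dh = np.linalg.norm(H[:, None] - H[None, :], axis=2)
        vals = (Ds / Ds.max()) * (1 - Dh / Dh.max())
        n_pairs = 4096
        se = vals.std() / np.sqrt(n_pairs)
        for seed in range(5):
            est = spatial_regularization(S, H, mode="sampled", n_pairs=n_pairs, seed=seed)
            assert abs(est - exact) <= 3 * se


class TestTotalLoss:
    def test_arithmetic(self):
        assert total_loss(1.0, 2.0, 3.0, TrainConfig()) == pytest.approx(4.2)

    def test_ablation_weights(self):
        cfg_spa = TrainConfig(lam=0.0)
        cfg_clu = TrainConfig(gamma=0.0)
        assert total_loss(1.0, 5.0, 2.0, cfg_spa) == pytest.approx(3.0)
        assert total_loss(1.0, 5.0, 2.0, cfg_clu) == pytest.approx(1.5)

    def test_weighted_sum_oracle(self, rng):
        for _ in range(20):
            r, c, s = rng.uniform(size=3)
            lam, gam = rng.uniform(size=2)
            cfg = TrainConfig(lam=lam, gamma=gam)
            assert total_loss(r, c, s, cfg) == pytest.approx(r + lam * c + gam * s)


def _small_problem(n=80, f=20, seed=3):
    ds = hs.generate(hs.SyntheticSpec(n_spots=n, n_genes=f, n_domains=2,
                                      markers_per_domain=3, seed=seed))
    dsp, feats = hs.preprocess(ds, min_spots=1, n_components=f)
    _, A = hs.build_hypergraph(dsp.S, k=5)
    return dsp, feats, A


class TestPretrain:
    def test_loss_decreases(self):
        dsp, feats, A = _small_problem()
        cfg = TrainConfig(pretrain_epochs=40, k=5, seed=0)
        params = init_params(feats.n_features, seed=1)
        trace = pretrain(params, feats.values, A, dsp.S, cfg)
        assert trace.rec[-1] < trace.rec[0]
        assert len(trace.total) == 40

    def test_zero_lr_leaves_parameters_unchanged(self):
        dsp, feats, A = _small_problem()
        cfg = TrainConfig(pretrain_epochs=5, lr=0.0, k=5, seed=0)
        params = init_params(feats.n_features, seed=1)
        before = {k: v.copy() for k, v in params.state_arrays().items()}
        loss_before = float(forward_pass(params, feats.values, A, sample=False)["loss_rec"].data)
        pretrain(params, feats.values, A, dsp.S, cfg)
        for k, v in params.state_arrays().items():
            np.testing.assert_array_equal(v, before[k])
        loss_after = float(forward_pass(params, feats.values, A, sample=False)["loss_rec"].data)
        assert loss_after == loss_before

    def test_seeded_determinism(self):
        dsp, feats, A = _small_problem()
        cfg = TrainConfig(pretrain_epochs=10, k=5, seed=4)
        finals = []
        for _ in range(2):
            params = init_params(feats.n_features, seed=1)
            finals.append(pretrain(params, feats.values, A, dsp.S, cfg).rec[-1])
        assert finals[0] == pytest.approx(finals[1], abs=1e-6)


class TestFit:
    def test_more_centroids_than_spots_raises(self, rng):
        with pytest.raises(ConfigError, match="more centroids than spots"):
            kmeans_init(rng.normal(size=(5, 3)), n_centroids=6, seed=0)

    def test_rows_of_q_and_t_sum_to_one(self):
        dsp, feats, A = _small_problem()
        cfg = TrainConfig(pretrain_epochs=5, train_epochs=5, k=5, n_centroids=4, seed=0)
        params = init_params(feats.n_features, seed=1)
        pretrain(params, feats.values, A, dsp.S, cfg)
        _, state, _ = fit(params, feats.values, A, dsp.S, cfg)
        np.testing.assert_allclose(state.Q.sum(axis=1), 1.0, atol=1e-6)
        np.testing.assert_allclose(state.T.sum(axis=1), 1.0, atol=1e-6)
        assert np.all(state.Q > 0)

    def test_total_loss_does_not_increase(self):
        dsp, feats, A = _small_problem()
        cfg = TrainConfig(pretrain_epochs=30, train_epochs=30, k=5, n_centroids=4, seed=0)
        params = init_params(feats.n_features, seed=1)
        pretrain(params, feats.values, A, dsp.S, cfg)
        _, _, trace = fit(params, feats.values, A, dsp.S, cfg)
        assert trace.total[-1] <= trace.total[0]

    def test_degenerate_weights_match_reconstruction_only_loop(self):
        """lambda=0, gamma=0: fit follows the exact trajectory of a loop that
        optimizes the reconstruction loss alone from the same state."""
        dsp, feats, A = _small_problem()
        cfg = TrainConfig(pretrain_epochs=5, train_epochs=8, lam=0.0, gamma=0.0,
                          k=5, n_centroids=4, seed=11)
        params = init_params(feats.n_features, seed=2)
        pretrain(params, feats.values, A, dsp.S, cfg)
        ref = init_params(feats.n_features, seed=2)
        for k, v in params.state_arrays().items():
            getattr(ref, k).data[:] = v

        _, _, trace = fit(params, feats.values, A, dsp.S, cfg)

        # manual reconstruction-only continuation with the same rng stream
        H0 = forward_pass(ref, feats.values, A, sample=False)["H"].data
        cents = kmeans_init(H0, cfg.n_centroids, stage_seed(cfg.seed, "kmeans"))
        from hyperspot.autodiff import Tensor

        cent_t = Tensor(cents, requires_grad=True)
        opt = Adam(ref.trainable() + [cent_t], lr=cfg.lr)
        rng2 = np.random.default_rng(stage_seed(cfg.seed, "fit"))
        rec = []
        for _ in range(cfg.train_epochs):
            opt.zero_grad()
            eps = rng2.standard_normal((feats.values.shape[0], cfg.d_g))
            out = forward_pass(ref, feats.values, A, sample=True, eps=eps)
            out["loss_rec"].backward()
            opt.step()
            rec.append(float(out["loss_rec"].data))
        np.testing.assert_allclose(trace.rec, rec, atol=1e-9)

    def test_spatial_weight_aligns_embedding_with_space(self):
        """gamma=1 gives at least the spatial-distance correlation of gamma=0."""
        corrs = {}
        for gamma in (0.0, 1.0):
            dsp, feats, A = _small_problem(n=120, f=30, seed=5)
            cfg = TrainConfig(pretrain_epochs=40, train_epochs=40, gamma=gamma,
                              k=5, n_centroids=4, seed=2)
            params = init_params(feats.n_features, seed=3)
            pretrain(params, feats.values, A, dsp.S, cfg)
            emb, _, _ = fit(params, feats.values, A, dsp.S, cfg)
            ds_pairs = np.linalg.norm(dsp.S[:, None] - dsp.S[None, :], axis=2).ravel()
            dh_pairs = np.linalg.norm(emb.H[:, None] - emb.H[None, :], axis=2).ravel()
            corrs[gamma] = spearmanr(ds_pairs, dh_pairs).statistic
        assert corrs[1.0] >= corrs[0.0]
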