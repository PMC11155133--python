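"""Forward-pass semantics of the autoencoder and hypergraph-conv branches."""

import numpy as np
import pytest
from scipy import sparse

from hyperspot import build_hypergraph
from hyperspot.autodiff import Tensor
from hyperspot.exceptions import ConfigError
from hyperspot.model import (
    ModelParams,
    decode_reconstruct,
    encode_expression,
    forward_pass,
    hgcn_forward,
    init_params,
    reconstruction_loss,
    vgae_spatial_embedding,
)


def _tiny_params(F=4, hf=5, df=3, hg=4, dg=2, seed=1):
    return init_params(F, hidden_f=hf, d_f=df, hidden_g=hg, d_g=dg, seed=seed)


class TestEncoder:
    def test_zero_weights_give_zero_embedding(self):
        p = _tiny_params()
        for t in (p.W_a, p.b_a, p.W_b, p.b_b):
            t.data[:] = 0.0
        H = encode_expression(np.random.default_rng(0).normal(size=(6, 4)), p)
        np.testing.assert_array_equal(H.data, 0.0)

    def test_elu_is_identity_on_positive_path(self):
        p = _tiny_params(F=1, hf=1, df=1)
        p.W_a.data[:] = 1.0
        p.b_a.data[:] = 0.0
        p.W_b.data[:] = 1.0
        p.b_b.data[:] = 0.0
        x = np.array([[0.3], [2.0]])
        np.testing.assert_allclose(encode_expression(x, p).data, x, atol=1e-12)

    def test_matches_explicit_forward_oracle(self, rng):
        p = _tiny_params(seed=3)
        X = rng.normal(size=(7, 4))

        def elu(v):
            return np.where(v > 0, v, np.expm1(v))

        ref = elu(elu(X @ p.W_a.data + p.b_a.data) @ p.W_b.data + p.b_b.data)
        np.testing.assert_allclose(encode_expression(X, p).data, ref, atol=1e-6)

    def test_shape_mismatch_raises(self):
        with pytest.raises(ConfigError):
            encode_expression(np.ones((3, 9)), _tiny_params(F=4))


class TestHGCN:
    def test_identity_adjacency_reduces_to_mlp(self, rng):
        p = _tiny_params()
        H = rng.normal(size=(6, 3))
        out = hgcn_forward(np.eye(6), H, p.W1_mu, p.W2_mu)
        ref = np.maximum(H @ p.W1_mu.data, 0) @ p.W2_mu.data
        np.testing.assert_allclose(out.data, ref, atol=1e-12)

    def test_zero_input_gives_zero(self):
        p = _tiny_params()
        out = hgcn_forward(np.eye(5), np.zeros((5, 3)), p.W1_mu, p.W2_mu)
        np.testing.assert_array_equal(out.data, 0.0)

    def test_matches_dense_matrix_chain_oracle(self, rng):
        p = _tiny_params()
        S = rng.uniform(size=(10, 2))
        _, A = build_hypergraph(S, k=3)
        H = rng.normal(size=(10, 3))
        ref = A.toarray() @ (np.maximum(A.toarray() @ H @ p.W1_mu.data, 0) @ p.W2_mu.data)
        out_sparse = hgcn_forward(A, H, p.W1_mu, p.W2_mu)
        out_dense = hgcn_forward(A.toarray(), H, p.W1_mu, p.W2_mu)
        np.testing.assert_allclose(out_sparse.data, ref, atol=1e-6)
        np.testing.assert_allclose(out_dense.data, ref, atol=1e-6)

    def test_dimension_mismatch_raises(self):
        p = _tiny_params()
        with pytest.raises(ConfigError):
            hgcn_forward(np.eye(4), np.ones((5, 3)), p.W1_mu, p.W2_mu)


class TestVariationalSampling:
    def _setup(self, rng):
        p = _tiny_params()
        S = rng.uniform(size=(8, 2))
        _, A = build_hypergraph(S, k=2)
        H_f = encode_expression(rng.normal(size=(8, 4)), p)
        return p, A, H_f

    def test_inference_mode_returns_mean(self, rng):
        p, A, H_f = self._setup(rng)
        H_g, mu, _ = vgae_spatial_embedding(A, H_f, p, sample=False)
        np.testing.assert_array_equal(H_g.data, mu.data)

    def test_vanishing_sigma_returns_mean(self, rng):
        p, A, H_f = self._setup(rng)
        # drive the log-std head to its clamp floor: sigma = e^-10
        p.W2_sig.data[:] = -1e6
        H_g, mu, log_sigma = vgae_spatial_embedding(A, H_f, p, seed=0, sample=True)
        assert np.all(log_sigma.data == -10.0)
        np.testing.assert_allclose(H_g.data, mu.data, atol=1e-3)

    def test_seeded_determinism(self, rng):
        p, A, H_f = self._setup(rng)
        a = vgae_spatial_embedding(A, H_f, p, seed=5, sample=True)[0].data
        b = vgae_spatial_embedding(A, H_f, p, seed=5, sample=True)[0].data
        c = vgae_spatial_embedding(A, H_f, p, seed=6, sample=True)[0].data
        np.testing.assert_array_equal(a, b)
        assert not np.array_equal(a, c)

    def test_monte_carlo_mean_approaches_mu(self, rng):
        p, A, H_f = self._setup(rng)
        _, mu, log_sigma = vgae_spatial_embedding(A, H_f, p, sample=False)
        sigma = np.exp(log_sigma.data[0, 0])
        n = 10_000
        draws = mu.data[0, 0] + sigma * np.random.default_rng(42).standard_normal(n)
        assert abs(draws.mean() - mu.data[0, 0]) < 4 * sigma / np.sqrt(n)


class TestDecoder:
    def test_perfect_reconstruction_zero_loss(self, rng):
        X = rng.normal(size=(5, 4))
        assert float(reconstruction_loss(X, X).data) == 0.0

    def test_all_ones_error_closed_form(self):
        assert float(reconstruction_loss(np.zeros((2, 2)), np.ones((2, 2))).data) == 1.0

    def test_elementwise_oracle(self, rng):
        X, Xr = rng.normal(size=(5, 4)), rng.normal(size=(5, 4))
        ref = ((X - Xr) ** 2).sum() / 20
        np.testing.assert_allclose(float(reconstruction_loss(X, Xr).data), ref, atol=1e-12)

    def test_decoder_is_affine(self, rng):
        p = _tiny_params()
        H = rng.normal(size=(6, 5))
        np.testing.assert_allclose(
            decode_reconstruct(H, p).data, H @ p.W_dec.data + p.b_dec.data, atol=1e-12
        )


class TestForwardPass:
    def test_joint_embedding_is_concatenation(self, rng):
        p = _tiny_params()
        S = rng.uniform(size=(8, 2))
        _, A = build_hypergraph(S, k=2)
        out = forward_pass(p, rng.normal(size=(8, 4)), A, sample=False)
        np.testing.assert_array_equal(
            out["H"].data, np.concatenate([out["H_f"].data, out["H_g"].data], axis=1)
        )

    def test_deterministic_given_params_and_seed(self, rng):
        p = _tiny_params()
        S = rng.uniform(size=(8, 2))
        _, A = build_hypergraph(S, k=2)
        X = rng.normal(size=(8, 4))
        a = forward_pass(p, X, A, sample=True, seed=9)["loss_rec"].data
        b = forward_pass(p, X, A, sample=True, seed=9)["loss_rec"].data
        assert float(a) == float(b)

    def test_permutation_equivariance(self, rng):
        p = _tiny_params()
        S = rng.uniform(size=(12, 2))
        X = rng.normal(size=(12, 4))
        _, A = build_hypergraph(S, k=3)
        perm = rng.permutation(12)
        _, A_perm = build_hypergraph(S[perm], k=3)
        H = forward_pass(p, X, A, sample=False)["H"].data
        H_perm = forward_pass(p, X[perm], A_perm, sample=False)["H"].data
        np.testing.assert_allclose(H_perm, H[perm], atol=1e-10)

    def test_reconstruction_gradient_matches_numerics(self, rng):
        p = _tiny_params()
        S = rng.uniform(size=(6, 2))
        X = rng.normal(size=(6, 4))
        _, A = build_hypergraph(S, k=2)
        eps = rng.standard_normal((6, 2))
        loss = forward_pass(p, X, A, sample=True, eps=eps)["loss_rec"]
        loss.backward()
        h = 1e-6
        for name in ModelParams.__dataclass_fields__:
            arr = getattr(p, name).data
            ana = getattr(p, name).grad
            it = np.nditer(arr, flags=["multi_index"])
            num = np.zeros_like(arr)
            for _ in it:
                idx = it.multi_index
                orig = arr[idx]
                arr[idx] = orig + h
                fp = float(forward_pass(p, X, A, sample=True, eps=eps)["loss_rec"].data)
                arr[idx] = orig - h
                fm = float(forward_pass(p, X, A, sample=True, eps=eps)["loss_rec"].data)
                arr[idx] = orig
                num[idx] = (fp - fm) / (2 * h)
            scale = np.maximum(np.abs(ana), np.abs(num))
            mask = scale > 1e-10
            if mask.any():
                rel = np.abs(ana - num)[mask] / scale[mask]
                assert rel.max() < 1e-4, name


def test_checkpoint_round_trip(tmp_path, rng):
    p = _tiny_params(seed=8)
    from hyperspot.model import load_params, save_params

    save_params(p, tmp_path / "ckpt")
    back = load_params(tmp_path / "ckpt")
    for name, arr in p.state_arrays().items():
        np.testing.assert_array_equal(getattr(back, name).data, arr)
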