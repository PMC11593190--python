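"""ViT encoder unit tests, including a per-head loop oracle for MHA."""
import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from histofuse.imageio_preproc import ImageTile
from histofuse.vit_context import (LayerParams, ViTConfig, attention,
                                   encode_tokens, encoder_layer, gelu,
                                   init_params, layer_norm,
                                   multi_head_attention, patchify,
                                   softmax_rows, vit_encode)


def oracle_multi_head(X, params, h):
    """Independent per-head loop: explicit softmax, per-row normalisation."""
    d = X.shape[1]
    d_k = d // h
    Q, K, V = X @ params.Wq, X @ params.Wk, X @ params.Wv
    heads = []
    for i in range(h):
        q = Q[:, i * d_k:(i + 1) * d_k]
        k = K[:, i * d_k:(i + 1) * d_k]
        v = V[:, i * d_k:(i + 1) * d_k]
        scores = np.empty((q.shape[0], k.shape[0]))
        for a in range(q.shape[0]):
            for b in range(k.shape[0]):
                scores[a, b] = float(q[a] @ k[b]) / math.sqrt(d_k)
        W = np.empty_like(scores)
        for a in range(scores.shape[0]):
            e = np.exp(scores[a] - scores[a].max())
            W[a] = e / e.sum()
        heads.append(W @ v)
    return np.concatenate(heads, axis=1) @ params.Wo


def random_layer(rng, d, m):
    return LayerParams(
        Wq=rng.normal(size=(d, d)), Wk=rng.normal(size=(d, d)),
        Wv=rng.normal(size=(d, d)), Wo=rng.normal(size=(d, d)),
        ln1_g=np.ones(d), ln1_b=np.zeros(d),
        ln2_g=np.ones(d), ln2_b=np.zeros(d),
        W1=rng.normal(size=(d, m)), b1=np.zeros(m),
        W2=rng.normal(size=(m, d)), b2=np.zeros(d))


class TestPatchify:
    def test_224_image_yields_196_tokens_of_768(self, rng):
        px = rng.integers(0, 256, size=(224, 224, 3), dtype=np.uint8)
        patches = patchify(px, 16)
        assert patches.shape == (196, 768)

    def test_locality_of_first_patch(self):
        px = np.zeros((32, 32, 3), dtype=np.uint8)
        px[:16, :16] = 255
        patches = patchify(px, 16)
        assert np.all(patches[0] == 255)
        assert np.all(patches[1:] == 0)

    def test_constant_image_gives_identical_rows(self):
        px = np.full((64, 64, 3), 17, dtype=np.uint8)
        patches = patchify(px, 16)
        assert np.all(patches == patches[0])

    def test_indivisible_geometry_rejected(self):
        with pytest.raises(ValueError, match="divisible"):
            patchify(np.zeros((30, 30, 3)), 16)


class TestSoftmax:
    def test_symmetry(self):
        np.testing.assert_allclose(softmax_rows(np.array([[0.0, 0.0]])),
                                   [[0.5, 0.5]])

    def test_closed_form(self):
        e = math.e
        np.testing.assert_allclose(
            softmax_rows(np.array([[1.0, 0.0]])),
            [[e / (e + 1), 1 / (e + 1)]], atol=1e-12)

    def test_shift_invariance(self, rng):
        M = rng.normal(size=(4, 6))
        np.testing.assert_allclose(softmax_rows(M), softmax_rows(M + 123.0),
                                   atol=1e-12)

    def test_rows_are_stochastic(self, rng):
        S = softmax_rows(rng.normal(scale=10.0, size=(20, 7)))
        assert S.min() >= 0.0
        np.testing.assert_allclose(S.sum(axis=1), 1.0, atol=1e-9)

    @settings(max_examples=50, derandomize=True)
    @given(st.lists(st.lists(st.floats(-1e6, 1e6), min_size=2, max_size=6),
                    min_size=1, max_size=5).filter(
                        lambda rows: len({len(r) for r in rows}) == 1))
    def test_row_stochastic_for_any_finite_matrix(self, rows):
        S = softmax_rows(np.array(rows))
        assert S.min() >= 0.0
        np.testing.assert_allclose(S.sum(axis=1), 1.0, atol=1e-9)


class TestAttention:
    def test_single_token_returns_value(self, rng):
        Q, K = rng.normal(size=(1, 3)), rng.normal(size=(1, 3))
        V = np.array([[2.0, -1.0]])
        np.testing.assert_allclose(attention(Q, K, V), V, atol=1e-12)

    def test_zero_query_uniform_average(self, rng):
        K = rng.normal(size=(5, 4))
        V = rng.normal(size=(5, 2))
        out = attention(np.zeros((3, 4)), K, V)
        np.testing.assert_allclose(out, np.tile(V.mean(axis=0), (3, 1)),
                                   atol=1e-12)

    def test_hand_worked_dk1_example(self):
        Q = K = V = np.array([[1.0], [0.0]])
        out = attention(Q, K, V)
        e = math.e
        assert out[0, 0] == pytest.approx(e / (e + 1), abs=1e-5)  # 0.73106
        assert out[1, 0] == pytest.approx(0.5, abs=1e-12)

    def test_large_scores_remain_finite(self):
        Q = K = np.full((4, 8), 1e4)
        V = np.ones((4, 8))
        out = attention(Q, K, V)
        assert np.all(np.isfinite(out))

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError):
            attention(np.zeros((2, 3)), np.zeros((2, 4)), np.zeros((2, 3)))
        with pytest.raises(ValueError):
            attention(np.zeros((2, 3)), np.zeros((4, 3)), np.zeros((2, 3)))


class TestMultiHead:
    def test_matches_per_head_loop_oracle(self, rng):
        for h, d in [(2, 4), (3, 6), (4, 8)]:
            lp = random_layer(rng, d, 2 * d)
            X = rng.normal(size=(3, d))
            np.testing.assert_allclose(multi_head_attention(X, lp, h),
                                       oracle_multi_head(X, lp, h),
                                       atol=1e-9)

    def test_single_head_identity_output_projection(self, rng):
        d = 4
        lp = random_layer(rng, d, 8)
        lp.Wo = np.eye(d)
        X = rng.normal(size=(5, d))
        expected = attention(X @ lp.Wq, X @ lp.Wk, X @ lp.Wv)
        np.testing.assert_allclose(multi_head_attention(X, lp, 1), expected,
                                   atol=1e-12)

    def test_output_shape_contract(self, rng):
        lp = random_layer(rng, 8, 16)
        X = rng.normal(size=(6, 8))
        assert multi_head_attention(X, lp, 4).shape == X.shape

    def test_indivisible_heads_rejected(self, rng):
        lp = random_layer(rng, 6, 12)
        with pytest.raises(ValueError, match="divisible"):
            multi_head_attention(np.zeros((2, 6)), lp, 4)


class TestEncoderLayer:
    def test_zero_weights_give_residual_identity(self, rng):
        d, m = 4, 8
        lp = LayerParams(
            Wq=np.zeros((d, d)), Wk=np.zeros((d, d)), Wv=np.zeros((d, d)),
            Wo=np.zeros((d, d)),
            ln1_g=np.ones(d), ln1_b=np.zeros(d),
            ln2_g=np.ones(d), ln2_b=np.zeros(d),
            W1=np.zeros((d, m)), b1=np.zeros(m),
            W2=np.zeros((m, d)), b2=np.zeros(d))
        X = rng.normal(size=(5, d))
        np.testing.assert_allclose(encoder_layer(X, lp, 2), X, atol=1e-12)

    def test_matches_stepwise_composition(self, rng):
        d, m, h = 6, 12, 3
        lp = random_layer(rng, d, m)
        X = rng.normal(size=(4, d))
        mid = X + oracle_multi_head(layer_norm(X, lp.ln1_g, lp.ln1_b), lp, h)
        normed = layer_norm(mid, lp.ln2_g, lp.ln2_b)
        expected = mid + gelu(normed @ lp.W1 + lp.b1) @ lp.W2 + lp.b2
        np.testing.assert_allclose(encoder_layer(X, lp, h), expected,
                                   atol=1e-9)

    def test_deterministic(self, rng):
        cfg = ViTConfig(embed_dim=8, n_heads=2, n_layers=2, mlp_dim=16,
                        weight_source=9)
        px = rng.integers(0, 256, size=(32, 32, 3), dtype=np.uint8)
        np.testing.assert_array_equal(encode_tokens(px, cfg),
                                      encode_tokens(px, cfg))


class TestEncode:
    def test_token_matrix_is_196_by_768(self, rng):
        cfg = ViTConfig(n_layers=1, weight_source=0)
        tile = ImageTile(rng.integers(0, 256, size=(224, 224, 3),
                                      dtype=np.uint8))
        tokens = encode_tokens(tile, cfg)
        assert tokens.shape == (196, 768)
        block = vit_encode(tile, cfg)
        assert block.name == "contextual"
        assert block.dim == 196 * 768

    def test_permutation_equivariance_without_positions(self, rng):
        cfg = ViTConfig(patch_size=8, embed_dim=8, n_heads=2, n_layers=1,
                        mlp_dim=16, weight_source=4, positional="zero")
        px = rng.integers(0, 256, size=(24, 24, 3), dtype=np.uint8)
        tokens = encode_tokens(px, cfg)
        # permute the 3x3 patch grid of the input image
        perm = rng.permutation(9)
        patches = px.reshape(3, 8, 3, 8, 3).transpose(0, 2, 1, 3, 4) \
                    .reshape(9, 8, 8, 3)[perm]
        px_perm = patches.reshape(3, 3, 8, 8, 3).transpose(0, 2, 1, 3, 4) \
                         .reshape(24, 24, 3)
        np.testing.assert_allclose(encode_tokens(px_perm, cfg), tokens[perm],
                                   atol=1e-9)

    def test_positions_break_equivariance(self, rng):
        cfg = ViTConfig(patch_size=8, embed_dim=8, n_heads=2, n_layers=1,
                        mlp_dim=16, weight_source=4, positional="sinusoidal")
        px = rng.integers(0, 256, size=(24, 24, 3), dtype=np.uint8)
        tokens = encode_tokens(px, cfg)
        perm = np.roll(np.arange(9), 1)
        patches = px.reshape(3, 8, 3, 8, 3).transpose(0, 2, 1, 3, 4) \
                    .reshape(9, 8, 8, 3)[perm]
        px_perm = patches.reshape(3, 3, 8, 8, 3).transpose(0, 2, 1, 3, 4) \
                         .reshape(24, 24, 3)
        assert not np.allclose(encode_tokens(px_perm, cfg), tokens[perm])

    def test_config_validates_divisibility(self):
        with pytest.raises(ValueError, match="divisible"):
            ViTConfig(embed_dim=10, n_heads=4)
        with pytest.raises(ValueError, match="divisible"):
            ViTConfig().n_tokens(100)

    def test_attention_weights_row_stochastic_inside_encoder(self, rng):
        # indirect check: uniform weights emerge when queries are zeroed
        cfg = ViTConfig(patch_size=8, embed_dim=8, n_heads=2, n_layers=1,
                        mlp_dim=16, weight_source=4)
        params = init_params(cfg, 9, 4)
        X = rng.normal(size=(9, 8))
        params.layers[0].Wq = np.zeros((8, 8))
        out = multi_head_attention(X, params.layers[0], 2)
        assert np.all(np.isfinite(out))
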