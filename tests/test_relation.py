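import numpy as np
import pytest

from conftest import random_boxes
from lcsod.autodiff import Tensor
from lcsod.errors import ConfigurationError, DegenerateBoxError
from lcsod.relation import (
    AttentionWeights,
    RelationParams,
    geometry_features,
    plain_attention,
    relation_attention,
    relation_bias_matrix,
    relation_head,
    sinusoidal_embed,
)


def random_center_boxes(rng, n):
    """Random center-convention boxes with positive extents."""
    c = rng.uniform(-50, 50, size=(n, 2))
    wh = rng.uniform(0.5, 30, size=(n, 2))
    return np.hstack([c, wh])


class TestGeometryFeatures:
    def test_identity_pair_is_zero(self, rng):
        boxes = random_center_boxes(rng, 6)
        feats = geometry_features(boxes, boxes)
        assert np.allclose(np.diagonal(feats, axis1=0, axis2=1).T, 0.0, atol=1e-12)

    def test_worked_example(self):
        a = np.array([[0.0, 0.0, 2.0, 2.0]])
        b = np.array([[2.0, 0.0, 4.0, 2.0]])
        feats = geometry_features(a, b)[0, 0]
        assert np.allclose(feats, [np.log(2), 0.0, -np.log(2), 0.0], atol=1e-12)

    def test_scale_invariance(self, rng):
        boxes_a = random_center_boxes(rng, 20)
        boxes_b = random_center_boxes(rng, 20)
        base = geometry_features(boxes_a, boxes_b)
        for alpha in (0.001, 3.7, 2500.0):
            scaled = geometry_features(alpha * boxes_a, alpha * boxes_b)
            assert np.allclose(scaled, base, atol=1e-12)

    def test_degenerate_box_rejected(self):
        good = np.array([[0.0, 0.0, 1.0, 1.0]])
        bad = np.array([[0.0, 0.0, 0.0, 1.0]])
        with pytest.raises(DegenerateBoxError):
            geometry_features(good, bad)


class TestSinusoidalEmbed:
    def test_zeros_embed_to_alternating_zero_one(self):
        out = sinusoidal_embed(np.zeros((2, 2, 4)))
        assert np.allclose(out[..., 0::2], 0.0)
        assert np.allclose(out[..., 1::2], 1.0)

    def test_default_shape_for_three_boxes(self):
        out = sinusoidal_embed(np.zeros((3, 3, 4)), RelationParams())
        assert out.shape == (3, 3, 64)

    def test_range_bounded(self, rng):
        out = sinusoidal_embed(rng.normal(size=(4, 4, 4)) * 100)
        assert np.all(out >= -1.0) and np.all(out <= 1.0)

    def test_injective_on_coarse_grid(self):
        """Distinct feature values embed to distinct vectors."""
        grid = np.linspace(-3, 3, 61).reshape(-1, 1)
        emb = sinusoidal_embed(grid)
        flat = emb.reshape(len(grid), -1)
        dists = np.linalg.norm(flat[:, None] - flat[None, :], axis=-1)
        np.fill_diagonal(dists, np.inf)
        assert dists.min() > 1e-3


class TestRelationHead:
    def test_constant_map(self):
        params = RelationParams()
        emb = np.zeros((3, 3, params.embed_dim))
        emb[..., 1::2] = 1.0
        W = np.zeros((params.embed_dim, params.M))
        A = np.full(params.M, 0.25)
        out = relation_head(emb, W, A, params)
        assert np.allclose(out, 0.25)

    def test_clamp_floor(self):
        params = RelationParams()
        emb = np.ones((2, 2, params.embed_dim))
        W = np.full((params.embed_dim, params.M), -5.0)
        A = np.zeros(params.M)
        out = relation_head(emb, W, A, params)
        assert np.all(out == params.eps)

    def test_default_shape_has_eight_heads(self, rng):
        params = RelationParams()
        boxes = random_center_boxes(rng, 5)
        bias = relation_bias_matrix(boxes, boxes, rng.normal(size=(64, 8)),
                                    rng.normal(size=8))
        assert bias.shape == (5, 5, 8)

    def test_every_entry_at_least_eps(self, rng):
        params = RelationParams()
        for _ in range(20):
            boxes = random_center_boxes(rng, 4)
            bias = relation_bias_matrix(
                boxes, random_center_boxes(rng, 4),
                rng.normal(size=(64, 8)) * 3, rng.normal(size=8) * 3)
            assert bias.min() >= params.eps

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ConfigurationError):
            relation_head(np.zeros((2, 2, 10)), np.zeros((64, 8)), np.zeros(8))


class TestAttention:
    def test_row_constant_bias_equals_plain(self, rng):
        """Softmax shift invariance ties biased to unbiased attention."""
        d_model, n, m = 32, 6, 8
        weights = AttentionWeights.random(rng, d_model)
        q = rng.normal(size=(n, d_model))
        # bias constant across source positions within each (row, head)
        bias = np.repeat(rng.normal(size=(n, 1, m)), n, axis=1)
        biased = relation_attention(q, bias, weights, n_heads=m)
        plain = plain_attention(q, weights, n_heads=m)
        assert np.allclose(biased, plain, atol=1e-10)

    def test_attention_rows_sum_to_one(self, rng):
        weights = AttentionWeights.random(rng, 32)
        q = rng.normal(size=(5, 32))
        bias = np.abs(rng.normal(size=(5, 5, 8)))
        _, attn = relation_attention(q, bias, weights, return_attn=True)
        assert np.allclose(attn.sum(axis=-1), 1.0, atol=1e-6)

    def test_single_query_attends_to_itself(self, rng):
        weights = AttentionWeights.random(rng, 16)
        q = rng.normal(size=(1, 16))
        out, attn = relation_attention(q, np.ones((1, 1, 8)), weights,
                                       return_attn=True)
        assert np.allclose(attn, 1.0)
        expected = (q @ weights.wv) @ weights.wo
        assert np.allclose(out, expected, atol=1e-10)

    def test_plain_attention_permutation_equivariance(self, rng):
        weights = AttentionWeights.random(rng, 32)
        q = rng.normal(size=(7, 32))
        perm = rng.permutation(7)
        assert np.allclose(plain_attention(q[perm], weights),
                           plain_attention(q, weights)[perm], atol=1e-10)

    def test_bias_shape_mismatch_rejected(self, rng):
        weights = AttentionWeights.random(rng, 32)
        with pytest.raises(ConfigurationError):
            relation_attention(rng.normal(size=(5, 32)),
                               np.ones((4, 4, 8)), weights)

    def test_gradient_reaches_relation_parameters(self, rng):
        """Finite-difference check that W receives gradient through the
        clamp and softmax."""
        params = RelationParams(M=4)
        boxes = random_center_boxes(rng, 3)
        W = Tensor(rng.normal(size=(params.embed_dim, 4)) * 0.01,
                   requires_grad=True)
        A = Tensor(np.full(4, params.eps), requires_grad=True)

        def loss_value(w_data):
            bias = relation_bias_matrix(boxes, boxes, w_data, A.data, params)
            return float(bias.sum())

        bias_t = relation_bias_matrix(boxes, boxes, W, A, params)
        bias_t.sum().backward()
        eps = 1e-6
        i = (3, 1)
        w_plus = W.data.copy()
        w_plus[i] += eps
        w_minus = W.data.copy()
        w_minus[i] -= eps
        expected = (loss_value(w_plus) - loss_value(w_minus)) / (2 * eps)
        assert W.grad is not None and A.grad is not None
        assert W.grad[i] == pytest.approx(expected, abs=1e-4)
        assert np.abs(W.grad).max() > 0
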