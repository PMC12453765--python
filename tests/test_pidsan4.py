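"""PIDSAN4 blocks, attention, loss, and whole-network contracts."""

import numpy as np
import pytest

from oracles import conv2d_ref, maxpool2x2_ref, attention_ref, swish_ref
from pidsan.nn import Tensor, no_grad, swish
from pidsan.pidsan4 import (
    InvertedBottleneck, PatchEmbed, Pidsan4, Pidsan4Config,
    TokenSelfAttention, class_weights, downsample_stage,
    dual_attention_fuse, weighted_cross_entropy,
)


def tiny_config(**kw):
    kw.setdefault("input_size", 32)
    kw.setdefault("stem_channels", (2, 4))
    kw.setdefault("embed_dim", 8)
    kw.setdefault("dropout_rate", 0.0)
    kw.setdefault("seed", 0)
    return Pidsan4Config(**kw)


class TestSwish:
    def test_values(self):
        x = Tensor(np.array([0.0, 1.0, 4.0]))
        np.testing.assert_allclose(swish(x).data, [0.0, 0.7310586, 3.9280552],
                                   atol=1e-6)


class TestInvertedBottleneck:
    def test_zero_projection_is_identity(self, rng):
        block = InvertedBottleneck(4, rng)
        for branch in block.branches:
            branch[4].weight.data[:] = 0.0
            branch[4].bias.data[:] = 0.0
        x = Tensor(rng.standard_normal((2, 4, 6, 6)))
        np.testing.assert_allclose(block(x).data, x.data)

    def test_shape_preserved(self, rng):
        block = InvertedBottleneck(8, rng)
        out = block(Tensor(rng.standard_normal((1, 8, 12, 12))))
        assert out.shape == (1, 8, 12, 12)

    def test_channel_mismatch_rejected(self, rng):
        block = InvertedBottleneck(4, rng)
        with pytest.raises(ValueError, match="channel"):
            block(Tensor(rng.standard_normal((1, 3, 6, 6))))

    def test_matches_bruteforce_convolution_oracle(self, rng):
        """Eval-mode block output equals a nested-loop transcription of
        expand -> BN -> swish -> depthwise -> BN -> swish -> project + skip."""
        block = InvertedBottleneck(3, rng)
        block.eval()
        x = rng.standard_normal((1, 3, 5, 5))
        expected = np.array(x)
        for branch in block.branches:
            expand, bn1, dw, bn2, proj = branch
            h = conv2d_ref(x, expand.weight.data, expand.bias.data)
            h = (h - 0.0) / np.sqrt(1.0 + bn1.eps)        # fresh BN: mean 0, var 1
            h = swish_ref(h)
            h = conv2d_ref(h, dw.weight.data, dw.bias.data, padding=1, groups=3)
            h = h / np.sqrt(1.0 + bn2.eps)
            h = swish_ref(h)
            expected = expected + conv2d_ref(h, proj.weight.data, proj.bias.data)
        np.testing.assert_allclose(block(Tensor(x)).data, expected, atol=1e-10)


class TestDownsample:
    def test_constant_map(self):
        x = Tensor(np.full((1, 2, 4, 4), 0.5))
        out = downsample_stage(x)
        assert out.shape == (1, 2, 2, 2)
        np.testing.assert_allclose(out.data, swish_ref(0.5))

    def test_single_window(self):
        x = Tensor(np.array([[[[1.0, 2.0], [3.0, 4.0]]]]))
        np.testing.assert_allclose(downsample_stage(x).data, [[[[3.9280552]]]],
                                   atol=1e-6)

    def test_matches_pooling_oracle(self, rng):
        x = rng.standard_normal((2, 3, 8, 8))
        np.testing.assert_allclose(downsample_stage(Tensor(x)).data,
                                   swish_ref(maxpool2x2_ref(x)), atol=1e-12)

    def test_degenerate_input_rejected(self):
        with pytest.raises(ValueError, match="pool"):
            downsample_stage(Tensor(np.zeros((1, 1, 1, 1))))


class TestPatchEmbed:
    def test_sixteen_tokens_and_shape(self, rng):
        pe = PatchEmbed(channels=4, embed_dim=8, rng=rng)
        out = pe(Tensor(rng.standard_normal((3, 4, 7, 7))))
        assert out.shape == (3, 16, 8)

    def test_identity_projection_recovers_patches(self, rng):
        pe = PatchEmbed(channels=2, embed_dim=8, rng=rng)
        pe.proj.weight.data = np.eye(8)
        pe.proj.bias.data[:] = 0.0
        x = rng.standard_normal((1, 2, 8, 8))
        tokens = pe(Tensor(x)).data
        # token 0 is the top-left 2x2 patch, flattened as (row, col, channel)
        patch = x[0, :, :2, :2]                         # (C, 2, 2)
        np.testing.assert_allclose(tokens[0, 0], patch.transpose(1, 2, 0).ravel())


class TestTokenSelfAttention:
    def test_single_token_equals_value_projection(self, rng):
        attn = TokenSelfAttention(1, 6, "spatial", rng)
        x = Tensor(rng.standard_normal((1, 1, 6)))
        np.testing.assert_allclose(attn(x).data, attn.v(x).data, atol=1e-12)

    def test_identical_tokens_give_uniform_rows(self, rng):
        attn = TokenSelfAttention(5, 6, "spatial", rng)
        x = Tensor(np.tile(rng.standard_normal(6), (1, 5, 1)))
        weights = attn.attention_weights(x)
        np.testing.assert_allclose(weights, 0.2, atol=1e-12)
        out = attn(x).data
        np.testing.assert_allclose(out - out[:, :1], 0.0, atol=1e-12)

    def test_rows_sum_to_one(self, rng):
        for axis in ("spatial", "channel"):
            attn = TokenSelfAttention(4, 6, axis, rng)
            w = attn.attention_weights(Tensor(rng.standard_normal((2, 4, 6))))
            np.testing.assert_allclose(w.sum(axis=-1), 1.0, atol=1e-6)

    def test_matches_bruteforce_attention_oracle(self, rng):
        attn = TokenSelfAttention(2, 3, "spatial", rng)
        x = rng.standard_normal((2, 3))
        expected = attention_ref(x, attn.q.weight.data, attn.q.bias.data,
                                 attn.k.weight.data, attn.k.bias.data,
                                 attn.v.weight.data, attn.v.bias.data)
        np.testing.assert_allclose(attn(Tensor(x[None])).data[0], expected, atol=1e-10)

    def test_channel_attention_matches_transposed_oracle(self, rng):
        attn = TokenSelfAttention(4, 3, "channel", rng)
        x = rng.standard_normal((4, 3))
        expected = attention_ref(x.T, attn.q.weight.data, attn.q.bias.data,
                                 attn.k.weight.data, attn.k.bias.data,
                                 attn.v.weight.data, attn.v.bias.data).T
        np.testing.assert_allclose(attn(Tensor(x[None])).data[0], expected, atol=1e-10)

    def test_spatial_attention_is_permutation_equivariant(self, rng):
        attn = TokenSelfAttention(6, 5, "spatial", rng)
        x = rng.standard_normal((1, 6, 5))
        perm = rng.permutation(6)
        out = attn(Tensor(x)).data
        out_perm = attn(Tensor(x[:, perm])).data
        np.testing.assert_allclose(out_perm, out[:, perm], atol=1e-10)


class TestDualAttentionFuse:
    def test_zero_weights_return_embedding(self, rng):
        phi = Tensor(rng.standard_normal((1, 4, 3)))
        s = Tensor(rng.standard_normal((1, 4, 3)))
        c = Tensor(rng.standard_normal((1, 4, 3)))
        np.testing.assert_allclose(dual_attention_fuse(phi, s, c, 0.0, 0.0).data,
                                   phi.data)

    def test_linearity_in_spatial_term(self, rng):
        phi, s, c = (Tensor(rng.standard_normal((2, 4, 3))) for _ in range(3))
        a, b = 0.4, 0.7
        diff = (dual_attention_fuse(phi, s * 2.0, c, a, b).data
                - dual_attention_fuse(phi, s, c, a, b).data)
        np.testing.assert_allclose(diff, a * s.data, atol=1e-12)

    def test_default_initialization_is_half(self):
        model = Pidsan4(tiny_config())
        assert float(model.fuse_alpha.data) == 0.5
        assert float(model.fuse_beta.data) == 0.5

    def test_shape_mismatch_rejected(self, rng):
        with pytest.raises(ValueError, match="shape"):
            dual_attention_fuse(Tensor(np.zeros((1, 4, 3))),
                                Tensor(np.zeros((1, 4, 3))),
                                Tensor(np.zeros((1, 3, 3))), 0.5, 0.5)


class TestForward:
    def test_probabilities_and_batch_shape(self, rng):
        model = Pidsan4(tiny_config())
        probs = model.predict_proba(rng.random((3, 32, 32, 3)))
        assert probs.shape == (3, 2)
        np.testing.assert_allclose(probs.sum(axis=1), 1.0, atol=1e-6)

    def test_deterministic_with_fixed_weights(self, rng):
        model = Pidsan4(tiny_config())
        x = rng.random((2, 32, 32, 3))
        np.testing.assert_array_equal(model.predict_proba(x), model.predict_proba(x))

    def test_wrong_input_size_rejected(self, rng):
        model = Pidsan4(tiny_config())
        with pytest.raises(ValueError, match="expected input"):
            model.predict_proba(rng.random((1, 48, 48, 3)))

    def test_sixteen_tokens_from_full_size_input(self, rng):
        model = Pidsan4(Pidsan4Config(seed=0))
        model.eval()
        with no_grad():
            x = Tensor(rng.random((1, 3, 224, 224)))
            tokens = model.features(x)
        assert tokens.shape[1] == 16

    def test_describe_counts(self):
        model = Pidsan4(tiny_config())
        d = model.describe()
        assert d["parameters"] == sum(p.data.size for p in model.parameters())
        assert d["leaf_layers"] > 20


class TestClassWeights:
    @pytest.mark.parametrize("counts,expected", [
        ((100, 100), (1.0, 1.0)),
        ((10, 90), (5.0, 0.5555556)),
        ((5531, 5530), (0.99990960, 1.00009042)),
    ])
    def test_inverse_frequency(self, counts, expected):
        np.testing.assert_allclose(class_weights(counts), expected, atol=1e-7)

    def test_zero_count_rejected(self):
        with pytest.raises(ValueError, match="positive"):
            class_weights((10, 0))


class TestWeightedCrossEntropy:
    def test_perfect_prediction_zero_loss(self):
        onehot = np.eye(2)[[0, 1, 0]]
        assert weighted_cross_entropy(onehot, onehot) == 0.0

    def test_uniform_prediction_ln2(self):
        probs = np.full((4, 2), 0.5)
        onehot = np.eye(2)[[0, 1, 0, 1]]
        np.testing.assert_allclose(weighted_cross_entropy(probs, onehot),
                                   np.log(2.0), atol=1e-12)

    def test_weighted_example(self):
        # single sample, true class 0 with weight 2: 2 * (-ln 0.8)
        loss = weighted_cross_entropy(np.array([[0.8, 0.2]]), np.array([[1.0, 0.0]]),
                                      weights=np.array([2.0, 1.0]))
        np.testing.assert_allclose(loss, 0.4462871, atol=1e-7)

    def test_unit_weights_equal_unweighted(self, rng):
        probs = rng.dirichlet(np.ones(2), size=6)
        onehot = np.eye(2)[rng.integers(0, 2, 6)]
        assert weighted_cross_entropy(probs, onehot) == pytest.approx(
            weighted_cross_entropy(probs, onehot, weights=np.ones(2)), abs=1e-14)

    def test_zero_probability_clamped(self):
        loss = weighted_cross_entropy(np.array([[0.0, 1.0]]), np.array([[1.0, 0.0]]))
        assert np.isfinite(loss) and loss > 20


class TestLossGradient:
    def test_matches_finite_differences_on_toy_batch(self, rng):
        """End-to-end loss gradient vs central differences, 3-sample batch."""
        model = Pidsan4(tiny_config())
        model.train()
        x = rng.random((3, 3, 32, 32))
        onehot = np.eye(2)[[0, 1, 1]]

        def loss_value():
            model_probs = model(Tensor(x))
            return float(weighted_cross_entropy(model_probs, onehot).data)

        probs = model(Tensor(x))
        loss = weighted_cross_entropy(probs, onehot)
        model.zero_grad()
        loss.backward()
        eps = 1e-6
        rng_local = np.random.default_rng(1)
        for name, p in model.named_parameters():
            flat_index = rng_local.integers(p.data.size)
            idx = np.unravel_index(flat_index, p.data.shape)
            orig = p.data[idx]
            p.data[idx] = orig + eps
            fp = loss_value()
            p.data[idx] = orig - eps
            fm = loss_value()
            p.data[idx] = orig
            num = (fp - fm) / (2 * eps)
            ana = 0.0 if p.grad is None else p.grad[idx]
            assert ana == pytest.approx(num, rel=1e-4, abs=1e-7), name
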