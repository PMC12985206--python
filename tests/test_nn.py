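"""Autodiff engine and fusion-network components: gradients, masking, attention."""

import numpy as np
import pytest

from pathfuse.nn import CrossAttention, Encoder, FusionNetwork, MaskedLinear, Tensor
from pathfuse.nn.autograd import concatenate


def numeric_grad(fn, x, eps=1e-6):
    g = np.zeros_like(x)
    it = np.nditer(x, flags=["multi_index"])
    for _ in it:
        idx = it.multi_index
        xp, xm = x.copy(), x.copy()
        xp[idx] += eps
        xm[idx] -= eps
        g[idx] = (fn(xp) - fn(xm)) / (2 * eps)
    return g


class TestAutograd:
    @pytest.mark.parametrize(
        "name,expr",
        [
            ("matmul", lambda a, b: (a @ b.swapaxes(0, 1)).sum()),
            ("mul_broadcast", lambda a, b: (a * b[0]).sum()),
            ("div", lambda a, b: (a / (b + 3.0)).sum()),
            ("gelu", lambda a, b: (a.gelu() * b).sum()),
            ("sigmoid", lambda a, b: (a.sigmoid() + b).sum()),
            ("softplus", lambda a, b: a.softplus().sum() + b.sum()),
            ("leaky", lambda a, b: a.leaky_relu(0.01).sum() + b.sum()),
            ("softmax", lambda a, b: (a.softmax(axis=-1) * b).sum()),
            ("mean_axis", lambda a, b: (a.mean(axis=0) * b.mean(axis=0)).sum()),
            ("reshape", lambda a, b: (a.reshape(12) * b.reshape(12)).sum()),
            ("swap", lambda a, b: (a.swapaxes(0, 1) @ b).sum()),
            ("getitem", lambda a, b: (a[1:, :] * b[1:, :]).sum()),
        ],
    )
    def test_gradients_match_numeric(self, name, expr, rng):
        a0 = rng.normal(size=(3, 4))
        b0 = rng.normal(size=(3, 4))

        def value(arr, which):
            args = [Tensor(arr if which == 0 else a0, requires_grad=which == 0),
                    Tensor(arr if which == 1 else b0, requires_grad=which == 1)]
            return float(expr(*args).data)

        a, b = Tensor(a0, requires_grad=True), Tensor(b0, requires_grad=True)
        out = expr(a, b)
        out.backward()
        np.testing.assert_allclose(a.grad, numeric_grad(lambda x: value(x, 0), a0),
                                   rtol=1e-5, atol=1e-7)
        np.testing.assert_allclose(b.grad, numeric_grad(lambda x: value(x, 1), b0),
                                   rtol=1e-5, atol=1e-7)

    def test_concatenate_gradient(self, rng):
        a = Tensor(rng.normal(size=(2, 3)), requires_grad=True)
        b = Tensor(rng.normal(size=(2, 2)), requires_grad=True)
        out = concatenate([a, b], axis=1)
        (out * Tensor(np.arange(10.0).reshape(2, 5))).sum().backward()
        np.testing.assert_allclose(a.grad, [[0, 1, 2], [5, 6, 7]])
        np.testing.assert_allclose(b.grad, [[3, 4], [8, 9]])

    def test_batched_matmul_gradient(self, rng):
        h0 = rng.normal(size=(2, 3, 4))
        w0 = rng.normal(size=(4, 4))
        h = Tensor(h0, requires_grad=True)
        w = Tensor(w0, requires_grad=True)
        ((h @ w) ** 2.0).sum().backward()
        num = numeric_grad(
            lambda x: float(((Tensor(x) @ Tensor(w0)) ** 2.0).sum().data), h0
        )
        np.testing.assert_allclose(h.grad, num, rtol=1e-5, atol=1e-7)


class TestMaskedLinear:
    def test_all_zero_mask_gives_zero_output(self, rng):
        layer = MaskedLinear(np.zeros((4, 3)), rng)
        out = layer(Tensor(rng.normal(size=(2, 4))))
        np.testing.assert_array_equal(out.data, np.zeros((2, 3)))

    def test_leaky_negative_slope(self, rng):
        layer = MaskedLinear(np.ones((1, 1)), rng)
        layer.weight.data[:] = 1.0
        layer.bias.data[:] = 0.0
        out = layer(Tensor(np.array([[-1.0]])))
        assert out.data[0, 0] == pytest.approx(-0.01)

    def test_equals_dense_zeroing_oracle(self, rng):
        mask = (rng.uniform(size=(6, 5)) < 0.5).astype(float)
        layer = MaskedLinear(mask, rng)
        x = rng.normal(size=(3, 6))
        out = layer(Tensor(x), activate=False).data
        dense = x @ (layer.weight.data * mask) + layer.bias.data
        np.testing.assert_allclose(out, dense)

    def test_mask_reapplied_every_forward(self, rng):
        mask = np.eye(3)
        layer = MaskedLinear(mask, rng)
        x = rng.normal(size=(2, 3))
        before = layer(Tensor(x)).data.copy()
        layer.weight.data[0, 1] = 99.0  # masked position
        after = layer(Tensor(x)).data
        np.testing.assert_array_equal(before, after)

    def test_shape_mismatch_error(self, rng):
        layer = MaskedLinear(np.ones((4, 2)), rng)
        with pytest.raises(ValueError, match="input dim"):
            layer(Tensor(np.zeros((1, 5))))

    def test_slope_one_is_affine(self, rng):
        mask = np.ones((3, 2))
        layer = MaskedLinear(mask, rng, slope=1.0)
        x = rng.normal(size=(4, 3))
        np.testing.assert_allclose(
            layer(Tensor(x)).data, x @ (layer.weight.data * mask) + layer.bias.data
        )


class TestEncoder:
    def masks(self):
        return [np.ones((4, 2)), np.ones((2, 1))]

    def test_zero_input_zero_bias_zero_embedding(self, rng):
        enc = Encoder(self.masks(), rng)
        out, acts = enc(Tensor(np.zeros((3, 4))))
        np.testing.assert_array_equal(out.data, np.zeros((3, 1)))
        assert len(acts) == 2

    def test_output_is_scalar_per_sample_on_toy_hierarchy(self, rng):
        enc = Encoder(self.masks(), rng)
        out, _ = enc(Tensor(rng.normal(size=(5, 4))))
        assert out.shape == (5, 1)

    def test_masked_weight_perturbation_invisible(self, rng):
        masks = [np.kron(np.eye(2), np.ones((2, 1))), np.ones((2, 1))]
        enc = Encoder(masks, rng)
        x = rng.normal(size=(3, 4))
        before = enc(Tensor(x))[0].data.copy()
        enc.layers[0].weight.data[0, 1] += 123.0  # masked-out entry
        after = enc(Tensor(x))[0].data
        np.testing.assert_array_equal(before, after)


class TestCrossAttention:
    def test_single_modality_identity_weight(self, rng):
        att = CrossAttention(4, rng)
        h = Tensor(rng.normal(size=(2, 1, 4)))
        out, attn = att(h)
        np.testing.assert_allclose(attn.data, np.ones((2, 1, 1)))
        np.testing.assert_allclose(out.data, (h @ att.wv).data)

    def test_identical_embeddings_uniform_rows(self, rng):
        att = CrossAttention(4, rng)
        e = rng.normal(size=(1, 1, 4))
        h = Tensor(np.tile(e, (2, 3, 1)))
        _, attn = att(h)
        np.testing.assert_allclose(attn.data, np.full((2, 3, 3), 1 / 3), atol=1e-12)

    def test_matches_explicit_loop_oracle(self, rng):
        d, m = 5, 3
        att = CrossAttention(d, rng)
        h0 = rng.normal(size=(2, m, d))
        out, attn = att(Tensor(h0))
        wq, wk, wv = att.wq.data, att.wk.data, att.wv.data
        for b in range(2):
            q, k, v = h0[b] @ wq, h0[b] @ wk, h0[b] @ wv
            scores = q @ k.T / np.sqrt(d)
            a = np.exp(scores - scores.max(axis=1, keepdims=True))
            a = a / a.sum(axis=1, keepdims=True)
            np.testing.assert_allclose(attn.data[b], a, rtol=1e-12)
            np.testing.assert_allclose(out.data[b], a @ v, rtol=1e-12)

    def test_rows_sum_to_one(self, rng):
        att = CrossAttention(3, rng)
        _, attn = att(Tensor(rng.normal(size=(4, 3, 3))))
        np.testing.assert_allclose(attn.data.sum(axis=-1), np.ones((4, 3)))


class TestFusionNetwork:
    def net(self, m=3, seed=0):
        masks = [np.ones((6, 3)), np.ones((3, 2))]
        return FusionNetwork(masks, m, seed=seed)

    def xs(self, rng, m=3, n=4):
        return [Tensor(rng.normal(size=(n, 6))) for _ in range(m)]

    def test_modality_count_mismatch(self, rng):
        with pytest.raises(ValueError, match="modalities"):
            self.net()(self.xs(rng, m=2))

    def test_duplicate_sample_identical_logit(self, rng):
        net = self.net()
        base = [x.data for x in self.xs(rng)]
        dup = [Tensor(np.vstack([x, x[0:1]])) for x in base]
        out = net(dup)
        assert out["logit"].data[0] == pytest.approx(out["logit"].data[-1])

    def test_modality_weights_are_probabilities(self, rng):
        out = self.net()(self.xs(rng))
        w = out["modality_weights"].data
        assert (w >= 0).all()
        np.testing.assert_allclose(w.sum(axis=-1), np.ones(4))

    def test_gate_entries_in_unit_interval(self, rng):
        # range sweep over many random stacked features
        net = self.net()
        for _ in range(20):
            out = net(self.xs(rng, n=25))
            g = out["gate"].data
            assert (g > 0).all() and (g < 1).all()

    def test_batch_of_one_equals_batched(self, rng):
        net = self.net()
        base = [x.data for x in self.xs(rng)]
        full = net([Tensor(x) for x in base])["logit"].data
        singles = [
            net([Tensor(x[i:i + 1]) for x in base])["logit"].data[0] for i in range(4)
        ]
        np.testing.assert_allclose(full, singles, rtol=1e-12)

    def test_mask_noise_invariance_full_network(self, rng):
        net = self.net()
        mask = np.kron(np.eye(3), np.ones((2, 1)))  # block-sparse first layer
        netm = FusionNetwork([mask, np.ones((3, 2))], 3, seed=1)
        base = [x.data[:, :6] for x in self.xs(rng)]
        before = netm([Tensor(x) for x in base])["logit"].data.copy()
        for enc in netm.encoders:
            w = enc.layers[0].weight.data
            w += rng.normal(size=w.shape) * (1 - mask) * 50
        after = netm([Tensor(x) for x in base])["logit"].data
        np.testing.assert_array_equal(before, after)

    def test_residual_path_linearity(self, rng):
        # zeroing one modality's input changes the residual term by exactly
        # (1/m) x that embedding's change
        net = self.net()
        base = [x.data for x in self.xs(rng)]
        out_full = net([Tensor(x) for x in base])
        zeroed = [base[0], base[1], np.zeros_like(base[2])]
        out_zero = net([Tensor(x) for x in zeroed])
        h_full = out_full["embeddings"].data
        h_zero = out_zero["embeddings"].data
        resid_full = h_full.mean(axis=1)
        resid_zero = h_zero.mean(axis=1)
        delta_embedding = h_full[:, 2, :] - h_zero[:, 2, :]
        np.testing.assert_allclose(resid_full - resid_zero, delta_embedding / 3,
                                   rtol=1e-10, atol=1e-12)

    def test_forced_zero_gate_residual_only(self, rng):
        net = self.net()
        net.fusion.b2.data[:] = -1e9  # saturate the sigmoid gate to 0
        net.head_b.data[:] = 0.0
        out = net(self.xs(rng))
        resid = out["embeddings"].data.mean(axis=1)
        expected = resid @ net.head_w.data
        np.testing.assert_allclose(out["logit"].data, expected.ravel(), atol=1e-10)

    def test_state_dict_roundtrip(self, rng):
        net = self.net(seed=5)
        x = self.xs(rng)
        before = net(x)["logit"].data.copy()
        state = net.state_dict()
        other = self.net(seed=9)
        other.load_state_dict(state)
        np.testing.assert_array_equal(other(x)["logit"].data, before)
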