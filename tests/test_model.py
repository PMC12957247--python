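"""Conv_gMLP architecture oracles, gradient checks, and training behavior."""

import numpy as np
import pytest

from eegsev.autodiff import Adam, Tensor
from eegsev.model import ConvGMLP, ModelSpec, train


def _loss_fn(model, X, y, training=True):
    pred = model.forward(X, training=training)
    return ((pred - Tensor(y)) ** 2).mean()


class TestChannelExpand:
    def test_default_dims_shape(self):
        m = ConvGMLP(ModelSpec(num_layers=1))
        out = m.channel_expand(Tensor(np.random.default_rng(0).normal(size=(1, 480))))
        assert out.shape == (1, 64, 480)

    def test_identity_kernels_copy_input(self, rng):
        m = ConvGMLP(ModelSpec(d_feature=10, d_channel=5, num_layers=1,
                               d_ffn=2, norm="none"))
        m.w_expand.data[:] = 1.0
        m.b_expand.data[:] = 0.0
        x = rng.normal(size=(1, 10))
        out = m.channel_expand(Tensor(x)).data
        for k in range(5):
            np.testing.assert_array_equal(out[0, k], x[0])

    def test_rows_equal_scalar_broadcast(self, rng):
        # kernel size 1 on a single input channel: row k = w_k * x + b_k
        m = ConvGMLP(ModelSpec(d_feature=10, d_channel=5, num_layers=1,
                               d_ffn=2, norm="none", seed=7))
        x = rng.normal(size=(2, 10))
        out = m.channel_expand(Tensor(x)).data
        for b in range(2):
            for k in range(5):
                np.testing.assert_allclose(
                    out[b, k], m.w_expand.data[k] * x[b] + m.b_expand.data[k],
                    atol=1e-14)


class TestSpatialGatingUnit:
    def test_zero_init_identity_passes_u_stream(self, toy_model_spec, rng):
        # W = 0, b = 1, norm off: the gate is constantly one, so the SGU
        # reduces to its u stream and the block acts as a plain linear layer
        m = ConvGMLP(toy_model_spec)
        blk = m.blocks[0]
        blk.W_sgu.data[:] = 0.0
        blk.b_sgu.data[:] = 1.0
        z = Tensor(rng.normal(size=(2, 6, 6)))  # (B, S, 2*d_ffn)
        out = blk._sgu(z, training=False)
        np.testing.assert_allclose(out.data, z.data[:, :, :3], atol=1e-14)

    def test_width_halves(self, toy_model_spec, rng):
        m = ConvGMLP(toy_model_spec)
        out = m.blocks[0]._sgu(Tensor(rng.normal(size=(1, 6, 6))), False)
        assert out.shape == (1, 6, 3)

    def test_matches_explicit_loop(self, toy_model_spec, rng):
        m = ConvGMLP(toy_model_spec)
        blk = m.blocks[0]
        z = rng.normal(size=(1, 6, 6))
        out = blk._sgu(Tensor(z), training=False).data[0]
        u, v = z[0, :, :3], z[0, :, 3:]
        W, b = blk.W_sgu.data, blk.b_sgu.data
        expected = np.empty((6, 3))
        for s in range(6):
            for c in range(3):
                gate = sum(W[t, s] * v[t, c] for t in range(6)) + b[s]
                expected[s, c] = u[s, c] * gate
        np.testing.assert_allclose(out, expected, atol=1e-12)


class TestBlock:
    def test_residual_preserves_shape(self, toy_model_spec, rng):
        m = ConvGMLP(toy_model_spec)
        x = Tensor(rng.normal(size=(2, 6, 4)))
        out = m.blocks[0](x, training=False)
        assert out.shape == x.shape

    def test_zeroed_branch_is_pure_shortcut(self, toy_model_spec, rng):
        m = ConvGMLP(toy_model_spec)
        blk = m.blocks[0]
        blk.U.data[:] = 0.0
        blk.bU.data[:] = 0.0
        blk.V.data[:] = 0.0
        blk.bV.data[:] = 0.0
        x = rng.normal(size=(2, 6, 4))
        out = blk(Tensor(x), training=False)
        np.testing.assert_allclose(out.data, x, atol=1e-14)


class TestHead:
    def test_constant_input_closed_form(self, toy_model_spec):
        m = ConvGMLP(toy_model_spec)
        for blk in m.blocks:  # isolate the head: zero every block branch
            blk.U.data[:] = 0.0
            blk.bU.data[:] = 0.0
            blk.V.data[:] = 0.0
            blk.bV.data[:] = 0.0
        c = 1.7
        m.w_expand.data[:] = 0.0
        m.b_expand.data[:] = c  # activation map constant c
        out = m.forward(np.zeros((1, 6)), training=False)
        expected = c * m.w_head.data.sum() + m.b_head.data[0]
        assert out.data[0] == pytest.approx(expected, abs=1e-12)

    def test_zero_head_weights_output_bias(self, toy_model_spec, rng):
        m = ConvGMLP(toy_model_spec)
        m.w_head.data[:] = 0.0
        m.b_head.data[:] = -2.5
        out = m.forward(rng.normal(size=(4, 6)), training=False)
        np.testing.assert_allclose(out.data, -2.5, atol=1e-12)

    def test_pool_then_affine_matches_direct_arithmetic(self, toy_model_spec,
                                                        rng):
        m = ConvGMLP(toy_model_spec)
        x = rng.normal(size=(3, 6))
        out = m.forward(x, training=False).data
        # straight-line recomputation
        a = (x[:, None, :] * m.w_expand.data[None, :, None]
             + m.b_expand.data[None, :, None])
        h = np.transpose(a, (0, 2, 1))
        for blk in m.blocks:
            hn = h
            z = hn @ blk.U.data + blk.bU.data
            from scipy.special import erf
            z = z * 0.5 * (1 + erf(z / np.sqrt(2)))
            u, v = z[:, :, :3], z[:, :, 3:]
            gate = np.einsum("ts,btc->bsc", blk.W_sgu.data, v) \
                + blk.b_sgu.data[None, :, None]
            h = (u * gate) @ blk.V.data + blk.bV.data + h
        expected = h.mean(axis=1) @ m.w_head.data + m.b_head.data[0]
        np.testing.assert_allclose(out, expected, atol=1e-10)


class TestForward:
    def test_batch_of_inputs_gives_batch_of_scalars(self, toy_model_spec, rng):
        m = ConvGMLP(toy_model_spec)
        out = m.forward(rng.normal(size=(7, 6)))
        assert out.shape == (7,)

    def test_batching_consistent_with_single_samples(self, toy_model_spec, rng):
        m = ConvGMLP(toy_model_spec)
        X = rng.normal(size=(4, 6))
        batched = m.predict(X)
        singles = np.array([m.predict(X[i:i + 1])[0] for i in range(4)])
        np.testing.assert_allclose(batched, singles, atol=1e-12)

    def test_variants_are_wired_differently(self, rng):
        X = rng.normal(size=(3, 6))
        outs = {}
        for variant in ("CS", "SC"):
            spec = ModelSpec(d_feature=6, d_channel=4, num_layers=1, d_ffn=3,
                             norm="none", variant=variant, seed=5)
            outs[variant] = ConvGMLP(spec).forward(X).data
        assert not np.allclose(outs["CS"], outs["SC"])

    def test_invalid_feature_width_rejected(self, toy_model_spec, rng):
        with pytest.raises(ValueError):
            ConvGMLP(toy_model_spec).forward(rng.normal(size=(1, 7)))


@pytest.mark.parametrize("norm", ["none", "layer", "batch"])
@pytest.mark.parametrize("variant", ["CS", "SC"])
def test_all_parameter_gradients_match_finite_differences(norm, variant, rng):
    spec = ModelSpec(d_feature=5, d_channel=4, num_layers=2, d_ffn=3,
                     norm=norm, variant=variant, seed=2)
    m = ConvGMLP(spec)
    X = rng.normal(size=(6, 5))
    y = rng.normal(size=6)

    def loss_value():
        # batch statistics are recomputed per call in training mode, so the
        # loss is a pure function of parameters (running stats unused)
        return float(_loss_fn(m, X, y, training=True).data)

    loss = _loss_fn(m, X, y, training=True)
    for p in m.parameters():
        p.grad = None
    loss.backward()
    h = 1e-6
    for p in m.parameters():
        flat = p.data.reshape(-1)
        gflat = p.grad.reshape(-1)
        for i in np.linspace(0, flat.size - 1, min(4, flat.size)).astype(int):
            old = flat[i]
            flat[i] = old + h
            lp = loss_value()
            flat[i] = old - h
            lm = loss_value()
            flat[i] = old
            fd = (lp - lm) / (2 * h)
            # 1e-4 relative with an absolute floor of 1e-8 (central-difference
            # rounding noise dominates for near-zero gradients)
            denom = max(abs(fd), abs(gflat[i]), 1e-4)
            assert abs(gflat[i] - fd) / denom < 1e-4


class TestTraining:
    def test_overfits_toy_dataset(self, rng):
        # capacity check: 2000 full-batch steps drive training MSE to ~0
        X = rng.uniform(0, 1, size=(32, 20))
        y = X[:, 0] * 10 + X[:, 3] * 5
        spec = ModelSpec(d_feature=20, d_channel=8, num_layers=2, d_ffn=16,
                         norm="none", seed=0)
        m = ConvGMLP(spec)
        m.b_head.data[:] = y.mean()
        opt = Adam(m.parameters(), lr=1e-2)
        for _ in range(2000):
            loss = _loss_fn(m, X, y)
            opt.zero_grad()
            loss.backward()
            opt.step()
        assert float(loss.data) < 1e-2

    def test_constant_labels_learn_constant_predictor(self, rng):
        X = rng.uniform(0, 1, size=(20, 8))
        y = np.full(20, 7.0)
        spec = ModelSpec(d_feature=8, d_channel=4, num_layers=1, d_ffn=4,
                         norm="none", seed=0, max_epochs=30, patience=30,
                         learning_rate=1e-2, batch_size=8)
        m, log = train(X, y, spec)
        assert min(log.val_mae) < 0.2

    def test_training_is_deterministic(self, rng):
        X = rng.uniform(0, 1, size=(16, 8))
        y = rng.uniform(0, 56, size=16)
        spec = ModelSpec(d_feature=8, d_channel=4, num_layers=1, d_ffn=4,
                         norm="batch", seed=9, max_epochs=5, patience=5,
                         batch_size=8)
        m1, _ = train(X, y, spec)
        m2, _ = train(X, y, spec)
        for p1, p2 in zip(m1.parameters(), m2.parameters()):
            np.testing.assert_array_equal(p1.data, p2.data)

    def test_grouped_validation_split_respects_subjects(self, rng):
        from eegsev.model import _val_split
        groups = np.repeat([f"s{i}" for i in range(10)], 3)
        tr, val = _val_split(30, groups, 0.1, np.random.default_rng(0))
        val_subjects = set(groups[val])
        train_subjects = set(groups[tr])
        assert val_subjects.isdisjoint(train_subjects)

    def test_too_few_samples_rejected(self):
        with pytest.raises(ValueError):
            train(np.zeros((1, 4)), np.zeros(1),
                  ModelSpec(d_feature=4, d_channel=2, num_layers=1, d_ffn=2))
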