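"""Cross-branch attention network: primitive ops, composition, gradients,
and the receptive-field calculator."""

import numpy as np
import pytest

from decban import network as nw
from decban.errors import ConfigError, ShapeError


def small_config(**kw):
    defaults = dict(input_dim=5, kernel_sizes=(3, 5, 7), layers_per_branch=2,
                    filters_per_layer=6, max_words=30, seed=0)
    defaults.update(kw)
    return nw.ModelConfig(**defaults)


class TestInit:
    def test_seed_determinism_bit_identical(self):
        m1 = nw.init_model(small_config(seed=1))
        m2 = nw.init_model(small_config(seed=1))
        assert m1.params.keys() == m2.params.keys()
        for k in m1.params:
            assert np.array_equal(m1.params[k], m2.params[k])

    def test_three_branches_and_per_layer_attention(self):
        model = nw.init_model(small_config(layers_per_branch=3, max_words=40))
        conv_keys = [k for k in model.params if k.startswith("conv")]
        attn_keys = [k for k in model.params if k.startswith("attn")]
        assert len(conv_keys) == 3 * 3 * 2  # branches x layers x (W, b)
        assert len(attn_keys) == 3  # one attention vector per layer

    def test_kernel_shapes_follow_config(self):
        model = nw.init_model(small_config())
        for j, k in enumerate((3, 5, 7)):
            assert model.params[f"conv{j}_0_W"].shape == (6, 5, k)

    def test_max_words_too_small_rejected(self):
        with pytest.raises(ConfigError, match="receptive field"):
            small_config(max_words=10)  # deepest RF = 1 + 2*6 = 13

    def test_even_kernel_rejected(self):
        with pytest.raises(ConfigError):
            small_config(kernel_sizes=(3, 4, 7))


class TestBranchLayer:
    def test_zero_weights_relu_gives_zero(self):
        x = np.random.default_rng(0).normal(size=(2, 3, 10)).astype(np.float32)
        out = nw.branch_layer(x, np.zeros((4, 3, 3), np.float32),
                              np.zeros(4, np.float32), "relu")
        assert out.shape == (2, 4, 8)
        assert np.all(out == 0)

    def test_identity_kernel_shifts_input(self):
        x = np.arange(10, dtype=np.float32).reshape(1, 1, 10)
        W = np.zeros((1, 1, 3), np.float32)
        W[0, 0, 1] = 1.0  # centered single 1
        out = nw.branch_layer(x, W, np.zeros(1, np.float32), "identity")
        np.testing.assert_array_equal(out[0, 0], x[0, 0, 1:9])

    def test_valid_width_formula(self):
        x = np.zeros((1, 2, 10), np.float32)
        out = nw.branch_layer(x, np.zeros((3, 2, 3), np.float32),
                              np.zeros(3, np.float32))
        assert out.shape[2] == 8  # 10 - 3 + 1

    def test_narrow_input_raises(self):
        with pytest.raises(ShapeError):
            nw.branch_layer(np.zeros((1, 2, 2), np.float32),
                            np.zeros((3, 2, 3), np.float32),
                            np.zeros(3, np.float32))

    def test_agrees_with_nested_loop_oracle(self):
        """im2col/GEMM path matches a direct nested-loop cross-correlation."""
        rng = np.random.default_rng(3)
        x = rng.normal(size=(2, 5, 20)).astype(np.float32)
        W = rng.normal(size=(4, 5, 3)).astype(np.float32)
        b = rng.normal(size=4).astype(np.float32)
        out = nw.branch_layer(x, W, b, "identity")
        oracle = np.zeros((2, 4, 18))
        for s in range(2):
            for f in range(4):
                for t in range(18):
                    acc = b[f]
                    for c in range(5):
                        for u in range(3):
                            acc += W[f, c, u] * x[s, c, t + u]
                    oracle[s, f, t] = acc
        np.testing.assert_allclose(out, oracle, atol=1e-5)


class TestPool:
    def test_constant_map(self):
        x = np.full((1, 3, 7), 2.5, np.float32)
        np.testing.assert_array_equal(nw.pool(x), np.full((1, 3), 2.5))

    def test_spike_position_invariant(self):
        for pos in (0, 3, 6):
            x = np.zeros((1, 1, 7), np.float32)
            x[0, 0, pos] = 9.0
            assert nw.pool(x)[0, 0] == 9.0

    def test_padding_artifact_and_masked_variant(self):
        # all-negative features with a zero-padded tail: the unmasked pool
        # returns the padding's 0; the masked pool the true max
        x = np.full((1, 2, 10), -1.0, np.float32)
        x[0, :, 6:] = 0.0  # padding columns
        assert np.all(nw.pool(x) == 0.0)
        masked = nw.pool(x, lengths=np.array([6]))
        assert np.all(masked == -1.0)


class TestAttentionFuse:
    def test_identical_vectors_collapse(self):
        v = np.arange(5.0)[None]
        rng = np.random.default_rng(0)
        fused, a = nw.attention_fuse(v, v, v, rng.normal(size=5))
        np.testing.assert_allclose(fused, v, atol=1e-6)
        np.testing.assert_allclose(a.sum(), 1.0, atol=1e-6)

    def test_zero_weights_give_uniform_attention(self):
        ys = [np.array([[1.0, 2.0]]), np.array([[3.0, 4.0]]),
              np.array([[5.0, 6.0]])]
        fused, a = nw.attention_fuse(*ys, np.zeros(2))
        np.testing.assert_allclose(a, [[1 / 3] * 3])
        np.testing.assert_allclose(fused, np.mean(ys, axis=0))

    def test_shape_mismatch(self):
        with pytest.raises(ShapeError):
            nw.attention_fuse(np.ones((1, 3)), np.ones((1, 3)),
                              np.ones((1, 4)), np.ones(3))

    def test_softmax_shift_invariance(self):
        # adding a constant to all scores must not change the weights; with
        # the identity activation the scores are linear, so shift the input
        ys = [np.array([[1.0, -2.0, 0.5]]), np.array([[0.0, 1.0, 2.0]]),
              np.array([[-1.0, 0.0, 1.0]])]
        w = np.array([0.3, -0.2, 0.5])
        _, a1 = nw.attention_fuse(*ys, w, activation="identity")
        delta = 10.0 * w / (w @ w)  # adds exactly 10 to every score
        _, a2 = nw.attention_fuse(*(y + delta for y in ys), w,
                                  activation="identity")
        np.testing.assert_allclose(a1, a2, atol=1e-6)


class TestHeadAndFusion:
    def test_fuse_levels_order_and_length(self):
        a, b, c = (np.full((1, 4), v) for v in (1.0, 2.0, 3.0))
        out = nw.fuse_levels(a, b, c)
        assert out.shape == (1, 12)
        np.testing.assert_array_equal(out[0, :4], 1.0)
        np.testing.assert_array_equal(out[0, 8:], 3.0)

    def test_classify_symmetric_logits(self):
        probs = nw.classify(np.ones((1, 4)), np.zeros((2, 4)), np.zeros(2))
        np.testing.assert_allclose(probs, [[0.5, 0.5]])

    def test_classify_strong_bias(self):
        probs = nw.classify(np.ones((1, 4)), np.zeros((2, 4)),
                            np.array([10.0, -10.0]))
        assert probs[0, 0] > 0.999

    def test_classify_rows_sum_to_one(self):
        rng = np.random.default_rng(0)
        probs = nw.classify(rng.normal(size=(5, 4)),
                            rng.normal(size=(2, 4)), rng.normal(size=2))
        np.testing.assert_allclose(probs.sum(axis=1), 1.0, atol=1e-6)


class TestForward:
    def test_shapes_and_determinism(self):
        model = nw.init_model(small_config())
        rng = np.random.default_rng(1)
        x = rng.normal(size=(1, 5, 30)).astype(np.float32)
        batch = np.concatenate([x, x], axis=0)
        tr = nw.forward(model, batch)
        assert tr.probs.shape == (2, 2)
        np.testing.assert_array_equal(tr.probs[0], tr.probs[1])
        np.testing.assert_allclose(tr.probs.sum(axis=1), 1.0, atol=1e-6)
        for a in tr.attention_weights:
            assert np.all(a >= 0)
            np.testing.assert_allclose(a.sum(axis=1), 1.0, atol=1e-6)

    def test_zero_model_on_zero_input_is_uninformative(self):
        model = nw.init_model(small_config())
        for k in model.params:
            model.params[k][:] = 0
        tr = nw.forward(model, np.zeros((3, 5, 30), np.float32))
        np.testing.assert_allclose(tr.probs, 0.5)

    def test_gradients_match_finite_differences(self):
        model = nw.init_model(small_config(seed=5))
        model.params = {k: v.astype(np.float64) for k, v in model.params.items()}
        rng = np.random.default_rng(2)
        x = rng.normal(size=(3, 5, 30)).astype(np.float64)
        y = np.array([0, 1, 0])
        tr = nw.forward(model, x)
        grads = nw.backward(model, tr, y)
        eps = 1e-6
        for key in ("conv0_0_W", "conv2_1_b", "attn0_w", "attn1_w", "fc_W",
                    "fc_b"):
            flat = model.params[key].ravel()
            for i in rng.choice(flat.size, size=min(4, flat.size),
                                replace=False):
                orig = flat[i]
                flat[i] = orig + eps
                lp = nw.cross_entropy(nw.forward(model, x).probs, y)
                flat[i] = orig - eps
                lm = nw.cross_entropy(nw.forward(model, x).probs, y)
                flat[i] = orig
                num = (lp - lm) / (2 * eps)
                ana = grads[key].ravel()[i]
                assert ana == pytest.approx(num, rel=1e-4, abs=1e-8), key


class TestReceptiveField:
    @pytest.mark.parametrize(
        "kernel,layer,expected",
        [(3, 1, 3), (3, 2, 5), (5, 1, 5), (5, 2, 9), (7, 3, 19), (1, 4, 1)],
    )
    def test_closed_form(self, kernel, layer, expected):
        assert nw.receptive_field(kernel, layer) == expected

    @pytest.mark.parametrize("kernel,layers", [(3, 2), (5, 2), (7, 3)])
    def test_empirical_perturbation_probe(self, kernel, layers):
        """Perturbing one input column changes layer-n outputs only at
        positions whose analytic receptive field covers that column."""
        rng = np.random.default_rng(0)
        C, M = 3, 40
        ws = [rng.uniform(0.5, 1.0, size=(4, C, kernel)).astype(np.float32)]
        ws += [rng.uniform(0.5, 1.0, size=(4, 4, kernel)).astype(np.float32)
               for _ in range(layers - 1)]
        bs = [np.zeros(4, np.float32) for _ in range(layers)]

        def run(x):
            for W, b in zip(ws, bs):
                x = nw.branch_layer(x, W, b, "relu")
            return x

        base_in = rng.uniform(0.1, 1.0, size=(1, C, M)).astype(np.float32)
        base_out = run(base_in)
        col = 17
        pert = base_in.copy()
        pert[0, :, col] += 1.0
        diff = np.abs(run(pert) - base_out).sum(axis=1)[0]
        changed = np.nonzero(diff > 1e-6)[0]
        rf = nw.receptive_field(kernel, layers)
        expected = np.arange(max(0, col - rf + 1), min(base_out.shape[2], col + 1))
        # all-positive weights and inputs: the change reaches exactly the
        # analytic span
        np.testing.assert_array_equal(changed, expected)


class TestCheckpoint:
    def test_round_trip(self, tmp_path):
        model = nw.init_model(small_config(seed=9))
        path = tmp_path / "model.npz"
        nw.save_model(model, path)
        back = nw.load_model(path)
        assert back.config == model.config
        for k in model.params:
            assert np.array_equal(back.params[k], model.params[k])

    def test_version_mismatch_refused(self, tmp_path, monkeypatch):
        model = nw.init_model(small_config())
        path = tmp_path / "model.npz"
        monkeypatch.setattr(nw, "CHECKPOINT_FORMAT_VERSION", 99)
        nw.save_model(model, path)
        monkeypatch.undo()
        with pytest.raises(ConfigError, match="version"):
            nw.load_model(path)
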