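import math

import numpy as np
import pytest

from mindrisk import network as nw
from mindrisk.autodiff import Tensor, parameter
from mindrisk.network import (
    ModelConfig,
    canonical_positional_encoding,
    forward,
    init_params,
    loss_fn,
    param_count,
    positional_addend,
)

TINY = dict(
    d_token=8, n_heads=2, n_layers=1, ffn_dim=8, lstm_units=6, attention_dim=4,
    caal_heads=2, dropout=0.0, seed=3,
)


def tiny_config(**kw):
    return ModelConfig(**{**TINY, **kw})


class TestConfig:
    def test_head_divisibility(self):
        with pytest.raises(ValueError, match="divisible"):
            ModelConfig(d_token=30, n_heads=4)

    def test_even_width_required(self):
        with pytest.raises(ValueError, match="even"):
            ModelConfig(d_token=31, n_heads=1)

    def test_off_grid_flags_small_widths(self):
        cfg = tiny_config()
        assert "ffn_dim" in cfg.off_grid()
        on_grid = ModelConfig(
            d_token=32, n_heads=4, n_layers=2, ffn_dim=256, lstm_units=64,
            attention_dim=32, caal_heads=2, fusion="concat", dropout=0.1,
            lambda_xai=0.1, learning_rate=1e-4, batch_size=64,
        )
        assert on_grid.off_grid() == []


class TestTokenize:
    def test_zero_input_zero_bias_gives_zero_tokens(self):
        cfg = tiny_config()
        params = init_params(cfg, "caal")
        params["b_tok"].data[:] = 0.0
        tokens = nw.tokenize(Tensor(np.zeros((1, 10))), params)
        np.testing.assert_allclose(tokens.data, 0.0)

    def test_per_feature_locality(self):
        cfg = tiny_config()
        params = init_params(cfg, "caal")
        params["b_tok"].data[:] = 0.0
        x = np.ones((1, 10))
        x2 = x.copy()
        x2[0, 3] = 2.0
        t1 = nw.tokenize(Tensor(x), params).data
        t2 = nw.tokenize(Tensor(x2), params).data
        np.testing.assert_allclose(t2[0, 3], 2 * t1[0, 3])
        np.testing.assert_allclose(np.delete(t2, 3, axis=1), np.delete(t1, 3, axis=1))

    def test_shape(self):
        cfg = ModelConfig(d_token=32, n_heads=4)
        params = init_params(cfg, "caal")
        tokens = nw.tokenize(Tensor(np.zeros((5, 10))), params)
        assert tokens.shape == (5, 10, 32)


class TestFeatureAttention:
    def test_zero_query_key_gives_uniform_attention(self):
        cfg = tiny_config()
        params = init_params(cfg, "caal")
        for layer in range(cfg.n_layers):
            params[f"W_Q_{layer}"].data[:] = 0.0
            params[f"W_K_{layer}"].data[:] = 0.0
        tokens = nw.tokenize(Tensor(np.random.default_rng(0).normal(size=(2, 10))), params)
        _, weights = nw.feature_attention(tokens, params, cfg)
        for w in weights:
            np.testing.assert_allclose(w, 1.0 / 10, atol=1e-12)

    def test_identical_tokens_give_uniform_attention(self):
        cfg = tiny_config()
        params = init_params(cfg, "caal")
        tokens = nw.tokenize(Tensor(np.full((1, 10), 0.7)), params)
        # make every token identical (same tokenizer row)
        params["W_tok"].data[:] = params["W_tok"].data[0]
        params["b_tok"].data[:] = params["b_tok"].data[0]
        tokens = nw.tokenize(Tensor(np.full((1, 10), 0.7)), params)
        _, weights = nw.feature_attention(tokens, params, cfg)
        np.testing.assert_allclose(weights[0], 1.0 / 10, atol=1e-9)

    def test_rows_stochastic(self):
        cfg = tiny_config()
        params = init_params(cfg, "caal")
        tokens = nw.tokenize(
            Tensor(np.random.default_rng(1).normal(size=(3, 10))), params
        )
        _, weights = nw.feature_attention(tokens, params, cfg)
        for w in weights:
            np.testing.assert_allclose(w.sum(axis=-1), 1.0, atol=1e-6)


class TestPositionalEncoding:
    def test_exact_form(self):
        pe = positional_addend(10, 32)
        i = np.arange(10)
        np.testing.assert_array_equal(pe, np.sin(i / 10.0 ** (2 * i / 32)))

    def test_index_zero_unchanged(self):
        assert positional_addend(10, 8)[0] == 0.0

    def test_scalar_value_i1_d4(self):
        assert positional_addend(2, 4)[1] == pytest.approx(
            math.sin(1 / 10**0.5), abs=1e-12
        )
        assert positional_addend(2, 4)[1] == pytest.approx(0.31098, abs=1e-5)

    def test_not_idempotent(self):
        pe = positional_addend(10, 8)
        assert not np.allclose(pe + pe, pe)

    def test_canonical_pairs(self):
        pe = canonical_positional_encoding(10, 8)
        assert pe.shape == (10, 8)
        np.testing.assert_allclose(pe[0, 0::2], 0.0)
        np.testing.assert_allclose(pe[0, 1::2], 1.0)


class TestLSTM:
    def test_zero_input_zero_bias_fixed_point(self):
        cfg = tiny_config()
        params = init_params(cfg, "lstm")  # scalar-sequence baseline
        params["b_lstm"].data[:] = 0.0
        x = Tensor(np.zeros((2, 10, 1)))
        hs = nw.lstm_sequence(x, params, cfg.lstm_units)
        np.testing.assert_allclose(hs[-1].data, 0.0)

    def test_hand_unrolled_gate_oracle(self):
        # 1 unit, 1-wide input, 2 steps, all weights fixed scalars
        u = 1
        wx = 0.5 * np.ones((1, 4))
        wh = 0.25 * np.ones((1, 4))
        b = 0.1 * np.ones(4)
        params = {
            "W_lstm_x": parameter(wx),
            "W_lstm_h": parameter(wh),
            "b_lstm": parameter(b),
        }
        x = np.array([[[1.0], [-1.0]]])  # (B=1, T=2, d=1)
        hs = nw.lstm_sequence(Tensor(x), params, u)

        def sig(v):
            return 1.0 / (1.0 + math.exp(-v))

        h = c = 0.0
        for x_t in (1.0, -1.0):
            zi = x_t * 0.5 + h * 0.25 + 0.1
            i, f, g, o = sig(zi), sig(zi), math.tanh(zi), sig(zi)
            c = f * c + i * g
            h = o * math.tanh(c)
        assert hs[-1].data[0, 0] == pytest.approx(h, abs=1e-12)

    def test_order_sensitivity(self):
        cfg = tiny_config()
        params = init_params(cfg, "lstm")
        rng = np.random.default_rng(2)
        x = rng.normal(size=(1, 10, 1))
        h1 = nw.lstm_sequence(Tensor(x), params, cfg.lstm_units)[-1].data
        h2 = nw.lstm_sequence(Tensor(x[:, ::-1]), params, cfg.lstm_units)[-1].data
        assert not np.allclose(h1, h2)


class TestCaalAndClassifier:
    def test_equal_scores_give_uniform_attribution(self):
        cfg = tiny_config()
        params = init_params(cfg, "caal")
        for head in range(cfg.caal_heads):
            params[f"W_L_{head}"].data[:] = 0.0  # all scores 0 -> uniform
        rng = np.random.default_rng(0)
        A_T = Tensor(rng.normal(size=(2, 10, cfg.d_token)))
        h_T = Tensor(rng.normal(size=(2, cfg.lstm_units)))
        A_C, _ = nw.caal_fuse(A_T, h_T, params, cfg)
        np.testing.assert_allclose(A_C.data, 0.1, atol=1e-12)

    def test_dominant_logit_saturates(self):
        # +30 on one logit pushes softmax mass > 0.999 onto it
        logits = np.zeros((1, 10))
        logits[0, 4] = 30.0
        s = Tensor(logits).softmax(axis=-1)
        assert s.data[0, 4] > 0.999

    def test_heads_sum_to_one(self):
        cfg = tiny_config()
        params = init_params(cfg, "caal")
        rng = np.random.default_rng(1)
        A_C, fused = nw.caal_fuse(
            Tensor(rng.normal(size=(4, 10, cfg.d_token))),
            Tensor(rng.normal(size=(4, cfg.lstm_units))),
            params,
            cfg,
        )
        np.testing.assert_allclose(A_C.data.sum(axis=-1), 1.0, atol=1e-6)

    def test_fusion_modes_change_width(self):
        for fusion in ("add", "concat"):
            cfg = tiny_config(fusion=fusion)
            params = init_params(cfg, "caal")
            rng = np.random.default_rng(0)
            _, fused = nw.caal_fuse(
                Tensor(rng.normal(size=(1, 10, cfg.d_token))),
                Tensor(rng.normal(size=(1, cfg.lstm_units))),
                params,
                cfg,
            )
            expected = cfg.attention_dim * cfg.caal_heads
            if fusion == "concat":
                expected += cfg.lstm_units
            assert fused.shape == (1, expected)

    def test_zero_logits_uniform_probabilities(self):
        cfg = tiny_config()
        params = init_params(cfg, "caal")
        params["W_O"].data[:] = 0.0
        params["b_O"].data[:] = 0.0
        y = nw.classify(Tensor(np.random.default_rng(0).normal(size=(3, params["W_O"].shape[0]))), params)
        np.testing.assert_allclose(y.data, 1.0 / 3, atol=1e-12)


class TestLoss:
    def test_perfect_prediction_zero_loss(self):
        y_hat = Tensor(np.array([[1.0, 0.0, 0.0]]))
        assert float(loss_fn(y_hat, [0], None, 0.0).data) == pytest.approx(0.0, abs=1e-9)

    def test_uniform_prediction_ln3(self):
        y_hat = Tensor(np.full((4, 3), 1 / 3))
        assert float(loss_fn(y_hat, [0, 1, 2, 0], None, 0.0).data) == pytest.approx(
            math.log(3), abs=1e-12
        )

    def test_uniform_attribution_regularizer_value(self):
        # lambda 0.1 with uniform A_C over 10 features adds 0.1*log2(10)
        y_hat = Tensor(np.array([[1.0, 0.0, 0.0]]))
        A_C = Tensor(np.full((1, 2, 10), 0.1))
        val = float(loss_fn(y_hat, [0], A_C, 0.1).data)
        assert val == pytest.approx(0.1 * math.log2(10), abs=1e-9)

    def test_zero_probability_clamped(self):
        y_hat = Tensor(np.array([[0.0, 1.0, 0.0]]))
        val = float(loss_fn(y_hat, [0], None, 0.0).data)
        assert np.isfinite(val) and val == pytest.approx(-math.log(1e-12))


class TestVariants:
    def test_lstm_variant_has_no_transformer_parameters(self):
        params = init_params(tiny_config(), "E1")
        assert not any(k.startswith(("W_Q", "W_K", "W_V", "W_ffn")) for k in params)

    def test_full_model_larger_than_early_fusion(self):
        cfg = tiny_config()
        assert param_count(init_params(cfg, "E6")) > param_count(
            init_params(cfg, "E4")
        )

    @pytest.mark.parametrize("variant", sorted(nw.VARIANTS))
    def test_all_variants_forward(self, variant):
        cfg = tiny_config()
        params = init_params(cfg, variant)
        rng = np.random.default_rng(0)
        trace = forward(rng.normal(size=(7, 10)), params, cfg, variant)
        y = trace["y_hat"].data
        assert y.shape == (7, 3)
        np.testing.assert_allclose(y.sum(axis=1), 1.0, atol=1e-6)
        assert (y >= 0).all()

    def test_unknown_variant_rejected(self):
        with pytest.raises(ValueError, match="unknown variant"):
            init_params(tiny_config(), "E9")


class TestTraining:
    @pytest.fixture(scope="class")
    def toy_data(self):
        rng = np.random.default_rng(11)
        X = rng.normal(size=(120, 10))
        logits = np.stack([X[:, 0] + X[:, 1], np.zeros(120), -X[:, 0] - X[:, 1]], 1)
        y = logits.argmax(axis=1)
        return X, y

    def test_loss_decreases(self, toy_data):
        X, y = toy_data
        cfg = tiny_config(max_epochs=15, learning_rate=5e-3, optimizer="adam")
        _, state = nw.train(X, y, None, None, cfg, "caal")
        assert state.train_loss[-1] < state.train_loss[0]

    def test_seed_reproducibility(self, toy_data):
        X, y = toy_data
        cfg = tiny_config(max_epochs=4, optimizer="adam", learning_rate=5e-3)
        p1, _ = nw.train(X, y, None, None, cfg, "caal")
        p2, _ = nw.train(X, y, None, None, cfg, "caal")
        for k in p1:
            np.testing.assert_array_equal(p1[k].data, p2[k].data)

    def test_sharpness_regularizer_direction(self, toy_data):
        # a strong attribution-entropy penalty must yield sharper A_C
        X, y = toy_data
        ents = {}
        for lam in (0.0, 10.0):
            cfg = tiny_config(
                max_epochs=12, optimizer="adam", learning_rate=5e-3, lambda_xai=lam
            )
            params, _ = nw.train(X, y, None, None, cfg, "caal")
            trace = forward(X, params, cfg, "caal")
            ents[lam] = float(nw.attribution_entropy(trace["A_C"]).data)
        assert ents[10.0] < ents[0.0]


class TestGradientCheck:
    def test_backprop_matches_finite_differences(self):
        cfg = tiny_config()
        params = init_params(cfg, "caal")
        rng = np.random.default_rng(0)
        X = rng.normal(size=(2, 10))
        y = np.array([0, 2])

        def total():
            t = forward(X, params, cfg, "caal")
            return loss_fn(t["y_hat"], y, t["A_C"], cfg.lambda_xai)

        loss = total()
        for p in params.values():
            p.zero_grad()
        loss.backward()
        names = list(params)
        for _ in range(20):
            name = names[rng.integers(len(names))]
            p = params[name]
            flat = p.data.ravel()
            i = rng.integers(flat.size)
            eps = 1e-6
            orig = flat[i]
            flat[i] = orig + eps
            lp = float(total().data)
            flat[i] = orig - eps
            lm = float(total().data)
            flat[i] = orig
            fd = (lp - lm) / (2 * eps)
            an = p.grad.ravel()[i]
            assert abs(fd - an) <= 1e-3 * max(abs(fd), abs(an), 1e-4), name


class TestCheckpoint:
    def test_roundtrip(self, tmp_path):
        cfg = tiny_config()
        params = init_params(cfg, "caal")
        path = tmp_path / "ckpt.npz"
        nw.save_checkpoint(path, params, cfg, "caal", {"note": "x"})
        params2, cfg2, variant, extra = nw.load_checkpoint(path)
        assert variant == "caal" and extra["note"] == "x"
        assert cfg2 == cfg
        for k in params:
            np.testing.assert_array_equal(params[k].data, params2[k].data)
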