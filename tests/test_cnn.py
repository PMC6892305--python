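import itertools

import numpy as np
import pytest

from medrelex.autodiff import Tensor
from medrelex.cnn import (CNNConfig, classify, conv_pool, init_cnn_params,
                          init_linear_params, linear_head, pair_pos_neg,
                          ranking_loss)


def brute_force_conv_pool(hidden, seq_len, filters, biases, windows):
    """Sliding-window dot-product loop reference for one batch item."""
    feats = []
    for w in windows:
        filt, bias = filters[w], biases[w]
        maps = filt.shape[2]
        best = np.full(maps, -np.inf)
        any_valid = False
        for t in range(hidden.shape[0] - w + 1):
            if t + w > seq_len:
                continue
            any_valid = True
            for m in range(maps):
                acc = bias[m]
                for i in range(w):
                    acc += hidden[t + i] @ filt[i, :, m]
                best[m] = max(best[m], max(acc, 0.0))
        feats.extend(best if any_valid else np.maximum(bias, 0.0))
    return np.array(feats)


class TestConvPool:
    def test_zero_states_and_biases_give_zero_features(self):
        cfg = CNNConfig(windows=(3,), maps=4)
        params = init_cnn_params(cfg, hidden=5, n_classes=2, seed=0)
        hidden = Tensor(np.zeros((2, 7, 5)))
        out = conv_pool(hidden, np.ones((2, 7), int), params, cfg)
        assert np.array_equal(out.data, np.zeros((2, 4)))

    def test_matches_loop_oracle_small_case(self):
        cfg = CNNConfig(windows=(3,), maps=2)
        params = init_cnn_params(cfg, hidden=4, n_classes=2, seed=1)
        rng = np.random.default_rng(2)
        hidden = rng.standard_normal((1, 6, 4))
        mask = np.array([[1, 1, 1, 1, 1, 0]])
        out = conv_pool(Tensor(hidden), mask, params, cfg)
        expected = brute_force_conv_pool(
            hidden[0], 5,
            {3: params["cnn/w3_filt"].data}, {3: params["cnn/w3_bias"].data}, (3,))
        assert np.allclose(out.data[0], expected, atol=1e-6)

    @pytest.mark.parametrize("case", range(30))
    def test_matches_oracle_on_integer_weight_configurations(self, case):
        rng = np.random.default_rng(case)
        L = int(rng.integers(3, 9))
        H = int(rng.integers(1, 5))
        windows = tuple(sorted(set(rng.integers(1, 4, size=rng.integers(1, 3)).tolist())))
        cfg = CNNConfig(windows=windows, maps=2)
        params = init_cnn_params(cfg, hidden=H, n_classes=2, seed=case)
        for w in windows:
            params[f"cnn/w{w}_filt"].data = rng.integers(-2, 3, (w, H, 2)).astype(float)
            params[f"cnn/w{w}_bias"].data = rng.integers(-2, 3, 2).astype(float)
        hidden = rng.integers(-2, 3, (1, L, H)).astype(float)
        seq_len = int(rng.integers(1, L + 1))
        mask = (np.arange(L) < seq_len).astype(int)[None, :]
        out = conv_pool(Tensor(hidden), mask, params, cfg)
        expected = brute_force_conv_pool(
            hidden[0], seq_len,
            {w: params[f"cnn/w{w}_filt"].data for w in windows},
            {w: params[f"cnn/w{w}_bias"].data for w in windows}, windows)
        assert np.allclose(out.data[0], expected, atol=1e-6)

    def test_appending_padding_rows_leaves_features_unchanged(self):
        cfg = CNNConfig(windows=(2, 3), maps=3)
        params = init_cnn_params(cfg, hidden=4, n_classes=2, seed=3)
        rng = np.random.default_rng(4)
        real = rng.standard_normal((1, 5, 4))
        padded = np.concatenate([real, rng.standard_normal((1, 3, 4))], axis=1)
        out_real = conv_pool(Tensor(real), np.ones((1, 5), int), params, cfg)
        mask = np.array([[1] * 5 + [0] * 3])
        out_padded = conv_pool(Tensor(padded), mask, params, cfg)
        assert np.allclose(out_real.data, out_padded.data, atol=1e-12)


class TestClassify:
    def test_zero_parameters_give_uniform(self):
        cfg = CNNConfig(windows=(2,), maps=3)
        params = init_cnn_params(cfg, hidden=4, n_classes=5, seed=0)
        params["cnn/fc_w"].data[:] = 0.0
        probs = classify(Tensor(np.ones((4, 3))), params, dropout=0.0)
        assert np.allclose(probs.data, 0.2)

    def test_distributions_normalize(self):
        cfg = CNNConfig(windows=(2,), maps=6)
        params = init_cnn_params(cfg, hidden=4, n_classes=3, seed=1)
        feats = np.random.default_rng(2).standard_normal((1000, 6)) * 5
        probs = classify(Tensor(feats), params, dropout=0.0)
        assert np.allclose(probs.data.sum(axis=1), 1.0, atol=1e-6)

    def test_softmax_shift_invariance(self):
        cfg = CNNConfig(windows=(2,), maps=2)
        params = init_cnn_params(cfg, hidden=4, n_classes=3, seed=1)
        feats = Tensor(np.ones((1, 2)))
        base = classify(feats, params, dropout=0.0).data
        params["cnn/fc_b"].data += 100.0  # constant added to every logit
        shifted = classify(feats, params, dropout=0.0).data
        assert np.allclose(base, shifted, atol=1e-9)


class TestRankingLoss:
    def test_satisfied_margin_is_zero(self):
        assert ranking_loss([1.0] * 5, [0.0] * 5).item() == 0.0

    def test_equal_scores_cost_one_each(self):
        assert ranking_loss([0.4] * 7, [0.4] * 7).item() == pytest.approx(7.0)

    def test_matches_elementwise_loop(self):
        rng = np.random.default_rng(0)
        g_pos, g_neg = rng.random(50), rng.random(50)
        expected = sum(max(0.0, 1.0 - p + n) for p, n in zip(g_pos, g_neg))
        assert ranking_loss(g_pos, g_neg).item() == pytest.approx(expected)

    def test_out_of_range_scores_rejected(self):
        with pytest.raises(ValueError, match="softmax"):
            ranking_loss([1.4], [0.0])

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError, match="pair"):
            ranking_loss([0.5, 0.5], [0.5])

    def test_monotonic_on_grid(self):
        grid = np.linspace(0, 1, 11)
        for gn in grid:
            losses = [ranking_loss([gp], [gn]).item() for gp in grid]
            assert all(a >= b - 1e-12 for a, b in zip(losses, losses[1:]))
        for gp in grid:
            losses = [ranking_loss([gp], [gn]).item() for gn in grid]
            assert all(a <= b + 1e-12 for a, b in zip(losses, losses[1:]))


class TestPairing:
    def test_cycles_shorter_side(self):
        labels = np.array([1, 0, 0, 0, 1])
        pi, ni = pair_pos_neg(labels, np.random.default_rng(0))
        assert len(pi) == len(ni) == 3
        assert set(pi) <= {0, 4} and set(ni) == {1, 2, 3}

    def test_all_pairs_mode(self):
        labels = np.array([1, 1, 0, 0, 0])
        pi, ni = pair_pos_neg(labels, np.random.default_rng(0), all_pairs=True)
        assert sorted(zip(pi, ni)) == sorted(
            (p, n) for p in (0, 1) for n in (2, 3, 4))

    def test_single_class_batch_returns_none(self):
        assert pair_pos_neg(np.array([1, 1]), np.random.default_rng(0)) is None


class TestLinearHead:
    def test_zero_parameters_uniform(self):
        params = init_linear_params(hidden=6, n_classes=4, seed=0)
        params["lin/fc_w"].data[:] = 0.0
        probs = linear_head(Tensor(np.ones((3, 6))), params, dropout=0.0)
        assert np.allclose(probs.data, 0.25)

    def test_agrees_with_classify_on_same_parameters(self):
        rng = np.random.default_rng(1)
        lin = init_linear_params(hidden=4, n_classes=3, seed=2)
        cnn = {"cnn/fc_w": Tensor(lin["lin/fc_w"].data.copy()),
               "cnn/fc_b": Tensor(lin["lin/fc_b"].data.copy())}
        x = Tensor(rng.standard_normal((5, 4)))
        assert np.allclose(linear_head(x, lin, dropout=0.0).data,
                           classify(x, cnn, dropout=0.0).data)

    def test_loss_gradient_reaches_embeddings_when_unfrozen(self, tiny_params):
        from medrelex.encoder import encode_batch, pool_first_token
        rng = np.random.default_rng(3)
        ids = rng.integers(0, 30, (2, 6))
        segs = np.zeros((2, 6), int)
        mask = np.ones((2, 6), int)
        lin = init_linear_params(hidden=8, n_classes=2, seed=4)
        hidden = encode_batch(ids, segs, mask, tiny_params)
        probs = linear_head(pool_first_token(hidden, tiny_params), lin, dropout=0.0)
        loss = -(probs.take_rows(np.arange(2), np.array([0, 1])).log().mean())
        loss.backward()
        g = tiny_params.params["embeddings/token"].grad
        assert g is not None and np.abs(g).max() > 0

        # finite-difference agreement at one coordinate
        table = tiny_params.params["embeddings/token"]
        idx = np.unravel_index(np.argmax(np.abs(g)), g.shape)

        def loss_value():
            h = encode_batch(ids, segs, mask, tiny_params)
            p = linear_head(pool_first_token(h, tiny_params), lin, dropout=0.0)
            return -(p.take_rows(np.arange(2), np.array([0, 1])).log().mean()).item()

        eps = 1e-6
        orig = table.data[idx]
        table.data[idx] = orig + eps
        lp = loss_value()
        table.data[idx] = orig - eps
        lm = loss_value()
        table.data[idx] = orig
        for t in tiny_params.all_tensors():
            t.grad = None  # session fixture: leave no gradient state behind
        assert (lp - lm) / (2 * eps) == pytest.approx(g[idx], rel=1e-4)
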