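import numpy as np
import pytest

from medrelex.autodiff import Tensor
from medrelex.encoder import (EncoderConfig, EncoderParams, PretrainSchedule,
                              _batch_arrays, _layer_norm, count_parameters,
                              embed, encode, encode_batch, encoder_layer,
                              make_nsp_pairs, mask_tokens, pretrain)
from medrelex.synthetic import SynthConfig, generate_pretrain_corpus
from medrelex.wordpiece import SPECIALS, Vocabulary, build_vocab, encode_pair


def small_vocab():
    return Vocabulary(list(SPECIALS) + [f"w{i}" for i in range(25)])


def some_sequence(vocab, max_len=12):
    return encode_pair("w1 w2", "w3 w4 w5 w1", vocab, max_len)


class TestEmbed:
    def test_zero_segment_and_position_gives_token_rows(self, tiny_params):
        vocab = small_vocab()
        seq = some_sequence(vocab)
        tables = tiny_params.tables()
        tables.segment = np.zeros_like(tables.segment)
        tables.position = np.zeros_like(tables.position)
        out = embed(seq, tables)
        assert np.array_equal(out, tables.token[np.asarray(seq.ids)])

    def test_rowwise_sum_matches_loop_oracle(self, tiny_params):
        vocab = small_vocab()
        seq = some_sequence(vocab)
        tables = tiny_params.tables()
        out = embed(seq, tables)
        for i, (tid, sid, pos) in enumerate(zip(seq.ids, seq.segment_ids, seq.positions)):
            expected = np.array([tables.token[tid][j] + tables.segment[sid][j]
                                 + tables.position[pos][j]
                                 for j in range(tables.token.shape[1])])
            assert np.array_equal(out[i], expected)  # additivity is exact

    def test_position_dependence_changes_exactly_swapped_rows(self, tiny_params):
        vocab = small_vocab()
        seq = encode_pair("w1 w1", "w2 w2", vocab, 10)
        tables = tiny_params.tables()
        out = embed(seq, tables)
        # tokens at positions 1 and 2 share id and segment but not position
        assert not np.array_equal(out[1], out[2])
        delta = tables.position[1] - tables.position[2]
        assert np.allclose(out[1] - out[2], delta)

    def test_out_of_range_id_raises(self, tiny_params):
        vocab = small_vocab()
        seq = some_sequence(vocab)
        bad = type(seq)(tokens=seq.tokens, ids=tuple([9999] + list(seq.ids[1:])),
                        segment_ids=seq.segment_ids, positions=seq.positions,
                        mask=seq.mask)
        with pytest.raises(ValueError, match="out of range"):
            embed(bad, tiny_params.tables())


def brute_force_attention(x, mask, p, cfg, prefix="layer0/"):
    """Three-nested-loop softmax(QK'/sqrt(d)) V reference, then the layer tail."""
    B, L, H = x.shape
    A, dh = cfg.n_heads, cfg.head_dim
    gp = lambda n: p[prefix + n].data
    out = np.zeros_like(x)
    for b in range(B):
        q = x[b] @ gp("attn_q_w") + gp("attn_q_b")
        k = x[b] @ gp("attn_k_w") + gp("attn_k_b")
        v = x[b] @ gp("attn_v_w") + gp("attn_v_b")
        ctx = np.zeros((L, H))
        for a in range(A):
            qs, ks, vs = (m[:, a * dh:(a + 1) * dh] for m in (q, k, v))
            for i in range(L):
                scores = np.array([qs[i] @ ks[j] / np.sqrt(dh)
                                   if mask[b, j] else -np.inf for j in range(L)])
                w = np.exp(scores - scores.max())
                w /= w.sum()
                ctx[i, a * dh:(a + 1) * dh] = sum(w[j] * vs[j] for j in range(L))
        out[b] = ctx @ gp("attn_out_w") + gp("attn_out_b")
    return out


class TestEncoderLayer:
    def test_single_unmasked_token_attention_is_one(self, tiny_params, tiny_config):
        B, L, H = 1, 6, tiny_config.hidden
        x = Tensor(np.random.default_rng(0).standard_normal((B, L, H)))
        mask = np.zeros((B, L), int)
        mask[0, 0] = 1
        _, probs = encoder_layer(x, mask, tiny_params, 0, return_attention=True)
        assert np.allclose(probs[0, :, :, 0], 1.0)

    def test_attention_rows_sum_to_one_over_unmasked(self, tiny_params):
        rng = np.random.default_rng(1)
        x = Tensor(rng.standard_normal((2, 8, 8)))
        mask = np.ones((2, 8), int)
        mask[:, 5:] = 0
        _, probs = encoder_layer(x, mask, tiny_params, 0, return_attention=True)
        assert np.allclose(probs.sum(axis=-1), 1.0)
        assert np.allclose(probs[..., 5:], 0.0, atol=1e-12)

    def test_attention_matches_three_loop_oracle(self):
        cfg = EncoderConfig(n_layers=1, hidden=4, n_heads=2, vocab_size=10,
                            max_positions=8, dropout=0.0)
        params = EncoderParams.init(cfg, seed=3)
        # make projections sizable so attention is non-trivial
        for k, t in params.params.items():
            if "attn" in k and k.endswith("_w"):
                t.data *= 20.0
        rng = np.random.default_rng(4)
        x_np = rng.standard_normal((2, 3, 4))
        mask = np.array([[1, 1, 1], [1, 1, 0]])
        oracle_attn = brute_force_attention(x_np, mask, params.params, cfg)
        h1 = _layer_norm(Tensor(x_np) + Tensor(oracle_attn),
                         params.params["layer0/attn_ln_gain"],
                         params.params["layer0/attn_ln_bias"])
        got = encoder_layer(Tensor(x_np), mask, params, 0)
        # compare through the attention sub-layer output (pre-FFN states)
        from medrelex.autodiff import gelu
        ff = gelu(h1 @ params.params["layer0/ffn_w1"] + params.params["layer0/ffn_b1"]) \
            @ params.params["layer0/ffn_w2"] + params.params["layer0/ffn_b2"]
        expected = _layer_norm(h1 + ff, params.params["layer0/ffn_ln_gain"],
                               params.params["layer0/ffn_ln_bias"])
        assert np.allclose(got.data, expected.data, atol=1e-6)

    def test_nonfinite_input_names_layer(self, tiny_params):
        x = Tensor(np.full((1, 4, 8), np.nan))
        with pytest.raises(FloatingPointError, match="layer 1"):
            encoder_layer(x, np.ones((1, 4), int), tiny_params, 1)


class TestEncode:
    def test_zero_layers_is_normalized_embedding(self):
        cfg = EncoderConfig(n_layers=0, hidden=8, n_heads=2, vocab_size=30,
                            max_positions=16, dropout=0.0)
        params = EncoderParams.init(cfg, seed=0)
        vocab = small_vocab()
        seq = some_sequence(vocab)
        raw = embed(seq, params.tables())
        expected = _layer_norm(Tensor(raw[None]),
                               params.params["embeddings/ln_gain"],
                               params.params["embeddings/ln_bias"]).data[0]
        assert np.allclose(encode(seq, params), expected)

    def test_padding_invariance(self, tiny_params):
        vocab = small_vocab()
        short = encode_pair("w1 w2", "w3 w4", vocab, 9)
        long = encode_pair("w1 w2", "w3 w4", vocab, 14)
        out_short = encode(short, tiny_params)
        out_long = encode(long, tiny_params)
        assert np.allclose(out_short[:9], out_long[:9], atol=1e-6)

    def test_evaluation_mode_is_bit_deterministic(self, tiny_params):
        vocab = small_vocab()
        seq = some_sequence(vocab)
        assert np.array_equal(encode(seq, tiny_params), encode(seq, tiny_params))


class TestMaskTokens:
    def test_twenty_maskable_selects_three(self):
        vocab = small_vocab()
        seq = encode_pair(" ".join(["w1"] * 8), " ".join(["w2"] * 12), vocab, 25)
        assert sum(seq.mask) - 3 == 20  # 20 maskable + [CLS] + 2 [SEP]
        batch = mask_tokens(seq, vocab, np.random.default_rng(0))
        assert len(batch.mask_positions) == 3

    def test_minimum_one_selection(self):
        vocab = small_vocab()
        seq = encode_pair("w1", "w2", vocab, 6)
        batch = mask_tokens(seq, vocab, np.random.default_rng(0))
        assert len(batch.mask_positions) == 1

    def test_specials_never_selected(self):
        vocab = small_vocab()
        seq = encode_pair("w1 w2 w3", "w4 w5", vocab, 16)
        special_positions = {i for i, t in enumerate(seq.tokens)
                             if t in ("[CLS]", "[SEP]", "[PAD]")}
        rng = np.random.default_rng(1)
        for _ in range(300):
            batch = mask_tokens(seq, vocab, rng)
            assert not set(batch.mask_positions.tolist()) & special_positions

    def test_all_mask_policy(self):
        vocab = small_vocab()
        seq = encode_pair("w1 w2 w3 w4", "w5 w6 w7 w8 w9 w10", vocab, 20)
        batch = mask_tokens(seq, vocab, np.random.default_rng(2), policy=(1.0, 0.0, 0.0))
        assert all(batch.ids[p] == vocab.token_to_id["[MASK]"]
                   for p in batch.mask_positions)

    def test_originals_recorded(self):
        vocab = small_vocab()
        seq = encode_pair("w1 w2 w3 w4", "w5 w6", vocab, 16)
        batch = mask_tokens(seq, vocab, np.random.default_rng(3))
        assert np.array_equal(batch.original_ids,
                              np.asarray(seq.ids)[batch.mask_positions])


class TestNspPairs:
    def corpus(self, n_docs=5, n_sent=6):
        return [[f"w{d} w{d} w{s}" for s in range(n_sent)] for d in range(n_docs)]

    def test_half_labeled_is_next(self):
        pairs = make_nsp_pairs(self.corpus(5, 21), np.random.default_rng(0))
        assert len(pairs) == 100
        n_next = sum(1 for _, isn in pairs if isn)
        assert abs(n_next - 50) <= 1

    def test_not_next_comes_from_other_document(self):
        corpus = self.corpus(6, 8)
        sentence_doc = {s: d for d, doc in enumerate(corpus) for s in doc}
        pairs = make_nsp_pairs(corpus, np.random.default_rng(1))
        for (a, b), isn in pairs:
            if not isn:
                assert sentence_doc[b] != sentence_doc[a]

    def test_two_documents_give_both_kinds(self):
        pairs = make_nsp_pairs(self.corpus(2, 2), np.random.default_rng(2))
        assert {isn for _, isn in pairs} == {True, False}

    def test_single_document_rejected(self):
        with pytest.raises(ValueError, match="2 documents"):
            make_nsp_pairs(self.corpus(1), np.random.default_rng(0))


class TestCountParameters:
    def test_base_geometry_close_to_printed_110m(self):
        cfg = EncoderConfig(n_layers=12, hidden=768, n_heads=12,
                            vocab_size=30522, max_positions=512, ff_inner=3072)
        n = count_parameters(cfg)
        assert abs(n - 110e6) / 110e6 < 0.01

    def test_zero_layer_count_is_embeddings_plus_pooler(self):
        cfg = EncoderConfig(n_layers=0, hidden=4, n_heads=1, vocab_size=1,
                            max_positions=1)
        expected = (1 * 4 + 2 * 4 + 1 * 4 + 2 * 4) + (4 * 4 + 4)
        assert count_parameters(cfg) == expected

    @pytest.mark.parametrize("seed", range(20))
    def test_formula_equals_checkpoint_enumeration(self, seed):
        rng = np.random.default_rng(seed)
        heads = int(rng.integers(1, 4))
        cfg = EncoderConfig(n_layers=int(rng.integers(0, 4)),
                            hidden=heads * int(rng.integers(2, 6)),
                            n_heads=heads,
                            vocab_size=int(rng.integers(6, 60)),
                            max_positions=int(rng.integers(4, 40)))
        params = EncoderParams.init(cfg, seed=seed)
        assert count_parameters(cfg) == params.n_trunk_elements()


class TestCheckpoint:
    def test_save_load_encode_is_bit_identical(self, tmp_path, tiny_params):
        vocab = small_vocab()
        seq = some_sequence(vocab)
        before = encode(seq, tiny_params)
        tiny_params.save(tmp_path / "ckpt")
        loaded = EncoderParams.load(tmp_path / "ckpt")
        assert np.array_equal(before, encode(seq, loaded))

    def test_shape_mismatch_detected(self, tmp_path, tiny_params):
        tiny_params.save(tmp_path / "ckpt")
        import json
        manifest = json.loads((tmp_path / "ckpt" / "config.json").read_text())
        manifest["shapes"]["pooler/b"] = [999]
        (tmp_path / "ckpt" / "config.json").write_text(json.dumps(manifest))
        with pytest.raises(ValueError, match="shape mismatch"):
            EncoderParams.load(tmp_path / "ckpt")


class TestPretrain:
    def make_corpus(self):
        return generate_pretrain_corpus(SynthConfig(n_docs=6, sentences_per_doc=6, seed=0))

    def test_loss_decreases_on_tiny_corpus(self):
        corpus = self.make_corpus()
        vocab = build_vocab((s for d in corpus for s in d), 130)
        cfg = EncoderConfig(n_layers=1, hidden=16, n_heads=2,
                            vocab_size=len(vocab), max_positions=24)
        _, history = pretrain(corpus, vocab, cfg,
                              PretrainSchedule(epochs=4, batch_size=8, max_len=16, seed=0))
        assert history["total_loss"][-1] < history["total_loss"][0]

    def test_zero_learning_rate_changes_nothing(self):
        corpus = self.make_corpus()
        vocab = build_vocab((s for d in corpus for s in d), 130)
        cfg = EncoderConfig(n_layers=1, hidden=16, n_heads=2,
                            vocab_size=len(vocab), max_positions=24)
        schedule = PretrainSchedule(epochs=1, batch_size=8, max_len=16, seed=0,
                                    learning_rate=0.0)
        params, _ = pretrain(corpus, vocab, cfg, schedule)
        fresh = EncoderParams.init(cfg, seed=schedule.seed)
        for name in fresh.params:
            assert np.array_equal(params.params[name].data, fresh.params[name].data)
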