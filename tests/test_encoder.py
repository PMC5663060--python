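"""Encoder building blocks against naive re-computations of their formulas."""

import numpy as np
import pytest

from charner.encoder import (CharAttentionParams, CombinerParams,
                             EncoderConfig, LSTMParams, _attention_weights,
                             char_attention, combine_hidden, encode_sentence,
                             lstm_forward, window_features, word_representation)
from charner.autodiff import Tensor

from conftest import build_tiny_model


def naive_char_attention(E, w, p, win=2):
    """Straight transcription of the attention formulas, no stabilization."""
    n, d = E.shape
    Epad = np.vstack([np.zeros((win, d)), E, np.zeros((win, d))])
    T = []
    for j in range(n):
        window = Epad[j:j + 2 * win + 1].reshape(-1)
        h = np.tanh(p.W_c.data @ window + p.b_c.data)
        T.append(np.exp(p.W_t.data @ h + p.U_t.data @ w + p.b_t.data))
    T = np.asarray(T)
    a = T / T.sum(axis=0)
    return (a * E).sum(axis=0), a


def make_attention(rng, d_char=4, d_word=6, hidden=3, win=2):
    return CharAttentionParams.init(d_char, d_word, hidden, win,
                                    rng if isinstance(rng, np.random.Generator)
                                    else np.random.default_rng(rng))


class TestCharAttention:
    def test_single_character_returns_its_embedding(self, rng):
        p = make_attention(rng)
        E = rng.normal(size=(1, 4))
        w = rng.normal(size=6)
        np.testing.assert_allclose(char_attention(E, w, p), E[0], atol=1e-12)
        np.testing.assert_allclose(_attention_weights(Tensor(E), Tensor(w), p, 2), 1.0)

    def test_zero_attention_params_give_uniform_average(self, rng):
        p = make_attention(rng)
        for t in (p.W_t, p.U_t, p.b_t):
            t.data[:] = 0.0
        E = rng.normal(size=(5, 4))
        w = rng.normal(size=6)
        np.testing.assert_allclose(char_attention(E, w, p), E.mean(axis=0),
                                   atol=1e-12)

    def test_matches_naive_formula(self, rng):
        p = make_attention(rng)
        for _ in range(20):
            n = int(rng.integers(1, 9))
            E = rng.normal(size=(n, 4)) * 0.5
            w = rng.normal(size=6) * 0.5
            expected, a = naive_char_attention(E, w, p)
            np.testing.assert_allclose(char_attention(E, w, p), expected,
                                       atol=1e-8)

    def test_weights_normalized_per_dimension(self, rng):
        p = make_attention(rng)
        for _ in range(30):
            n = int(rng.integers(1, 12))
            E = rng.normal(size=(n, 4))
            w = rng.normal(size=6)
            a = _attention_weights(Tensor(E), Tensor(w), p, 2)
            assert (a >= 0).all()
            np.testing.assert_allclose(a.sum(axis=0), 1.0, atol=1e-9)

    def test_empty_word_rejected(self, rng):
        p = make_attention(rng)
        with pytest.raises(ValueError):
            char_attention(np.zeros((0, 4)), np.zeros(6), p)


class TestWordRepresentation:
    def test_concatenation_order(self, rng):
        rc, ew = rng.normal(size=30), rng.normal(size=50)
        out = word_representation(rc, ew)
        assert out.shape == (80,)
        np.testing.assert_array_equal(out[:30], rc)
        np.testing.assert_array_equal(out[30:], ew)

    def test_without_char_part(self, rng):
        ew = rng.normal(size=50)
        np.testing.assert_array_equal(word_representation(None, ew), ew)

    def test_zero_char_part_keeps_word_part(self, rng):
        ew = rng.normal(size=5)
        np.testing.assert_array_equal(word_representation(np.zeros(3), ew)[3:], ew)


class TestWindowFeatures:
    def test_zero_half_width_is_identity(self, rng):
        reps = list(rng.normal(size=(4, 3)))
        out = window_features(reps, 0)
        np.testing.assert_array_equal(np.asarray(out), np.asarray(reps))

    def test_single_token_padding(self, rng):
        r = rng.normal(size=(1, 3))
        (x,) = window_features(list(r), 2)
        assert x.shape == (15,)
        np.testing.assert_array_equal(x[:6], 0)
        np.testing.assert_array_equal(x[6:9], r[0])
        np.testing.assert_array_equal(x[9:], 0)

    def test_middle_position_layout(self, rng):
        r = rng.normal(size=(3, 2))
        out = window_features(list(r), 2)
        x2 = out[1]
        np.testing.assert_array_equal(x2[:2], 0)          # pad
        np.testing.assert_array_equal(x2[2:8], r.reshape(-1))
        np.testing.assert_array_equal(x2[8:], 0)          # pad


class TestLSTM:
    def test_zero_params_zero_input_gives_zero_states(self):
        p = LSTMParams.init(3, 4, np.random.default_rng(0))
        for name in ("W_i", "W_f", "W_o", "W_g", "b_i", "b_f", "b_o", "b_g"):
            getattr(p, name).data[:] = 0.0
        out = lstm_forward(np.zeros((5, 3)), p)
        np.testing.assert_array_equal(np.asarray(out), 0.0)

    def test_single_step_matches_hand_gate_algebra(self, rng):
        p = LSTMParams.init(3, 2, np.random.default_rng(8))
        x = rng.normal(size=(1, 3))
        z = np.concatenate([x[0], np.zeros(2)])
        sig = lambda v: 1 / (1 + np.exp(-v))
        i = sig(p.W_i.data @ z + p.b_i.data)
        f = sig(p.W_f.data @ z + p.b_f.data)
        o = sig(p.W_o.data @ z + p.b_o.data)
        g = np.tanh(p.W_g.data @ z + p.b_g.data)
        expected = o * np.tanh(i * g)
        np.testing.assert_allclose(lstm_forward(x, p)[0], expected, atol=1e-12)

    def test_reverse_is_mirror_of_forward(self, rng):
        p = LSTMParams.init(3, 4, np.random.default_rng(1))
        xs = rng.normal(size=(6, 3))
        fwd = np.asarray(lstm_forward(xs[::-1], p))[::-1]
        rev = np.asarray(lstm_forward(xs, p, reverse=True))
        np.testing.assert_allclose(rev, fwd, atol=1e-12)

    def test_output_aligned_to_input_order(self, rng):
        p = LSTMParams.init(2, 3, np.random.default_rng(2))
        xs = rng.normal(size=(4, 2))
        out = lstm_forward(xs, p, reverse=True)
        # last input is the first the reversed pass consumes; with one step of
        # context its hidden state must equal the single-step state
        single = lstm_forward(xs[-1:], p)
        np.testing.assert_allclose(out[-1], single[0], atol=1e-12)


class TestCombiner:
    def test_zero_params_give_zero(self, rng):
        p = CombinerParams.init(6, 4, np.random.default_rng(0))
        p.W_f.data[:] = 0.0
        p.b_f.data[:] = 0.0
        out = combine_hidden(rng.normal(size=3), rng.normal(size=3), p)
        np.testing.assert_array_equal(out, 0.0)

    def test_matches_direct_formula_and_range(self, rng):
        p = CombinerParams.init(6, 4, np.random.default_rng(3))
        hf, hb = rng.normal(size=3), rng.normal(size=3)
        expected = np.tanh(p.W_f.data @ np.concatenate([hf, hb]) + p.b_f.data)
        out = combine_hidden(hf, hb, p)
        np.testing.assert_allclose(out, expected, atol=1e-12)
        assert (np.abs(out) < 1.0).all()

    def test_unidirectional_mode(self, rng):
        p = CombinerParams.init(3, 4, np.random.default_rng(4))
        hf = rng.normal(size=3)
        expected = np.tanh(p.W_f.data @ hf + p.b_f.data)
        np.testing.assert_allclose(combine_hidden(hf, None, p), expected,
                                   atol=1e-12)


class TestEncodeSentence:
    def test_shape_contract(self, tiny_model):
        params, sents = tiny_model
        for s in sents:
            feats = encode_sentence(s, params, params.config)
            assert feats.shape == (len(s), params.config.combiner_dim)

    def test_use_char_changes_architecture_and_output(self, tiny_sentences):
        import copy
        with_char = build_tiny_model(copy.deepcopy(tiny_sentences), use_char=True)
        without = build_tiny_model(copy.deepcopy(tiny_sentences), use_char=False)
        s_with = copy.deepcopy(tiny_sentences)
        s_without = copy.deepcopy(tiny_sentences)
        from charner.corpus import index_corpus
        index_corpus(s_with, with_char.word_table.vocab, with_char.char_alphabet,
                     with_char.tag_alphabet)
        index_corpus(s_without, without.word_table.vocab, without.char_alphabet,
                     without.tag_alphabet)
        a = encode_sentence(s_with[0], with_char, with_char.config)
        b = encode_sentence(s_without[0], without, without.config)
        assert a.shape == b.shape
        assert not np.allclose(a, b)

    def test_unidirectional_has_no_backward_params(self, tiny_sentences):
        params = build_tiny_model(tiny_sentences, bidirectional=False)
        assert params.lstm_bwd is None
        feats = encode_sentence(tiny_sentences[0], params, params.config)
        assert feats.shape == (len(tiny_sentences[0]), params.config.combiner_dim)

    def test_deterministic_given_parameters(self, tiny_model):
        params, sents = tiny_model
        a = encode_sentence(sents[0], params, params.config)
        b = encode_sentence(sents[0], params, params.config)
        np.testing.assert_array_equal(a, b)

    def test_feature_export_hook_writes_tsv(self, tiny_model, tmp_path):
        from charner.encoder import export_features
        params, sents = tiny_model
        path = tmp_path / "feats.tsv"
        export_features(sents[:2], params, params.config, path)
        rows = [l.split("\t") for l in path.read_text().splitlines()]
        assert len(rows) == len(sents[0]) + len(sents[1])
        assert rows[0][2] == sents[0].tokens[0].surface
        assert len(rows[0]) == 3 + params.config.combiner_dim
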