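"""Objective, gradients, AdaGrad arithmetic, the training loop and archives."""

import copy

import numpy as np
import pytest

from charner.corpus import TaggedSentence, index_corpus
from charner.evaluation import score_tag_sequences
from charner.synth import SynthConfig, generate_corpus
from charner.training import (AdaGradOptimizer, ConfigError, ModelIOError,
                              ModelParams, TrainConfig, adagrad_step,
                              gradients, index_for_model, load_model,
                              predict_tags, save_model, sentence_loss, train)

from conftest import build_tiny_model


def finite_difference(sentence, params, lam, eps=1e-5, **kw):
    """Central finite differences over every coordinate of every block."""
    out = {}
    for name, t in params.named_tensors():
        arr = t.data
        fd = np.zeros_like(arr)
        it = np.nditer(arr, flags=["multi_index"])
        for _ in it:
            ix = it.multi_index
            orig = arr[ix]
            arr[ix] = orig + eps
            lp = sentence_loss(sentence, params, lam, **kw)
            arr[ix] = orig - eps
            lm = sentence_loss(sentence, params, lam, **kw)
            arr[ix] = orig
            fd[ix] = (lp - lm) / (2 * eps)
        out[name] = fd
    return out


def max_relative_error(analytic, numeric):
    worst = 0.0
    for name in analytic:
        a, n = analytic[name], numeric[name]
        denom = np.maximum(np.maximum(np.abs(a), np.abs(n)), 1e-8)
        worst = max(worst, float((np.abs(a - n) / denom).max()))
    return worst


class TestSentenceLoss:
    def test_zero_params_give_uniform_crf_loss(self, tiny_model):
        params, sents = tiny_model
        for _, t in params.named_tensors():
            t.data[:] = 0.0
        K = len(params.tag_alphabet)
        for s in sents:
            assert sentence_loss(s, params, 0.0) == pytest.approx(
                len(s) * np.log(K), abs=1e-10)

    def test_ridge_term_is_zero_at_zero_params(self, tiny_model):
        params, sents = tiny_model
        for _, t in params.named_tensors():
            t.data[:] = 0.0
        assert sentence_loss(sents[0], params, 10.0) == pytest.approx(
            sentence_loss(sents[0], params, 0.0))

    def test_loss_is_nonnegative(self, tiny_model):
        params, sents = tiny_model
        for s in sents:
            assert sentence_loss(s, params, 1e-8) >= 0.0

    def test_strict_sign_flag_flips_ridge(self, tiny_model):
        params, sents = tiny_model
        s = sents[0]
        base = sentence_loss(s, params, 0.0)
        pen = sentence_loss(s, params, 0.5, ridge_as_penalty=True)
        rew = sentence_loss(s, params, 0.5, ridge_as_penalty=False)
        assert pen > base > rew
        assert pen - base == pytest.approx(base - rew, rel=1e-9)


class TestGradients:
    @pytest.mark.parametrize("decoder", ["crf", "softmax"])
    @pytest.mark.parametrize("bidirectional", [True, False])
    def test_finite_difference_all_blocks(self, tiny_sentences, decoder,
                                          bidirectional):
        params = build_tiny_model(copy.deepcopy(tiny_sentences),
                                  bidirectional=bidirectional, decoder=decoder)
        sents = copy.deepcopy(tiny_sentences)
        index_for_model(params, sents)
        s = sents[0]
        lam = 0.01
        analytic = gradients(s, params, lam, decoder=decoder)
        numeric = finite_difference(s, params, lam, decoder=decoder)
        assert max_relative_error(analytic, numeric) < 1e-4

    def test_frozen_word_embeddings_get_zero_gradient(self, tiny_sentences):
        params = build_tiny_model(tiny_sentences, fine_tune_words=False)
        g = gradients(tiny_sentences[0], params, 0.01)
        assert not np.any(g["word_matrix"])
        assert np.any(g["char_matrix"])

    def test_ridge_contribution_is_lambda_theta(self, tiny_model):
        params, sents = tiny_model
        s = sents[0]
        lam = 0.37
        g0 = gradients(s, params, 0.0)
        g1 = gradients(s, params, lam)
        for name, t in params.trainable_tensors():
            np.testing.assert_allclose(g1[name] - g0[name], lam * t.data,
                                       atol=1e-9)


class TestAdaGrad:
    def test_first_step_is_alpha_sign_g(self):
        theta, state = adagrad_step(1.0, 7.3, 0.0, alpha=0.01)
        assert theta == pytest.approx(1.0 - 0.01)
        theta, _ = adagrad_step(1.0, -7.3, 0.0, alpha=0.01)
        assert theta == pytest.approx(1.0 + 0.01)

    def test_three_four_five_step(self):
        theta, state = adagrad_step(0.0, 3.0, 0.0, alpha=0.01)
        assert state == pytest.approx(9.0)
        theta2, state2 = adagrad_step(theta, 4.0, state, alpha=0.01)
        assert state2 == pytest.approx(25.0)
        assert theta - theta2 == pytest.approx(0.01 * 4.0 / 5.0)

    def test_step_size_decays_under_constant_gradient(self):
        theta, state = 0.0, 0.0
        steps = []
        for _ in range(6):
            new_theta, state = adagrad_step(theta, 2.0, state, alpha=0.1)
            steps.append(theta - new_theta)
            theta = new_theta
        assert all(a > b for a, b in zip(steps, steps[1:]))

    def test_zero_gradient_is_a_guarded_noop(self):
        theta, state = adagrad_step(0.5, 0.0, 0.0, alpha=0.01)
        assert theta == 0.5 and state == 0.0

    def test_vectorized_optimizer_matches_scalar_rule(self, tiny_model, rng):
        params, _ = tiny_model
        opt = AdaGradOptimizer(params, alpha=0.05)
        name, t = next(params.trainable_tensors())
        g = rng.normal(size=t.data.shape)
        expected, _ = adagrad_step(t.data.copy(), g, np.zeros_like(g), 0.05)
        t.grad = g
        opt.step()
        np.testing.assert_allclose(t.data, expected, atol=1e-12)


def small_corpus(n=10, seed=4):
    cfg = SynthConfig(n_sentences=n, seed=seed)
    corpus = generate_corpus(cfg)
    return corpus.train


class TestTrainLoop:
    def overfit(self, decoder="crf", seed=5, max_epochs=50):
        sents = small_corpus()
        params = build_tiny_model(sents, hidden=20, combiner=16, char_hidden=10,
                                  word_dim=20, char_dim=8, word_window=2,
                                  char_window=2, seed=seed, decoder=decoder)
        cfg = TrainConfig(max_epochs=max_epochs, patience=max_epochs,
                          decoder=decoder, seed=seed)
        params, log = train(sents, [], params, cfg)
        pred = predict_tags(params, sents, decoder=decoder)
        return params, log, score_tag_sequences([s.tags for s in sents], pred)

    def test_overfits_ten_sentences(self):
        _, log, result = self.overfit()
        assert result.f1 == 1.0
        assert len(log) <= 50

    def test_softmax_decoder_ignores_transitions(self):
        sents = small_corpus()
        params = build_tiny_model(sents, hidden=8, combiner=6, decoder="softmax")
        before = params.transitions.data.copy()
        cfg = TrainConfig(max_epochs=2, patience=2, decoder="softmax", l2=0.0)
        train(sents, [], params, cfg)
        np.testing.assert_array_equal(params.transitions.data, before)

    def test_identical_seeds_give_identical_logs_and_params(self):
        runs = []
        for _ in range(2):
            sents = small_corpus()
            params = build_tiny_model(sents, hidden=8, combiner=6, seed=9)
            cfg = TrainConfig(max_epochs=3, patience=3, seed=9)
            params, log = train(sents, [], params, cfg)
            runs.append((log, params.snapshot()))
        assert runs[0][0] == runs[1][0]
        for name in runs[0][1]:
            np.testing.assert_array_equal(runs[0][1][name], runs[1][1][name])

    def test_large_l2_shrinks_parameter_norms(self):
        sents = small_corpus()
        params = build_tiny_model(sents, hidden=6, combiner=5)
        cfg = TrainConfig(max_epochs=4, patience=4, l2=10.0)
        norms = []
        snap = params.snapshot()
        for epochs in (1, 2, 3, 4):
            params.restore(snap)
            c = TrainConfig(max_epochs=epochs, patience=epochs, l2=10.0,
                            shuffle=False)
            # disable model selection effects by measuring the live params
            from charner.training import AdaGradOptimizer, _loss_t
            opt = AdaGradOptimizer(params, c.learning_rate)
            for _ in range(epochs):
                for s in sents:
                    params.zero_grads()
                    loss = _loss_t(s, params, c.l2, "crf", True)
                    loss.backward()
                    opt.step()
            norms.append(sum(np.linalg.norm(t.data)
                             for _, t in params.trainable_tensors()))
        assert all(a > b for a, b in zip(norms, norms[1:]))

    def test_small_step_never_increases_loss(self, tiny_model):
        params, sents = tiny_model
        s = sents[0]
        cfg = TrainConfig(learning_rate=1e-4)
        opt = AdaGradOptimizer(params, cfg.learning_rate)
        from charner.training import _loss_t
        prev = sentence_loss(s, params, 0.0)
        for _ in range(5):
            params.zero_grads()
            loss = _loss_t(s, params, 0.0, "crf", True)
            loss.backward()
            opt.step()
            now = sentence_loss(s, params, 0.0)
            assert now <= prev + 1e-9
            prev = now

    def test_empty_corpus_raises(self, tiny_model):
        params, _ = tiny_model
        with pytest.raises(ConfigError):
            train([], [], params, TrainConfig())


class TestModelArchive:
    def test_round_trip_preserves_decoding(self, tmp_path, tiny_model):
        params, sents = tiny_model
        before = predict_tags(params, sents)
        path = tmp_path / "model.npz"
        save_model(path, params)
        loaded = load_model(path)
        raw = [TaggedSentence.from_pairs(s.surfaces, ["O"] * len(s))
               for s in sents]
        index_for_model(loaded, raw, with_tags=False)
        assert predict_tags(loaded, raw) == before
        for (n1, t1), (n2, t2) in zip(params.named_tensors(),
                                      loaded.named_tensors()):
            assert n1 == n2
            np.testing.assert_array_equal(t1.data, t2.data)

    def test_truncated_file_raises_clean_error(self, tmp_path, tiny_model):
        params, _ = tiny_model
        path = tmp_path / "model.npz"
        save_model(path, params)
        blob = path.read_bytes()
        path.write_bytes(blob[: len(blob) // 2])
        with pytest.raises(ModelIOError):
            load_model(path)

    def test_no_char_model_refuses_char_features(self, tmp_path, tiny_sentences):
        params = build_tiny_model(tiny_sentences, use_char=False)
        path = tmp_path / "m.npz"
        save_model(path, params)
        loaded = load_model(path)
        assert loaded.attention is None
        assert not loaded.config.use_char
        from charner.encoder import encode_sentence, EncoderConfig
        bad = EncoderConfig(use_char=True, bidirectional=loaded.config.bidirectional,
                            word_window=loaded.config.word_window,
                            char_window=loaded.config.char_window,
                            hidden_dim=loaded.config.hidden_dim,
                            combiner_dim=loaded.config.combiner_dim,
                            char_hidden_dim=loaded.config.char_hidden_dim)
        sents = copy.deepcopy(tiny_sentences)
        index_for_model(loaded, sents)
        with pytest.raises(ValueError):
            encode_sentence(sents[0], loaded, bad)
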