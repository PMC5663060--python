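"""Canned benchmark experiments on the synthetic corpora.

These are the package's reference experiments: capability checks (overfit,
learnability) and the two ablation contrasts (CRF vs per-position softmax
decoding on the transition-dependent corpus; with vs without the character
representation on the morphology-dependent corpus).  Each is a pure
function of its seed so runs are reproducible.

Problem sizes are chosen for desk-scale, single-core runs: the capability
experiments use the 2000-sentence default corpus with the reference
hyperparameters; the ablation contrasts use 400-sentence variant corpora
with a reduced (50-unit) network, since the separations they demonstrate
are structural rather than capacity-driven.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List

from .model import BiLstmCrfTagger
from .synth import (SynthConfig, embedding_vocab, generate_corpus,
                    generate_embeddings)


@dataclass
class ExperimentResult:
    name: str
    f1: float
    n_train: int
    epochs_run: int
    extra: dict | None = None


def _fit(corpus, emb, **kw) -> BiLstmCrfTagger:
    tagger = BiLstmCrfTagger(embeddings=emb, **kw)
    tagger.fit([s.surfaces for s in corpus.train], [s.tags for s in corpus.train],
               X_dev=[s.surfaces for s in corpus.dev],
               y_dev=[s.tags for s in corpus.dev])
    return tagger


def overfit_check(seed: int = 42, n_sentences: int = 10,
                  max_epochs: int = 50) -> ExperimentResult:
    """Drive training F1 to 1.0 on a tiny corpus with the reference
    hyperparameters (char 30 / hidden 100 / combiner 100 / α 0.01 / λ 1e-8)."""
    corpus = generate_corpus(SynthConfig(n_sentences=n_sentences, seed=seed))
    X = [s.surfaces for s in corpus.train]
    y = [s.tags for s in corpus.train]
    tagger = BiLstmCrfTagger(max_epochs=max_epochs, patience=max_epochs,
                             dev_fraction=0.0, seed=seed)
    tagger.fit(X, y)
    hist = [r["dev_f1"] for r in tagger.history_]
    first = next((i + 1 for i, v in enumerate(hist) if v == 1.0), len(hist))
    return ExperimentResult("overfit", tagger.score(X, y), n_sentences,
                            len(hist), {"epochs_to_perfect": first})


def learnability(seed: int = 11, n_sentences: int = 2000,
                 max_epochs: int = 5) -> ExperimentResult:
    """Test-split span F1 of the full BLSTM+Char+CRF model on the default
    synthetic corpus at the reference hyperparameters."""
    cfg = SynthConfig(n_sentences=n_sentences, seed=seed)
    corpus = generate_corpus(cfg)
    emb = generate_embeddings(embedding_vocab(cfg), dim=50, seed=seed)
    tagger = _fit(corpus, emb, max_epochs=max_epochs, patience=2, seed=seed)
    f1 = tagger.score([s.surfaces for s in corpus.test],
                      [s.tags for s in corpus.test])
    return ExperimentResult("learnability", f1, n_sentences,
                            len(tagger.history_))


_ABLATION_NET = dict(word_dim=30, hidden_dim=50, combiner_dim=50,
                     char_hidden_dim=30, max_epochs=6, patience=6)


def _ablation_pair(variant: str, seed: int, configs: List[dict],
                   n_sentences: int = 400) -> List[float]:
    cfg = SynthConfig(n_sentences=n_sentences, variant=variant, seed=seed)
    corpus = generate_corpus(cfg)
    emb = generate_embeddings(embedding_vocab(cfg), dim=30, seed=seed)
    scores = []
    for overrides in configs:
        tagger = _fit(corpus, emb, seed=seed, **_ABLATION_NET, **overrides)
        scores.append(tagger.score([s.surfaces for s in corpus.test],
                                   [s.tags for s in corpus.test]))
    return scores


def crf_vs_softmax(seed: int = 21, n_sentences: int = 400) -> ExperimentResult:
    """CRF minus softmax test F1 on the transition-dependent corpus.

    The type cue sits on the last entity token, and both arms share a
    causal encoder (forward LSTM, no context window, no characters), so
    position-wise argmax cannot type the earlier entity tokens while the
    joint decode propagates the cue backward through the transitions."""
    causal = {"bidirectional": False, "word_window": 0, "use_char": False}
    f_crf, f_soft = _ablation_pair("transition", seed,
                                   [dict(causal, decoder="crf"),
                                    dict(causal, decoder="softmax")],
                                   n_sentences)
    return ExperimentResult("crf_vs_softmax", f_crf - f_soft, n_sentences, 0,
                            {"crf_f1": f_crf, "softmax_f1": f_soft})


def char_vs_nochar(seed: int = 22, n_sentences: int = 400) -> ExperimentResult:
    """+Char minus -Char test F1 on the morphology-dependent corpus, where
    every entity token is out-of-vocabulary and only a character suffix
    carries the type."""
    f_char, f_none = _ablation_pair("morphology", seed,
                                    [{"use_char": True}, {"use_char": False}],
                                    n_sentences)
    return ExperimentResult("char_vs_nochar", f_char - f_none, n_sentences, 0,
                            {"char_f1": f_char, "nochar_f1": f_none})
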