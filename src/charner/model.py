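"""The scikit-learn-style estimator wrapping the whole tagger.

``BiLstmCrfTagger`` is a sequence classifier: ``X`` is a list of token
sequences (strings), ``y`` a list of equally long BIEOS tag sequences.
``fit`` builds the alphabets, indexes the corpus, trains with online
AdaGrad and keeps the best dev-split parameters; ``predict`` returns tag
sequences, ``transform`` the per-token encoder features (the raw
representation-export hook), ``score`` the span-level F1.

Every architectural ablation is a constructor switch: ``use_char``,
``bidirectional``, ``decoder`` ("crf" or "softmax") and
``fine_tune_words``.
"""

from __future__ import annotations

import copy
from typing import List, Optional, Sequence

import numpy as np
from sklearn.base import BaseEstimator
from sklearn.exceptions import NotFittedError

from .corpus import CharAlphabet, TaggedSentence, index_corpus
from .embeddings import EmbeddingTable, load_word2vec_text, random_word_table
from .encoder import EncoderConfig, encode_sentence
from .evaluation import score_tag_sequences
from .tagging import TagAlphabet, bieos_to_spans
from .training import (ModelParams, TrainConfig, index_for_model, predict_tags,
                       train)


class BiLstmCrfTagger(BaseEstimator):
    """(Bi)LSTM-CRF sequence tagger with attention-composed character features.

    Parameters mirror the reference configuration: 30-dim characters,
    100-unit LSTM and combiner layers, ±2 word/character windows, AdaGrad
    at α=0.01 with λ=1e-8.

    Attributes (after ``fit``)
    --------------------------
    params_ : ModelParams
        All trained tensors plus the alphabets.
    history_ : list of dict
        Per-epoch training log (loss, dev P/R/F1).
    best_epoch_ : int
        Epoch whose parameters were kept.
    """

    def __init__(self, word_dim: int = 50, char_dim: int = 30,
                 char_hidden_dim: int = 50, hidden_dim: int = 100,
                 combiner_dim: int = 100, word_window: int = 2,
                 char_window: int = 2, use_char: bool = True,
                 bidirectional: bool = True, decoder: str = "crf",
                 use_stop: bool = True, learning_rate: float = 0.01,
                 l2: float = 1e-8, max_epochs: int = 100, patience: int = 10,
                 fine_tune_words: bool = True, digit_run: bool = True,
                 embeddings: Optional[EmbeddingTable] = None,
                 dev_fraction: float = 0.1, shuffle: bool = True,
                 ridge_as_penalty: bool = True, seed: int = 0, verbose: int = 0):
        self.word_dim = word_dim
        self.char_dim = char_dim
        self.char_hidden_dim = char_hidden_dim
        self.hidden_dim = hidden_dim
        self.combiner_dim = combiner_dim
        self.word_window = word_window
        self.char_window = char_window
        self.use_char = use_char
        self.bidirectional = bidirectional
        self.decoder = decoder
        self.use_stop = use_stop
        self.learning_rate = learning_rate
        self.l2 = l2
        self.max_epochs = max_epochs
        self.patience = patience
        self.fine_tune_words = fine_tune_words
        self.digit_run = digit_run
        self.embeddings = embeddings
        self.dev_fraction = dev_fraction
        self.shuffle = shuffle
        self.ridge_as_penalty = ridge_as_penalty
        self.seed = seed
        self.verbose = verbose

    # -- configuration plumbing ---------------------------------------------------
    def _encoder_config(self) -> EncoderConfig:
        return EncoderConfig(use_char=self.use_char,
                             bidirectional=self.bidirectional,
                             word_window=self.word_window,
                             char_window=self.char_window,
                             hidden_dim=self.hidden_dim,
                             combiner_dim=self.combiner_dim,
                             char_hidden_dim=self.char_hidden_dim)

    def _train_config(self) -> TrainConfig:
        return TrainConfig(learning_rate=self.learning_rate, l2=self.l2,
                           seed=self.seed, max_epochs=self.max_epochs,
                           patience=self.patience,
                           fine_tune_words=self.fine_tune_words,
                           decoder=self.decoder, use_stop=self.use_stop,
                           ridge_as_penalty=self.ridge_as_penalty,
                           shuffle=self.shuffle, encoder=self._encoder_config())

    @staticmethod
    def _to_sentences(X: Sequence[Sequence[str]],
                      y: Optional[Sequence[Sequence[str]]]) -> List[TaggedSentence]:
        if y is None:
            return [TaggedSentence.from_pairs(words, ["O"] * len(words)) for words in X]
        if len(X) != len(y):
            raise ValueError(f"{len(X)} sentences vs {len(y)} tag sequences")
        sents = [TaggedSentence.from_pairs(words, tags) for words, tags in zip(X, y)]
        for s in sents:
            s.validate()
        return sents

    def _word_table(self, sentences: Sequence[TaggedSentence]) -> EmbeddingTable:
        emb = self.embeddings
        if emb is None:
            from .corpus import normalize_token
            tokens = (normalize_token(t.surface, self.digit_run)
                      for s in sentences for t in s.tokens)
            return random_word_table(tokens, self.word_dim, seed=self.seed)
        if isinstance(emb, (str, bytes)):
            emb = load_word2vec_text(emb, expected_dim=None, seed=self.seed)
        # never mutate a caller-owned table during fine-tuning
        table = EmbeddingTable(dict(emb.vocab), emb.matrix.astype(np.float64).copy(),
                               trainable=emb.trainable)
        return table

    # -- estimator API --------------------------------------------------------------
    def fit(self, X, y, X_dev=None, y_dev=None):
        """Train on token/tag sequences; an internal seeded 10% dev split is
        used for model selection when no explicit dev set is given."""
        sentences = self._to_sentences(X, y)
        if not sentences:
            raise ValueError("empty training corpus")
        if X_dev is not None:
            dev = self._to_sentences(X_dev, y_dev)
            train_sents = sentences
        else:
            rng = np.random.default_rng(self.seed)
            n_dev = int(round(len(sentences) * self.dev_fraction))
            order = rng.permutation(len(sentences))
            dev = [sentences[i] for i in order[:n_dev]]
            train_sents = [sentences[i] for i in order[n_dev:]]
            if not train_sents:
                train_sents, dev = sentences, []

        tag_alphabet = TagAlphabet.from_tags([s.tags for s in sentences])
        char_alphabet = CharAlphabet.from_sentences(train_sents)
        word_table = self._word_table(train_sents)
        from .embeddings import init_char_embeddings
        char_table = init_char_embeddings(len(char_alphabet), self.char_dim,
                                          seed=self.seed)
        params = ModelParams.build(word_table, char_table, tag_alphabet,
                                   char_alphabet, self._encoder_config(),
                                   seed=self.seed, decoder=self.decoder,
                                   use_stop=self.use_stop,
                                   fine_tune_words=self.fine_tune_words,
                                   digit_run=self.digit_run)
        index_corpus(train_sents, word_table.vocab, char_alphabet, tag_alphabet,
                     digit_run=self.digit_run)
        index_corpus(dev, word_table.vocab, char_alphabet, tag_alphabet,
                     digit_run=self.digit_run)
        params, log = train(train_sents, dev, params, self._train_config(),
                            verbose=self.verbose)
        self.params_ = params
        self.history_ = log
        self.best_epoch_ = log[-1]["best_epoch"] if log else 0
        self.tag_alphabet_ = tag_alphabet
        self.char_alphabet_ = char_alphabet
        self.n_parameters_ = params.n_parameters()
        return self

    def _require_fitted(self):
        if not hasattr(self, "params_"):
            raise NotFittedError("this BiLstmCrfTagger instance is not fitted yet")

    def predict(self, X) -> List[List[str]]:
        """BIEOS tag sequence for each token sequence."""
        self._require_fitted()
        sents = self._to_sentences(X, None)
        index_for_model(self.params_, sents, with_tags=False)
        return predict_tags(self.params_, sents)

    def predict_spans(self, X):
        """Entity spans (start, end, type) per sentence."""
        return [bieos_to_spans(tags) for tags in self.predict(X)]

    def transform(self, X) -> List[np.ndarray]:
        """Per-token encoder features h_1..h_T, one (T, combiner_dim) array
        per sentence — the representation-inspection hook."""
        self._require_fitted()
        sents = self._to_sentences(X, None)
        index_for_model(self.params_, sents, with_tags=False)
        return [encode_sentence(s, self.params_, self.params_.config) for s in sents]

    def score(self, X, y) -> float:
        """Micro-averaged span F1 against gold tag sequences."""
        return score_tag_sequences(list(y), self.predict(X)).f1

    def evaluate(self, X, y):
        """Full :class:`~charner.evaluation.EvalResult` on gold sequences."""
        return score_tag_sequences(list(y), self.predict(X))
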