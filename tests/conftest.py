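import numpy as np
import pytest

from charner.corpus import CharAlphabet, TaggedSentence, index_corpus
from charner.embeddings import init_char_embeddings, random_word_table
from charner.encoder import EncoderConfig
from charner.tagging import TagAlphabet
from charner.training import ModelParams


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def tiny_sentences():
    """Three short sentences with two entity types and mixed orthography."""
    return [
        TaggedSentence.from_pairs(
            ["Characterization", "of", "IL-2", "receptors", "."],
            ["O", "O", "B-protein", "E-protein", "O"]),
        TaggedSentence.from_pairs(
            ["The", "zfp36", "gene", "binds", "IL-2", "."],
            ["O", "B-DNA", "E-DNA", "O", "S-protein", "O"]),
        TaggedSentence.from_pairs(
            ["No", "entities", "here", "."],
            ["O", "O", "O", "O"]),
    ]


def build_tiny_model(sentences, *, hidden=5, combiner=4, char_hidden=3,
                     word_window=1, char_window=1, use_char=True,
                     bidirectional=True, word_dim=6, char_dim=4, seed=3,
                     decoder="crf", use_stop=True, fine_tune_words=True):
    """A fully wired ModelParams over ``sentences`` at toy dimensions."""
    from charner.corpus import normalize_token
    config = EncoderConfig(use_char=use_char, bidirectional=bidirectional,
                           word_window=word_window, char_window=char_window,
                           hidden_dim=hidden, combiner_dim=combiner,
                           char_hidden_dim=char_hidden)
    tag_alpha = TagAlphabet.from_tags([s.tags for s in sentences])
    char_alpha = CharAlphabet.from_sentences(sentences)
    vocab = [normalize_token(t.surface) for s in sentences for t in s.tokens]
    word_table = random_word_table(vocab, word_dim, seed=seed)
    char_table = init_char_embeddings(len(char_alpha), char_dim, seed=seed + 1)
    params = ModelParams.build(word_table, char_table, tag_alpha, char_alpha,
                               config, seed=seed + 2, decoder=decoder,
                               use_stop=use_stop, fine_tune_words=fine_tune_words)
    index_corpus(sentences, word_table.vocab, char_alpha, tag_alpha)
    return params


@pytest.fixture
def tiny_model(tiny_sentences):
    return build_tiny_model(tiny_sentences), tiny_sentences
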