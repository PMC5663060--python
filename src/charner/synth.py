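"""Seeded synthetic corpora and embeddings with the structure the model exploits.

The generator emulates the *shape* of biomedical gene-mention corpora
without any real text: multi-type entities of 1-5 tokens (about 40%
single-token, 15% longer than three tokens), type-specific morphological
suffixes inside entity tokens, optional trigger words in front of
mentions, and a filler vocabulary for the rest of the sentence.  Tokens
are synthetic strings, so no real gene names leak into tests.

Besides the default corpus, two engineered variants isolate one signal
each:

``transition``
    Multi-token entities whose tokens come from a shared, type-neutral
    vocabulary except the *final* token, which carries the only lexical
    type cue.  Decoded left-to-right with a causal (forward-only,
    window-free) encoder, per-position argmax cannot type the earlier
    entity tokens — only a joint decode can propagate the entity-final
    cue backward through type-consistent tag transitions.  This is the
    variant on which the CRF decoder must beat the softmax decoder.

``morphology``
    Entity tokens are fresh random strings (out of every embedding
    vocabulary) whose only type signal is a deterministic character
    suffix — the variant on which the character representation must beat
    the word-only model.

All generators are pure functions of (config, seed).
"""

from __future__ import annotations

import string
from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Sequence, Tuple

import numpy as np

from .corpus import AltEntity, TaggedSentence, normalize_token
from .embeddings import EmbeddingTable, PAD_WORD, glorot_bound, save_word2vec_text
from .corpus import UNKNOWN_WORD
from .tagging import EntitySpan, spans_to_bieos

_SUFFIX_POOL = ("ase", "gene", "ide", "ome", "yl")


class SynthConfigError(ValueError):
    pass


@dataclass
class SynthConfig:
    """Knobs of the corpus generator; defaults mirror the shared-task shape
    (40% one-token mentions, 15% mentions longer than three tokens)."""

    n_sentences: int = 2000
    entity_types: Tuple[str, ...] = ("DNA", "protein")
    entity_length_probs: Mapping[int, float] = field(
        default_factory=lambda: {1: 0.40, 2: 0.225, 3: 0.225, 4: 0.075, 5: 0.075})
    entities_per_sentence_probs: Tuple[float, ...] = (0.15, 0.55, 0.30)
    n_filler: int = 120
    n_stems_per_type: int = 60
    n_triggers_per_type: int = 4
    morphology_cue_rate: float = 0.9
    context_cue_rate: float = 0.7
    max_sentence_len: int = 30
    dev_fraction: float = 0.10
    test_fraction: float = 0.20
    variant: str = "default"          # default | transition | morphology
    seed: int = 0

    def __post_init__(self):
        total = sum(self.entity_length_probs.values())
        if abs(total - 1.0) > 1e-9:
            raise SynthConfigError(f"entity length probabilities sum to {total}, not 1")
        if abs(sum(self.entities_per_sentence_probs) - 1.0) > 1e-9:
            raise SynthConfigError("entities-per-sentence probabilities must sum to 1")
        for p in list(self.entity_length_probs.values()) + list(self.entities_per_sentence_probs):
            if not 0.0 <= p <= 1.0:
                raise SynthConfigError("probabilities must lie in [0, 1]")
        if not 0.0 <= self.morphology_cue_rate <= 1.0 or not 0.0 <= self.context_cue_rate <= 1.0:
            raise SynthConfigError("cue rates must lie in [0, 1]")
        if self.variant not in ("default", "transition", "morphology"):
            raise SynthConfigError(f"unknown variant {self.variant!r}")
        longest = max(self.entity_length_probs)
        if longest + 2 > self.max_sentence_len:
            raise SynthConfigError("longest entity cannot fit in the sentence cap")
        if self.n_sentences < 1:
            raise SynthConfigError("n_sentences must be >= 1")


@dataclass
class SynthCorpus:
    train: List[TaggedSentence]
    dev: List[TaggedSentence]
    test: List[TaggedSentence]

    @property
    def splits(self):
        return {"train": self.train, "dev": self.dev, "test": self.test}


def _random_stem(rng: np.random.Generator, lo: int = 3, hi: int = 6) -> str:
    n = int(rng.integers(lo, hi + 1))
    letters = rng.integers(0, 26, size=n)
    return "".join(string.ascii_lowercase[i] for i in letters)


class _Inventories:
    """Deterministic token inventories derived from (config.seed) alone."""

    def __init__(self, config: SynthConfig):
        rng = np.random.default_rng(np.random.SeedSequence([config.seed, 0xF1]))
        self.fillers = [f"{_random_stem(rng)}{i}" if rng.random() < 0.15
                        else _random_stem(rng) for i in range(config.n_filler)]
        self.suffix = {t: _SUFFIX_POOL[i % len(_SUFFIX_POOL)]
                       for i, t in enumerate(sorted(config.entity_types))}
        self.triggers = {t: [f"cue{_random_stem(rng)}" for _ in range(config.n_triggers_per_type)]
                         for t in sorted(config.entity_types)}
        self.stems = {t: [_random_stem(rng) for _ in range(config.n_stems_per_type)]
                      for t in sorted(config.entity_types)}
        self.shared = [_random_stem(rng) for _ in range(config.n_stems_per_type)]


def _sample_entity_tokens(config: SynthConfig, inv: _Inventories, etype: str,
                          length: int, rng: np.random.Generator) -> List[str]:
    if config.variant == "morphology":
        # fresh out-of-vocabulary stems; the suffix is the only type signal
        return [_random_stem(rng) + inv.suffix[etype] for _ in range(length)]
    if config.variant == "transition":
        # type-neutral tokens except the final one, which carries the only
        # lexical type cue; earlier positions are typed correctly only by a
        # decoder that can propagate the cue backward through the tag chain
        tokens = [str(rng.choice(inv.shared)) for _ in range(length - 1)]
        tokens.append(str(rng.choice(inv.stems[etype])))
        return tokens
    tokens = []
    for j in range(length):
        stem = str(rng.choice(inv.stems[etype]))
        if j == 0 and rng.random() < config.morphology_cue_rate:
            stem += inv.suffix[etype]
        tokens.append(stem)
    return tokens


def _sample_sentence(config: SynthConfig, inv: _Inventories,
                     rng: np.random.Generator) -> TaggedSentence:
    lengths = sorted(config.entity_length_probs)
    probs = [config.entity_length_probs[k] for k in lengths]
    n_ent = int(rng.choice(len(config.entities_per_sentence_probs),
                           p=config.entities_per_sentence_probs))
    words: List[str] = []
    spans: List[EntitySpan] = []

    def fillers(lo=1, hi=4):
        for _ in range(int(rng.integers(lo, hi + 1))):
            words.append(str(rng.choice(inv.fillers)))

    fillers()
    for _ in range(n_ent):
        etype = str(rng.choice(sorted(config.entity_types)))
        length = int(rng.choice(lengths, p=probs))
        if config.variant == "transition":
            length = max(2, length)  # the variant exists for multi-token structure
        use_trigger = config.variant == "default" and rng.random() < config.context_cue_rate
        if len(words) + length + int(use_trigger) + 1 > config.max_sentence_len:
            break  # never truncate through an entity
        if use_trigger:
            words.append(str(rng.choice(inv.triggers[etype])))
        start = len(words)
        words.extend(_sample_entity_tokens(config, inv, etype, length, rng))
        spans.append(EntitySpan(start, start + length, etype))
        fillers()
    words = words[:config.max_sentence_len]
    spans = [s for s in spans if s.end <= len(words)]
    sent = TaggedSentence.from_pairs(words, spans_to_bieos(spans, len(words)))
    sent.validate()
    return sent


def generate_corpus(config: SynthConfig) -> SynthCorpus:
    """Train/dev/test splits of BIEOS-valid synthetic sentences.

    Split sizes are ``n_sentences`` for train and the configured fractions
    thereof for dev/test; the three splits are drawn from disjoint seeded
    streams.
    """
    inv = _Inventories(config)
    sizes = {
        "train": config.n_sentences,
        "dev": max(1, int(round(config.n_sentences * config.dev_fraction))),
        "test": max(1, int(round(config.n_sentences * config.test_fraction))),
    }
    splits = {}
    for si, (name, size) in enumerate(sizes.items()):
        rng = np.random.default_rng(np.random.SeedSequence([config.seed, 1 + si]))
        splits[name] = [_sample_sentence(config, inv, rng) for _ in range(size)]
    return SynthCorpus(**splits)


def embedding_vocab(config: SynthConfig) -> List[str]:
    """Normalized token vocabulary the synthetic embeddings should cover.

    For the ``morphology`` variant entity tokens are deliberately excluded —
    they must stay out-of-vocabulary so the character model carries the
    type signal.
    """
    inv = _Inventories(config)
    vocab = [normalize_token(w) for w in inv.fillers]
    for t in sorted(config.entity_types):
        vocab.extend(normalize_token(w) for w in inv.triggers[t])
        if config.variant == "default":
            for stem in inv.stems[t]:
                vocab.append(stem)
                vocab.append(stem + inv.suffix[t])
        elif config.variant == "transition":
            vocab.extend(inv.stems[t])  # the entity-final type cues
    if config.variant == "transition":
        vocab.extend(inv.shared)
    seen = set()
    out = []
    for tok in vocab:
        if tok not in seen:
            seen.add(tok)
            out.append(tok)
    return out


def generate_embeddings(vocab: Sequence[str], dim: int = 50,
                        cue_structure: bool = True, seed: int = 0,
                        path=None) -> EmbeddingTable:
    """Synthetic pre-trained word vectors in word2vec text format.

    With ``cue_structure`` tokens sharing a trailing morpheme (last three
    characters) share a latent direction, so "pre-trained embeddings carry
    signal" is itself testable.  Writes ``path`` when given and returns the
    in-memory table.
    """
    if dim <= 0:
        raise SynthConfigError("embedding dimension must be positive")
    rng = np.random.default_rng(np.random.SeedSequence([seed, 0xE3]))
    directions: Dict[str, np.ndarray] = {}
    rows = []
    ordered = []
    for tok in vocab:
        if tok in ordered:
            continue
        ordered.append(tok)
        noise = rng.normal(0.0, 1.0, size=dim)
        if cue_structure:
            key = tok[-3:]
            if key not in directions:
                directions[key] = rng.normal(0.0, 1.0, size=dim)
            vec = 0.85 * directions[key] + 0.35 * noise
        else:
            vec = noise
        rows.append(vec / max(np.linalg.norm(vec), 1e-12))
    vocab_map = {t: i for i, t in enumerate(ordered)}
    b = glorot_bound(len(ordered) + 2, dim)
    unk = rng.uniform(-b, b, size=dim)
    matrix = np.vstack(rows + [unk, np.zeros(dim)])
    vocab_map[UNKNOWN_WORD] = len(ordered)
    vocab_map[PAD_WORD] = len(ordered) + 1
    table = EmbeddingTable(vocab=vocab_map, matrix=matrix, trainable=True)
    if path is not None:
        save_word2vec_text(path, table)
    return table


def generate_alternatives(corpus: Sequence[TaggedSentence], rate: float,
                          seed: int = 0) -> List[AltEntity]:
    """GM-style alternative boundaries for a ``rate`` fraction of entities.

    Each selected entity gains a one-token-shorter or one-token-longer
    span (whichever is in range; a seeded coin picks when both are)."""
    if not 0.0 <= rate <= 1.0:
        raise SynthConfigError("rate must lie in [0, 1]")
    from .tagging import bieos_to_spans
    rng = np.random.default_rng(np.random.SeedSequence([seed, 0xA7]))
    out: List[AltEntity] = []
    for i, sent in enumerate(corpus):
        for span in bieos_to_spans(sent.tags):
            ent = AltEntity(i, span)
            if rng.random() < rate:
                options = []
                if span.end - span.start >= 2:
                    options.append(EntitySpan(span.start + 1, span.end, span.type))
                if span.end < len(sent):
                    options.append(EntitySpan(span.start, span.end + 1, span.type))
                if options:
                    ent.alternatives.append(options[int(rng.integers(len(options)))])
            out.append(ent)
    return out
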