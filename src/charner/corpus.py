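"""Corpus I/O: CoNLL-style column files, token normalization and indexing.

The corpus format is the two-column layout of the biomedical shared tasks:
one token per line with its tag in a later whitespace-separated column and a
blank line between sentences.  Tokens are normalized for word-embedding
lookup (lowercase, digit runs collapsed to the literal ``NUM``), while the
character model always sees the raw surface form — case and digits are
exactly the orthography the character attention exists to exploit.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Iterable, List, Mapping, Optional, Sequence

import numpy as np

from .tagging import EntitySpan, TagAlphabet, validate_bieos

UNKNOWN_WORD = "UNKNOWN"
NUM_TOKEN = "NUM"

_NUM_RE = re.compile(r"\d+|NUM")
_WHOLE_NUM_RE = re.compile(r"\d+")


class CorpusFormatError(ValueError):
    """Malformed corpus file (carries the offending line number)."""


@dataclass
class Token:
    surface: str
    normalized: Optional[str] = None
    word_index: Optional[int] = None
    char_indices: Optional[List[int]] = None


@dataclass
class TaggedSentence:
    tokens: List[Token]
    tags: List[str]
    tag_ids: Optional[np.ndarray] = field(default=None, repr=False)

    def __post_init__(self):
        if len(self.tokens) != len(self.tags):
            raise ValueError(f"{len(self.tokens)} tokens vs {len(self.tags)} tags")

    def __len__(self):
        return len(self.tokens)

    @property
    def surfaces(self) -> List[str]:
        return [t.surface for t in self.tokens]

    @classmethod
    def from_pairs(cls, words: Sequence[str], tags: Sequence[str]) -> "TaggedSentence":
        return cls([Token(w) for w in words], list(tags))

    def validate(self):
        validate_bieos(self.tags)


def normalize_token(surface: str, digit_run: bool = True) -> str:
    """Lowercase and replace numbers with the literal ``NUM``.

    With ``digit_run`` (default) every maximal digit run inside a token
    becomes ``NUM`` ("IL-2" -> "il-NUM"); otherwise only tokens that are
    entirely numeric are replaced.  Existing ``NUM`` substrings are kept
    verbatim so the mapping is idempotent.
    """
    if not digit_run and _WHOLE_NUM_RE.fullmatch(surface):
        return NUM_TOKEN
    parts = []
    pos = 0
    for m in _NUM_RE.finditer(surface):
        parts.append(surface[pos:m.start()].lower())
        piece = m.group()
        if piece == NUM_TOKEN or digit_run:
            parts.append(NUM_TOKEN)
        else:
            parts.append(piece)
        pos = m.end()
    parts.append(surface[pos:].lower())
    return "".join(parts)


def read_conll(path, token_column: int = 0, tag_column: int = 1) -> List[TaggedSentence]:
    """Read a CoNLL-style column file into tagged sentences.

    Sentences are split on blank lines; a missing trailing blank line still
    emits the final sentence.  Tags are returned verbatim (scheme conversion
    is a separate step).
    """
    if token_column < 0 or tag_column < 0:
        raise ValueError("column indices must be non-negative")
    sentences: List[TaggedSentence] = []
    words: List[str] = []
    tags: List[str] = []
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                if words:
                    sentences.append(TaggedSentence.from_pairs(words, tags))
                    words, tags = [], []
                continue
            fields = line.split()
            needed = max(token_column, tag_column)
            if len(fields) <= needed:
                raise CorpusFormatError(
                    f"{path}: line {lineno}: expected at least {needed + 1} columns, got {len(fields)}"
                )
            words.append(fields[token_column])
            tags.append(fields[tag_column])
    if words:
        sentences.append(TaggedSentence.from_pairs(words, tags))
    return sentences


def write_conll(path, sentences: Iterable[TaggedSentence]) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for sent in sentences:
            for tok, tag in zip(sent.tokens, sent.tags):
                fh.write(f"{tok.surface}\t{tag}\n")
            fh.write("\n")


class CharAlphabet:
    """Character -> id mapping with dedicated unknown and padding ids."""

    PAD = "<pad>"
    UNK = "<unk>"

    def __init__(self, chars: Iterable[str] = ()):
        self._index = {self.PAD: 0, self.UNK: 1}
        for ch in chars:
            self.add(ch)
        self.frozen = False

    @property
    def pad_id(self):
        return 0

    @property
    def unk_id(self):
        return 1

    def add(self, ch: str) -> int:
        if ch not in self._index:
            if getattr(self, "frozen", False):
                return self.unk_id
            self._index[ch] = len(self._index)
        return self._index[ch]

    def index(self, ch: str) -> int:
        return self._index.get(ch, self.unk_id)

    def freeze(self):
        self.frozen = True

    def __len__(self):
        return len(self._index)

    @classmethod
    def from_sentences(cls, sentences: Iterable[TaggedSentence]) -> "CharAlphabet":
        alpha = cls()
        for sent in sentences:
            for tok in sent.tokens:
                for ch in tok.surface:
                    alpha.add(ch)
        alpha.freeze()
        return alpha


def index_corpus(
    sentences: Sequence[TaggedSentence],
    embedding_vocab: Mapping[str, int],
    char_alphabet: CharAlphabet,
    tag_alphabet: Optional[TagAlphabet] = None,
    digit_run: bool = True,
) -> List[TaggedSentence]:
    """Assign word/char/tag ids in place (and return the same sentences).

    Word ids come from the normalized form (``UNKNOWN`` when absent from the
    embedding vocabulary); character ids from the raw surface.  Tags outside
    ``tag_alphabet`` raise — the alphabet is frozen on the training split.
    """
    unk_id = embedding_vocab[UNKNOWN_WORD]
    for sent in sentences:
        for tok in sent.tokens:
            tok.normalized = normalize_token(tok.surface, digit_run=digit_run)
            tok.word_index = embedding_vocab.get(tok.normalized, unk_id)
            tok.char_indices = [char_alphabet.index(c) for c in tok.surface]
        if tag_alphabet is not None:
            sent.tag_ids = np.asarray(tag_alphabet.encode(sent.tags), dtype=np.int64)
    return sentences


# -- alternative-annotation sidecar (GM-style scoring) ---------------------------

@dataclass
class AltEntity:
    """One gold entity plus its acceptable alternative boundaries."""

    sentence: int
    primary: EntitySpan
    alternatives: List[EntitySpan] = field(default_factory=list)

    @property
    def acceptable(self) -> List[EntitySpan]:
        return [self.primary, *self.alternatives]


def read_alternatives(path) -> List[AltEntity]:
    """Read the alternative-annotation sidecar.

    One record per gold entity, tab-separated::

        <sentence index>\t<type>\t<start>-<end>\t<alt start>-<alt end>;...

    Spans are half-open 0-based token intervals; the fourth column may be
    empty or absent when an entity has no alternatives.
    """
    entities: List[AltEntity] = []
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise CorpusFormatError(f"{path}: line {lineno}: expected >=3 tab-separated fields")
            try:
                sent_idx = int(fields[0])
                etype = fields[1]
                primary = _parse_span(fields[2], etype)
                alts = []
                if len(fields) > 3 and fields[3].strip():
                    alts = [_parse_span(p, etype) for p in fields[3].split(";") if p.strip()]
            except ValueError as err:
                raise CorpusFormatError(f"{path}: line {lineno}: {err}") from None
            entities.append(AltEntity(sent_idx, primary, alts))
    return entities


def write_alternatives(path, entities: Iterable[AltEntity]) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for ent in entities:
            alts = ";".join(f"{a.start}-{a.end}" for a in ent.alternatives)
            fh.write(f"{ent.sentence}\t{ent.primary.type}\t{ent.primary.start}-{ent.primary.end}\t{alts}\n")


def _parse_span(text: str, etype: str) -> EntitySpan:
    start, _, end = text.partition("-")
    return EntitySpan(int(start), int(end), etype)
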