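"""Embedding tables, word2vec-text I/O and weight initialization.

Initialization schemes:

* character embeddings — uniform on [0, 1), dimension 30 by default;
* layer weights and biases — uniform on ±sqrt(6/(nr+nc)) for the owning
  matrix's shape (biases share their matrix's bound);
* the UNKNOWN word row — same bounded-uniform rule for its own shape;
* padding rows — all zeros and never updated.

Only the word2vec *text* dialect is parsed (optional "count dim" header,
then one token and d reals per line).  Binary files should be converted to
text externally, keeping the on-disk inputs auditable.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, Iterable, Optional

import numpy as np

from .corpus import UNKNOWN_WORD

PAD_WORD = "<pad>"


class EmbeddingFormatError(ValueError):
    """Malformed embedding file."""


@dataclass
class EmbeddingTable:
    """Vocabulary -> row mapping over a dense |V| x d matrix.

    ``UNKNOWN`` and padding entries always exist; lookups of tokens outside
    the vocabulary resolve to the UNKNOWN row.
    """

    vocab: Dict[str, int]
    matrix: np.ndarray
    trainable: bool = True
    pad_id: int = field(init=False)
    unk_id: int = field(init=False)

    def __post_init__(self):
        if UNKNOWN_WORD not in self.vocab or PAD_WORD not in self.vocab:
            raise ValueError("embedding table must contain UNKNOWN and padding entries")
        if max(self.vocab.values()) >= self.matrix.shape[0]:
            raise ValueError("vocabulary id exceeds matrix row count")
        self.pad_id = self.vocab[PAD_WORD]
        self.unk_id = self.vocab[UNKNOWN_WORD]

    @property
    def dim(self) -> int:
        return self.matrix.shape[1]

    def __len__(self):
        return len(self.vocab)

    def lookup_id(self, token: str) -> int:
        return self.vocab.get(token, self.unk_id)

    def lookup(self, token: str) -> np.ndarray:
        return self.matrix[self.lookup_id(token)]


def glorot_bound(n_rows: int, n_cols: int) -> float:
    return math.sqrt(6.0 / (n_rows + n_cols))


def init_layer_weights(n_rows: int, n_cols: int, rng: np.random.Generator) -> np.ndarray:
    """Uniform samples on ±sqrt(6/(nr+nc)); pass ``n_cols`` vector length with
    the owning matrix's shape for biases."""
    if n_rows <= 0 or n_cols <= 0:
        raise ValueError("weight shape must be positive")
    b = glorot_bound(n_rows, n_cols)
    return rng.uniform(-b, b, size=(n_rows, n_cols))


def init_bias(length: int, n_rows: int, n_cols: int, rng: np.random.Generator) -> np.ndarray:
    """Bias drawn with the owning matrix's bound (biases are random here,
    not zero)."""
    b = glorot_bound(n_rows, n_cols)
    return rng.uniform(-b, b, size=length)


def init_char_embeddings(alphabet_size: int, dim: int = 30, seed: int = 0) -> EmbeddingTable:
    """Character table with entries uniform on [0, 1); pad row zeroed.

    ``alphabet_size`` counts the full alphabet *including* its pad (id 0)
    and unknown (id 1) entries, matching :class:`~charner.corpus.CharAlphabet`.
    """
    if alphabet_size <= 0 or dim <= 0:
        raise ValueError("alphabet size and dimension must be positive")
    rng = np.random.default_rng(seed)
    matrix = rng.uniform(0.0, 1.0, size=(alphabet_size, dim))
    matrix[0] = 0.0  # pad row
    vocab = {PAD_WORD: 0, UNKNOWN_WORD: 1}
    return EmbeddingTable(vocab=vocab, matrix=matrix, trainable=True)


def random_word_table(tokens: Iterable[str], dim: int, seed: int = 0,
                      trainable: bool = True) -> EmbeddingTable:
    """Word table initialized with the bounded-uniform rule (no pre-trained
    vectors); used when the caller supplies no embedding file."""
    vocab: Dict[str, int] = {}
    for tok in tokens:
        if tok not in vocab:
            vocab[tok] = len(vocab)
    for special in (UNKNOWN_WORD, PAD_WORD):
        if special not in vocab:
            vocab[special] = len(vocab)
    rng = np.random.default_rng(seed)
    matrix = init_layer_weights(len(vocab), dim, rng)
    matrix[vocab[PAD_WORD]] = 0.0
    return EmbeddingTable(vocab=vocab, matrix=matrix, trainable=trainable)


def load_word2vec_text(path, expected_dim: Optional[int] = None,
                       trainable: bool = True, seed: int = 0) -> EmbeddingTable:
    """Load a word2vec text-format embedding file.

    The optional "count dim" header is tolerated.  Vocabulary order follows
    the file; UNKNOWN (bounded-uniform) and padding (zero) rows are appended.
    """
    vocab: Dict[str, int] = {}
    vectors = []
    dim = None
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            parts = line.rstrip("\n").split()
            if not parts:
                continue
            if lineno == 1 and len(parts) == 2:
                try:
                    int(parts[0]), int(parts[1])
                    continue  # header line
                except ValueError:
                    pass
            token, values = parts[0], parts[1:]
            if dim is None:
                dim = len(values)
                if dim == 0:
                    raise EmbeddingFormatError(f"{path}: line {lineno}: no vector components")
            elif len(values) != dim:
                raise EmbeddingFormatError(
                    f"{path}: line {lineno}: expected {dim} components, got {len(values)}"
                )
            if token in vocab:
                continue  # keep first occurrence
            vocab[token] = len(vectors)
            try:
                vectors.append(np.array(values, dtype=np.float64))
            except ValueError:
                raise EmbeddingFormatError(f"{path}: line {lineno}: non-numeric component") from None
    if not vectors:
        raise EmbeddingFormatError(f"{path}: no vectors found")
    if expected_dim is not None and dim != expected_dim:
        raise EmbeddingFormatError(f"{path}: dimension {dim} != expected {expected_dim}")
    rng = np.random.default_rng(seed)
    rows = list(vectors)
    if UNKNOWN_WORD not in vocab:
        vocab[UNKNOWN_WORD] = len(rows)
        b = glorot_bound(len(rows) + 2, dim)
        rows.append(rng.uniform(-b, b, size=dim))
    if PAD_WORD not in vocab:
        vocab[PAD_WORD] = len(rows)
        rows.append(np.zeros(dim))
    return EmbeddingTable(vocab=vocab, matrix=np.vstack(rows), trainable=trainable)


def save_word2vec_text(path, table: EmbeddingTable, header: bool = True) -> None:
    """Write an embedding table in word2vec text format (specials omitted)."""
    items = [(t, i) for t, i in sorted(table.vocab.items(), key=lambda kv: kv[1])
             if t not in (UNKNOWN_WORD, PAD_WORD)]
    with open(path, "w", encoding="utf-8") as fh:
        if header:
            fh.write(f"{len(items)} {table.dim}\n")
        for token, idx in items:
            vec = " ".join(format(v, ".6f") for v in table.matrix[idx])
            fh.write(f"{token} {vec}\n")
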