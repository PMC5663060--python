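"""BIEOS/IOB2 tag schemes, span extraction and the tag alphabet.

Entities are represented as half-open, 0-based token intervals
(``EntitySpan(start, end, type)`` covering ``tokens[start:end]``).  Gold tag
sequences must be scheme-valid; *predicted* sequences may be anything the
decoder emits, so :func:`bieos_to_spans` is total and applies a fixed,
deterministic repair to ill-formed sequences (a stray I-/E- opens a span as
if it were B-; an open span is closed at the first incompatible tag).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, List, Sequence

BIEOS_PREFIXES = ("B", "I", "E", "S")
OUTSIDE = "O"


class TagSchemeError(ValueError):
    """Raised for scheme-invalid gold tag sequences."""


@dataclass(frozen=True, order=True)
class EntitySpan:
    """A typed entity occupying tokens[start:end] (half-open, 0-based)."""

    start: int
    end: int
    type: str

    def __post_init__(self):
        if not (0 <= self.start < self.end):
            raise ValueError(f"invalid span bounds ({self.start}, {self.end})")


def _split(tag: str) -> tuple[str, str | None]:
    if tag == OUTSIDE:
        return OUTSIDE, None
    if len(tag) > 2 and tag[1] == "-" and tag[0] in BIEOS_PREFIXES:
        return tag[0], tag[2:]
    raise TagSchemeError(f"malformed tag {tag!r}")


def validate_bieos(tags: Sequence[str]) -> None:
    """Raise :class:`TagSchemeError` unless ``tags`` is a valid BIEOS sequence."""
    open_type = None
    for i, tag in enumerate(tags):
        prefix, etype = _split(tag)
        if prefix in ("I", "E"):
            if open_type is None or open_type != etype:
                raise TagSchemeError(f"{tag} at position {i} does not continue an open {etype} entity")
            if prefix == "E":
                open_type = None
        else:
            if open_type is not None:
                raise TagSchemeError(f"{tags[i - 1]} at position {i - 1} is not closed before {tag}")
            if prefix == "B":
                open_type = etype
    if open_type is not None:
        raise TagSchemeError(f"entity of type {open_type} still open at end of sentence")


def validate_iob2(tags: Sequence[str]) -> None:
    prev_type = None
    for i, tag in enumerate(tags):
        if tag == OUTSIDE:
            prev_type = None
            continue
        if len(tag) < 3 or tag[1] != "-" or tag[0] not in ("B", "I"):
            raise TagSchemeError(f"malformed IOB2 tag {tag!r} at position {i}")
        prefix, etype = tag[0], tag[2:]
        if prefix == "I" and etype != prev_type:
            raise TagSchemeError(f"I-{etype} at position {i} has no preceding B-/I-{etype}")
        prev_type = etype


def iob2_to_bieos(tags: Sequence[str]) -> List[str]:
    """Convert a valid IOB2 sequence to BIEOS, preserving the span set."""
    validate_iob2(tags)
    out = list(tags)
    n = len(tags)
    for i, tag in enumerate(tags):
        if tag == OUTSIDE:
            continue
        prefix, etype = tag[0], tag[2:]
        nxt = tags[i + 1] if i + 1 < n else OUTSIDE
        continues = nxt != OUTSIDE and nxt[0] == "I" and nxt[2:] == etype
        if prefix == "B":
            out[i] = f"B-{etype}" if continues else f"S-{etype}"
        else:  # I
            out[i] = f"I-{etype}" if continues else f"E-{etype}"
    return out


def bieos_to_iob2(tags: Sequence[str]) -> List[str]:
    """Inverse scheme conversion (valid BIEOS in, valid IOB2 out)."""
    validate_bieos(tags)
    out = []
    for tag in tags:
        if tag == OUTSIDE:
            out.append(OUTSIDE)
            continue
        prefix, etype = tag[0], tag[2:]
        out.append(f"B-{etype}" if prefix in ("B", "S") else f"I-{etype}")
    return out


def bieos_to_spans(tags: Sequence[str]) -> List[EntitySpan]:
    """Extract entity spans; total on arbitrary (possibly invalid) sequences.

    Repair rules for ill-formed predictions: a stray I-/E- opens a new span
    as if it were B-; an open span is closed (and emitted) at the first tag
    that cannot continue it.  On valid input the result is exactly the
    maximal B…E / S groups.
    """
    spans: List[EntitySpan] = []
    open_start = None
    open_type = None

    def close(end: int):
        nonlocal open_start, open_type
        if open_start is not None and end > open_start:
            spans.append(EntitySpan(open_start, end, open_type))
        open_start = open_type = None

    for i, tag in enumerate(tags):
        if tag == OUTSIDE or len(tag) < 3 or tag[1] != "-" or tag[0] not in BIEOS_PREFIXES:
            close(i)
            continue
        prefix, etype = tag[0], tag[2:]
        if prefix == "B":
            close(i)
            open_start, open_type = i, etype
        elif prefix == "S":
            close(i)
            spans.append(EntitySpan(i, i + 1, etype))
        elif prefix == "I":
            if open_type != etype:
                close(i)
                open_start, open_type = i, etype
        else:  # E
            if open_type == etype:
                close(i + 1)
            else:
                close(i)
                spans.append(EntitySpan(i, i + 1, etype))
    close(len(tags))
    return spans


def spans_to_bieos(spans: Iterable[EntitySpan], length: int) -> List[str]:
    """Render disjoint spans as a BIEOS tag sequence of ``length`` tokens."""
    tags = [OUTSIDE] * length
    for sp in sorted(spans):
        if sp.end > length:
            raise ValueError(f"span {sp} exceeds sentence length {length}")
        if sp.end - sp.start == 1:
            tags[sp.start] = f"S-{sp.type}"
        else:
            tags[sp.start] = f"B-{sp.type}"
            for i in range(sp.start + 1, sp.end - 1):
                tags[i] = f"I-{sp.type}"
            tags[sp.end - 1] = f"E-{sp.type}"
    return tags


class TagAlphabet:
    """Bijection between BIEOS tag strings and integer ids.

    ``O`` is always id 0; each entity type contributes B-/I-/E-/S- tags in a
    deterministic order so that identical type sets always yield identical
    alphabets.
    """

    def __init__(self, entity_types: Iterable[str]):
        self.entity_types = tuple(sorted(set(entity_types)))
        self.labels: List[str] = [OUTSIDE]
        for t in self.entity_types:
            self.labels.extend([f"B-{t}", f"I-{t}", f"E-{t}", f"S-{t}"])
        self._index = {lab: i for i, lab in enumerate(self.labels)}

    @classmethod
    def from_tags(cls, tag_sequences: Iterable[Sequence[str]]) -> "TagAlphabet":
        types = set()
        for seq in tag_sequences:
            for tag in seq:
                if tag != OUTSIDE:
                    _, etype = _split(tag)
                    types.add(etype)
        return cls(types)

    def __len__(self):
        return len(self.labels)

    def __contains__(self, label):
        return label in self._index

    def index(self, label: str) -> int:
        try:
            return self._index[label]
        except KeyError:
            raise TagSchemeError(f"tag {label!r} not in alphabet {self.labels}") from None

    def label(self, idx: int) -> str:
        return self.labels[idx]

    def encode(self, tags: Sequence[str]) -> List[int]:
        return [self.index(t) for t in tags]

    def decode(self, ids: Sequence[int]) -> List[str]:
        return [self.labels[i] for i in ids]

    def __eq__(self, other):
        return isinstance(other, TagAlphabet) and self.labels == other.labels

    def __repr__(self):
        return f"TagAlphabet(types={self.entity_types})"
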