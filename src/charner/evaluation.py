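"""Span-level precision / recall / F1 with optional alternative-boundary credit.

A predicted entity is a true positive iff a gold entity in the same
sentence has the identical (start, end, type) — or, when GM-style
alternative annotations are supplied, iff it matches the primary or any
alternative boundary of a not-yet-consumed gold entity of the same type.
Matching is one-to-one (each gold entity credits at most one prediction)
and counts are pooled over the corpus before computing the metrics
(micro-averaging), mirroring the shared tasks' official scorers.

Ill-formed predicted tag sequences are repaired deterministically by the
span extractor; gold sequences are expected to be valid upstream.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass
from typing import Dict, List, Sequence

from .corpus import AltEntity, TaggedSentence
from .tagging import bieos_to_spans


class AlignmentError(ValueError):
    """Gold and predicted corpora do not line up."""


@dataclass(frozen=True)
class EvalResult:
    tp: int
    fp: int
    fn: int

    @property
    def precision(self) -> float:
        return self.tp / (self.tp + self.fp) if self.tp + self.fp else 0.0

    @property
    def recall(self) -> float:
        return self.tp / (self.tp + self.fn) if self.tp + self.fn else 0.0

    @property
    def f1(self) -> float:
        p, r = self.precision, self.recall
        return 2 * p * r / (p + r) if p + r else 0.0

    def __add__(self, other: "EvalResult") -> "EvalResult":
        return EvalResult(self.tp + other.tp, self.fp + other.fp, self.fn + other.fn)


def _check_alignment(gold_tags: Sequence[Sequence[str]],
                     pred_tags: Sequence[Sequence[str]]) -> None:
    if len(gold_tags) != len(pred_tags):
        raise AlignmentError(f"{len(gold_tags)} gold vs {len(pred_tags)} predicted sentences")
    for i, (g, p) in enumerate(zip(gold_tags, pred_tags)):
        if len(g) != len(p):
            raise AlignmentError(f"sentence {i}: {len(g)} gold vs {len(p)} predicted tokens")


def score_tag_sequences(gold_tags: Sequence[Sequence[str]],
                        pred_tags: Sequence[Sequence[str]]) -> EvalResult:
    """Micro-averaged exact span matching over aligned tag sequences."""
    _check_alignment(gold_tags, pred_tags)
    tp = fp = fn = 0
    for g, p in zip(gold_tags, pred_tags):
        gold_spans = set(bieos_to_spans(g))
        pred_spans = set(bieos_to_spans(p))
        hit = len(gold_spans & pred_spans)
        tp += hit
        fp += len(pred_spans) - hit
        fn += len(gold_spans) - hit
    return EvalResult(tp, fp, fn)


def score_corpus(gold: Sequence[TaggedSentence],
                 predicted: Sequence[TaggedSentence]) -> EvalResult:
    return score_tag_sequences([s.tags for s in gold], [s.tags for s in predicted])


def score_with_alternatives(gold: Sequence[TaggedSentence],
                            predicted: Sequence[TaggedSentence],
                            alternatives: Sequence[AltEntity]) -> EvalResult:
    """Exact matching where any acceptable boundary of a gold entity counts.

    Each gold entity is consumed by at most one prediction; predictions are
    matched greedily in sentence order (primary boundaries first).
    """
    gold_tags = [s.tags for s in gold]
    pred_tags = [s.tags for s in predicted]
    _check_alignment(gold_tags, pred_tags)
    per_sentence: Dict[int, List[AltEntity]] = defaultdict(list)
    for ent in alternatives:
        if not 0 <= ent.sentence < len(gold):
            raise AlignmentError(f"alternative record for sentence {ent.sentence} out of range")
        length = len(gold[ent.sentence])
        for span in ent.acceptable:
            if span.end > length:
                raise AlignmentError(
                    f"span {span} exceeds sentence {ent.sentence} length {length}")
        per_sentence[ent.sentence].append(ent)

    tp = fp = fn = 0
    for i, (g, p) in enumerate(zip(gold_tags, pred_tags)):
        entities = per_sentence.get(i)
        if entities is None:
            # no sidecar records: every gold span is its own sole boundary
            entities = [AltEntity(i, sp) for sp in bieos_to_spans(g)]
        preds = bieos_to_spans(p)
        consumed = [False] * len(entities)
        for span in preds:
            matched = False
            # primary boundaries take precedence over alternatives
            for exact_only in (True, False):
                for j, ent in enumerate(entities):
                    if consumed[j] or ent.primary.type != span.type:
                        continue
                    ok = span == ent.primary if exact_only else span in ent.acceptable
                    if ok:
                        consumed[j] = True
                        matched = True
                        break
                if matched:
                    break
            if matched:
                tp += 1
            else:
                fp += 1
        fn += consumed.count(False)
    return EvalResult(tp, fp, fn)


def per_type_breakdown(gold: Sequence[TaggedSentence],
                       predicted: Sequence[TaggedSentence]) -> Dict[str, EvalResult]:
    """Exact-match counts partitioned by entity type.

    A right-boundary/wrong-type prediction is an FP under the predicted type
    and an FN under the gold type; micro totals therefore equal
    :func:`score_corpus`.
    """
    gold_tags = [s.tags for s in gold]
    pred_tags = [s.tags for s in predicted]
    _check_alignment(gold_tags, pred_tags)
    counts: Dict[str, List[int]] = defaultdict(lambda: [0, 0, 0])  # tp, fp, fn
    for g, p in zip(gold_tags, pred_tags):
        gold_spans = set(bieos_to_spans(g))
        pred_spans = set(bieos_to_spans(p))
        for sp in gold_spans & pred_spans:
            counts[sp.type][0] += 1
        for sp in pred_spans - gold_spans:
            counts[sp.type][1] += 1
        for sp in gold_spans - pred_spans:
            counts[sp.type][2] += 1
    return {t: EvalResult(*c) for t, c in sorted(counts.items())}


def format_report(overall: EvalResult,
                  by_type: Dict[str, EvalResult] | None = None) -> str:
    """Plain-text report of overall (and per-type) P/R/F1 with raw counts."""
    lines = ["type\ttp\tfp\tfn\tprecision\trecall\tf1"]

    def row(name: str, r: EvalResult) -> str:
        return (f"{name}\t{r.tp}\t{r.fp}\t{r.fn}\t"
                f"{r.precision:.4f}\t{r.recall:.4f}\t{r.f1:.4f}")

    if by_type:
        for name, r in by_type.items():
            lines.append(row(name, r))
    lines.append(row("overall", overall))
    return "\n".join(lines)
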