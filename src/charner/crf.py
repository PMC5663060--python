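"""Linear-chain CRF: path scoring, exact log-partition, Viterbi, softmax.

The emission matrix F is K x T (``F[i, t]`` scores tag *i* at position *t*).
Transitions live in a (K+1) x (K+1) matrix A whose extra index K doubles as
the START state (row K: START -> tag) and the STOP state (column K:
tag -> STOP); A's START column and STOP row are unused.  A path y_1..y_T
scores

    S(y) = A[START, y_1] + sum_t>1 A[y_{t-1}, y_t] + sum_t F[y_t, t]
           (+ A[y_T, STOP] when the STOP augmentation is on)

All normalization runs in log space.  Ties in Viterbi and the per-position
softmax argmax resolve to the lowest tag index, so decoding is fully
deterministic.
"""

from __future__ import annotations

from typing import Sequence, Tuple

import numpy as np

from . import autodiff as ad
from .autodiff import Tensor


def _check(F: np.ndarray, A: np.ndarray) -> Tuple[int, int]:
    F = np.asarray(F)
    A = np.asarray(A)
    K, T = F.shape
    if A.shape != (K + 1, K + 1):
        raise ValueError(f"transition matrix must be {(K + 1, K + 1)}, got {A.shape}")
    if T < 1:
        raise ValueError("empty emission matrix")
    return K, T


def sentence_score(F: np.ndarray, A: np.ndarray, y: Sequence[int],
                   use_stop: bool = True) -> float:
    """Score of one tag path (transitions plus emissions)."""
    K, T = _check(F, A)
    y = np.asarray(y, dtype=int)
    if len(y) != T:
        raise ValueError(f"path length {len(y)} != sentence length {T}")
    if np.any(y < 0) or np.any(y >= K):
        raise ValueError("tag index out of range")
    score = A[K, y[0]] + F[y[0], 0]
    for t in range(1, T):
        score += A[y[t - 1], y[t]] + F[y[t], t]
    if use_stop:
        score += A[y[-1], K]
    return float(score)


def log_partition(F: np.ndarray, A: np.ndarray, use_stop: bool = True) -> float:
    """log sum over all K^T paths of exp(path score), by the forward
    recursion in log space."""
    K, T = _check(F, A)
    F = np.asarray(F, dtype=np.float64)
    A = np.asarray(A, dtype=np.float64)
    alpha = A[K, :K] + F[:, 0]
    trans = A[:K, :K]
    for t in range(1, T):
        alpha = _lse_step(alpha, trans) + F[:, t]
    if use_stop:
        alpha = alpha + A[:K, K]
    m = alpha.max()
    return float(m + np.log(np.exp(alpha - m).sum()))


def _lse_step(alpha: np.ndarray, trans: np.ndarray) -> np.ndarray:
    scores = alpha[:, None] + trans          # (K, K): prev -> next
    m = scores.max(axis=0)
    return m + np.log(np.exp(scores - m).sum(axis=0))


def log_prob(F: np.ndarray, A: np.ndarray, y: Sequence[int],
             use_stop: bool = True) -> float:
    """Log conditional probability of the path ``y``; always <= 0."""
    return sentence_score(F, A, y, use_stop) - log_partition(F, A, use_stop)


def viterbi(F: np.ndarray, A: np.ndarray, use_stop: bool = True
            ) -> Tuple[np.ndarray, float]:
    """Maximum-score path and its score; ties break to the lowest tag index."""
    K, T = _check(F, A)
    F = np.asarray(F, dtype=np.float64)
    A = np.asarray(A, dtype=np.float64)
    delta = A[K, :K] + F[:, 0]
    back = np.zeros((T, K), dtype=int)
    for t in range(1, T):
        scores = delta[:, None] + A[:K, :K]      # (prev, next)
        back[t] = scores.argmax(axis=0)          # argmax -> first (lowest) index
        delta = scores.max(axis=0) + F[:, t]
    if use_stop:
        delta = delta + A[:K, K]
    last = int(delta.argmax())
    best = float(delta[last])
    path = np.empty(T, dtype=int)
    path[-1] = last
    for t in range(T - 1, 0, -1):
        path[t - 1] = back[t, path[t]]
    return path, best


def softmax_decode(F: np.ndarray) -> np.ndarray:
    """Position-wise argmax of the emissions (the no-CRF ablation decoder);
    ignores transitions entirely."""
    F = np.asarray(F)
    if F.ndim != 2 or F.shape[1] < 1:
        raise ValueError("emission matrix must be K x T with T >= 1")
    return F.argmax(axis=0)


# -- tensor-level pieces used by the training objective ---------------------------

def sentence_score_t(F: Tensor, A: Tensor, y: np.ndarray, use_stop: bool = True) -> Tensor:
    K = F.shape[0]
    T = len(y)
    y = np.asarray(y, dtype=int)
    emit = F[(y, np.arange(T))].sum()
    prev = np.concatenate([[K], y[:-1]])
    trans = A[(prev, y)].sum()
    total = emit + trans
    if use_stop:
        total = total + A[(np.array([y[-1]]), np.array([K]))].sum()
    return total


def log_partition_t(F: Tensor, A: Tensor, use_stop: bool = True) -> Tensor:
    K, T = F.shape
    trans = A[:K, :K]
    alpha = A[K, :K] + F[:, 0]
    for t in range(1, T):
        scores = alpha.reshape((K, 1)) + trans
        alpha = ad.logsumexp(scores, axis=0) + F[:, t]
    if use_stop:
        alpha = alpha + A[:K, K]
    return ad.logsumexp(alpha)


def softmax_nll_t(F: Tensor, y: np.ndarray) -> Tensor:
    """Per-position cross-entropy of the gold tags (softmax-decoder training)."""
    T = len(y)
    gold = F[(np.asarray(y, dtype=int), np.arange(T))].sum()
    return ad.logsumexp(F, axis=0).sum() - gold
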