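"""Sentence encoder: character attention, context windows and (bi)LSTM.

Per token *i* with characters c_1..c_n the character representation is

    h_c^j = tanh(W_c [e_c^{j-2} ; ... ; e_c^{j+2}] + b_c)
    t_c^j = exp(W_t h_c^j + U_t e_w^i + b_t)
    a_c^j = t_c^j / sum_j t_c^j        (elementwise over the d_char dims)
    R_c^i = sum_j a_c^j ⊙ e_c^j

i.e. the attention weights are vector-valued: one weight per embedding
dimension, normalized over the characters of the word dimension-wise.  The
exponential is evaluated with a per-dimension max shift, which leaves the
normalized weights (and their gradients) unchanged.

The token representation is R^i = R_c^i ⊕ e_w^i, windowed as
x_i = R_{i-2} ⊕ ... ⊕ R_{i+2} with zero padding at the boundaries, passed
through one LSTM per direction (standard input/forget/output/candidate
gates, no peepholes, h_0 = c_0 = 0) and combined by
h_t = tanh(W_f [h_fwd ; h_bwd] + b_f).

All internals run on :class:`~charner.autodiff.Tensor`; the module-level
operations accept and return plain NumPy arrays.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Optional, Sequence

import numpy as np

from . import autodiff as ad
from .autodiff import Tensor
from .embeddings import init_bias, init_layer_weights


@dataclass
class EncoderConfig:
    """Architecture switches and sizes (defaults follow the reference setup:
    100-unit LSTM and combiner, ±2 word/char windows, 30-dim characters)."""

    use_char: bool = True
    bidirectional: bool = True
    word_window: int = 2
    char_window: int = 2
    hidden_dim: int = 100
    combiner_dim: int = 100
    char_hidden_dim: int = 50

    def __post_init__(self):
        if self.word_window < 0 or self.char_window < 0:
            raise ValueError("window half-widths must be >= 0")
        if min(self.hidden_dim, self.combiner_dim, self.char_hidden_dim) <= 0:
            raise ValueError("layer dimensions must be positive")


def _tensorize(arrays: dict, trainable: bool = True) -> dict:
    return {k: (v if isinstance(v, Tensor) else Tensor(v, requires_grad=trainable))
            for k, v in arrays.items()}


@dataclass
class CharAttentionParams:
    """W_c/b_c (window hidden layer) and W_t/U_t/b_t (attention scores)."""

    W_c: Tensor
    b_c: Tensor
    W_t: Tensor
    U_t: Tensor
    b_t: Tensor

    @classmethod
    def init(cls, d_char: int, d_word: int, hidden: int, char_window: int,
             rng: np.random.Generator) -> "CharAttentionParams":
        win = (2 * char_window + 1) * d_char
        return cls(
            W_c=Tensor(init_layer_weights(hidden, win, rng), requires_grad=True),
            b_c=Tensor(init_bias(hidden, hidden, win, rng), requires_grad=True),
            W_t=Tensor(init_layer_weights(d_char, hidden, rng), requires_grad=True),
            U_t=Tensor(init_layer_weights(d_char, d_word, rng), requires_grad=True),
            b_t=Tensor(init_bias(d_char, d_char, hidden, rng), requires_grad=True),
        )


@dataclass
class LSTMParams:
    """One direction's gate weights; each matrix is hidden x (input+hidden)."""

    W_i: Tensor
    W_f: Tensor
    W_o: Tensor
    W_g: Tensor
    b_i: Tensor
    b_f: Tensor
    b_o: Tensor
    b_g: Tensor

    @classmethod
    def init(cls, input_dim: int, hidden_dim: int, rng: np.random.Generator) -> "LSTMParams":
        cols = input_dim + hidden_dim
        mats = {f"W_{g}": init_layer_weights(hidden_dim, cols, rng) for g in "ifog"}
        biases = {f"b_{g}": init_bias(hidden_dim, hidden_dim, cols, rng) for g in "ifog"}
        return cls(**_tensorize({**mats, **biases}))

    @property
    def hidden_dim(self) -> int:
        return self.W_i.shape[0]

    @property
    def input_dim(self) -> int:
        return self.W_i.shape[1] - self.hidden_dim


@dataclass
class CombinerParams:
    """The tanh hidden layer f_1 merging the directional LSTM states."""

    W_f: Tensor
    b_f: Tensor

    @classmethod
    def init(cls, in_dim: int, out_dim: int, rng: np.random.Generator) -> "CombinerParams":
        return cls(
            W_f=Tensor(init_layer_weights(out_dim, in_dim, rng), requires_grad=True),
            b_f=Tensor(init_bias(out_dim, out_dim, in_dim, rng), requires_grad=True),
        )


# -- tensor-level building blocks -------------------------------------------------

def _window_index(n: int, half_width: int) -> np.ndarray:
    """Row j selects positions j..j+2w of a zero-padded sequence."""
    w = half_width
    return np.arange(n)[:, None] + np.arange(2 * w + 1)[None, :]


def _windowed(mat: Tensor, half_width: int) -> Tensor:
    """(n, d) -> (n, (2w+1)d): concatenated window rows with zero padding."""
    if half_width == 0:
        return mat
    n, d = mat.shape
    pad = Tensor(np.zeros((half_width, d)))
    padded = ad.concat([pad, mat, pad], axis=0)
    idx = _window_index(n, half_width)
    return padded[idx].reshape((n, (2 * half_width + 1) * d))


def _char_attention_t(char_emb: Tensor, word_emb: Tensor,
                      params: CharAttentionParams, char_window: int,
                      _WcT: Tensor | None = None, _WtT: Tensor | None = None) -> Tensor:
    n = char_emb.shape[0]
    if n == 0:
        raise ValueError("char_attention requires at least one character")
    WcT = params.W_c.T if _WcT is None else _WcT
    WtT = params.W_t.T if _WtT is None else _WtT
    win = _windowed(char_emb, char_window)                       # (n, 5d)
    h = ad.tanh(win @ WcT + params.b_c)                          # (n, hidden)
    scores = h @ WtT + (params.U_t @ word_emb + params.b_t)      # (n, d)
    shift = Tensor(scores.data.max(axis=0))                      # constant; softmax-invariant
    ex = ad.exp(scores - shift)
    weights = ex / ex.sum(axis=0, keepdims=True)                 # (n, d), columns sum to 1
    return (weights * char_emb).sum(axis=0)


def _attention_weights(char_emb: Tensor, word_emb: Tensor,
                       params: CharAttentionParams, char_window: int) -> np.ndarray:
    """The normalized per-dimension weights a_c^j (diagnostics/tests)."""
    with ad.no_grad():
        win = _windowed(char_emb, char_window)
        h = ad.tanh(win @ params.W_c.T + params.b_c)
        scores = (h @ params.W_t.T + (params.U_t @ word_emb + params.b_t)).data
    scores = scores - scores.max(axis=0)
    ex = np.exp(scores)
    return ex / ex.sum(axis=0, keepdims=True)


def _lstm_fused(X: Tensor, W: Tensor, b: Tensor, H: int) -> Tensor:
    """One LSTM direction as a single tape op with hand-derived BPTT.

    ``W`` stacks the input/forget/output/candidate gate matrices row-wise
    (4H x (D+H)); ``b`` the biases.  h_0 = c_0 = 0, no peepholes.
    """
    from scipy.special import expit
    Xd, Wd, bd = X.data, W.data, b.data
    T, D = Xd.shape
    Wx, Wh = Wd[:, :D], Wd[:, D:]
    gates_in = Xd @ Wx.T + bd                 # (T, 4H)
    gates = np.empty((T, 4 * H))
    cs = np.empty((T, H))
    hs = np.empty((T, H))
    h = np.zeros(H)
    c = np.zeros(H)
    for t in range(T):
        pre = gates_in[t] + Wh @ h
        gate = gates[t]
        gate[:3 * H] = expit(pre[:3 * H])
        gate[3 * H:] = np.tanh(pre[3 * H:])
        c = gate[H:2 * H] * c + gate[:H] * gate[3 * H:]
        h = gate[2 * H:3 * H] * np.tanh(c)
        cs[t] = c
        hs[t] = h

    def backward(grad):
        I, F, O, G = (gates[:, k * H:(k + 1) * H] for k in range(4))
        dpre = np.empty((T, 4 * H))
        dh_rec = np.zeros(H)
        dc_next = np.zeros(H)
        for t in range(T - 1, -1, -1):
            dh = grad[t] + dh_rec
            tc = np.tanh(cs[t])
            dc = dh * O[t] * (1.0 - tc * tc) + dc_next
            c_prev = cs[t - 1] if t > 0 else 0.0
            i, f, o, g = I[t], F[t], O[t], G[t]
            dpre[t, :H] = dc * g * i * (1.0 - i)
            dpre[t, H:2 * H] = dc * c_prev * f * (1.0 - f)
            dpre[t, 2 * H:3 * H] = dh * tc * o * (1.0 - o)
            dpre[t, 3 * H:] = dc * i * (1.0 - g * g)
            dh_rec = dpre[t] @ Wh
            dc_next = dc * f
        if X.requires_grad:
            X._accumulate(dpre @ Wx)
        if W.requires_grad:
            h_prev = np.vstack([np.zeros(H), hs[:-1]])
            W._accumulate(np.concatenate([dpre.T @ Xd, dpre.T @ h_prev], axis=1))
        if b.requires_grad:
            b._accumulate(dpre.sum(axis=0))

    return ad.make_op(hs, (X, W, b), backward)


def _lstm_t(xs: Tensor, params: LSTMParams, reverse: bool = False) -> Tensor:
    T, _ = xs.shape
    H = params.hidden_dim
    if reverse:
        xs = xs[np.arange(T - 1, -1, -1)]
    W = ad.concat([params.W_i, params.W_f, params.W_o, params.W_g], axis=0)  # (4H, D+H)
    b = ad.concat([params.b_i, params.b_f, params.b_o, params.b_g])
    out = _lstm_fused(xs, W, b, H)
    if reverse:
        out = out[np.arange(T - 1, -1, -1)]
    return out


def _combine_t(h_fwd: Tensor, h_bwd: Optional[Tensor], params: CombinerParams) -> Tensor:
    merged = h_fwd if h_bwd is None else ad.concat([h_fwd, h_bwd], axis=1)
    return ad.tanh(merged @ params.W_f.T + params.b_f)


def _encode_t(word_ids: np.ndarray, char_ids: Sequence[np.ndarray],
              word_matrix: Tensor, char_matrix: Tensor,
              attention: Optional[CharAttentionParams],
              lstm_fwd: LSTMParams, lstm_bwd: Optional[LSTMParams],
              combiner: CombinerParams, config: EncoderConfig) -> Tensor:
    """Full tensor-level encoder: indexed sentence -> (T, combiner_dim)."""
    word_vecs = word_matrix[np.asarray(word_ids)]               # (T, d_word)
    if config.use_char:
        if attention is None:
            raise ValueError("use_char requires attention parameters")
        WcT, WtT = attention.W_c.T, attention.W_t.T  # hoisted out of the token loop
        reps = []
        for t, cids in enumerate(char_ids):
            ce = char_matrix[np.asarray(cids)]
            rc = _char_attention_t(ce, word_vecs[t], attention, config.char_window,
                                   _WcT=WcT, _WtT=WtT)
            reps.append(ad.concat([rc, word_vecs[t]]))
        R = ad.stack(reps)                                      # (T, d_char + d_word)
    else:
        R = word_vecs
    X = _windowed(R, config.word_window)                        # (T, (2w+1)D)
    hf = _lstm_t(X, lstm_fwd)
    hb = _lstm_t(X, lstm_bwd, reverse=True) if config.bidirectional else None
    return _combine_t(hf, hb, combiner)


# -- public NumPy-facing operations -----------------------------------------------

def char_attention(char_embeddings: np.ndarray, word_embedding: np.ndarray,
                   params: CharAttentionParams, char_window: int = 2) -> np.ndarray:
    """Attention-composed character representation R_c of one word."""
    with ad.no_grad():
        out = _char_attention_t(Tensor(np.atleast_2d(char_embeddings)),
                                Tensor(word_embedding), params, char_window)
    return out.data


def word_representation(R_c: Optional[np.ndarray], e_w: np.ndarray) -> np.ndarray:
    """R = R_c ⊕ e_w (just e_w when the character part is absent)."""
    if R_c is None:
        return np.asarray(e_w, dtype=np.float64)
    return np.concatenate([R_c, e_w])


def window_features(reps: Sequence[np.ndarray], half_width: int) -> List[np.ndarray]:
    """Concatenate each position with its ±half_width neighbours (zero pads)."""
    if len(reps) == 0:
        raise ValueError("window_features requires a non-empty sentence")
    mat = np.asarray(reps, dtype=np.float64)
    with ad.no_grad():
        out = _windowed(Tensor(mat), half_width)
    return list(out.data)


def lstm_forward(xs: Sequence[np.ndarray], params: LSTMParams,
                 reverse: bool = False) -> List[np.ndarray]:
    """Run one LSTM direction; output stays aligned to the input order."""
    with ad.no_grad():
        out = _lstm_t(Tensor(np.asarray(xs, dtype=np.float64)), params, reverse=reverse)
    return list(out.data)


def combine_hidden(h_fwd: np.ndarray, h_bwd: Optional[np.ndarray],
                   params: CombinerParams) -> np.ndarray:
    """h_t = tanh(W_f [h_fwd ; h_bwd] + b_f) for a single position."""
    with ad.no_grad():
        hf = Tensor(np.atleast_2d(h_fwd))
        hb = Tensor(np.atleast_2d(h_bwd)) if h_bwd is not None else None
        out = _combine_t(hf, hb, params)
    return out.data[0]


def encode_sentence(sentence, model, config: EncoderConfig) -> np.ndarray:
    """Feature sequence h_1..h_T for an indexed sentence; (T, combiner_dim).

    ``model`` is a :class:`~charner.training.ModelParams`.
    """
    word_ids = np.asarray([t.word_index for t in sentence.tokens])
    char_ids = [np.asarray(t.char_indices) for t in sentence.tokens]
    with ad.no_grad():
        out = _encode_t(word_ids, char_ids, model.word_matrix, model.char_matrix,
                        model.attention, model.lstm_fwd,
                        model.lstm_bwd if config.bidirectional else None,
                        model.combiner, config)
    return out.data


def export_features(sentences, model, config: EncoderConfig, path) -> None:
    """Write per-token feature vectors h_t as TSV (sentence, position, token,
    then the vector) — the raw-representation inspection hook."""
    with open(path, "w", encoding="utf-8") as fh:
        for si, sent in enumerate(sentences):
            feats = encode_sentence(sent, model, config)
            for ti, (tok, vec) in enumerate(zip(sent.tokens, feats)):
                vals = "\t".join(format(v, ".6g") for v in vec)
                fh.write(f"{si}\t{ti}\t{tok.surface}\t{vals}\n")
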