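"""Maximum-likelihood training with online AdaGrad and L2 regularization.

The minimized per-sentence objective is

    loss = -log P(y | x) + (λ/2) ||Θ||²

over all trainable parameters Θ (zero-padding rows excluded implicitly:
they receive no data gradient and start at zero).  Updates are online
(batch size 1) in a seeded shuffled order per epoch; AdaGrad divides the
base rate α by the root of the accumulated squared gradients *including*
the current one, with no smoothing term — a coordinate whose accumulator
is still zero is simply not updated.

Model selection keeps the parameters of the epoch with the best dev-split
span F1 and stops after ``patience`` epochs without improvement.
"""

from __future__ import annotations

import io
import json
from dataclasses import asdict, dataclass, field
from typing import Dict, Iterator, List, Optional, Sequence, Tuple

import numpy as np

from . import autodiff as ad
from . import crf
from .autodiff import Tensor
from .corpus import CharAlphabet, TaggedSentence, index_corpus
from .embeddings import EmbeddingTable, init_bias, init_layer_weights
from .encoder import (CharAttentionParams, CombinerParams, EncoderConfig,
                      LSTMParams, _encode_t)
from .evaluation import score_tag_sequences
from .tagging import TagAlphabet

ARCHIVE_VERSION = 1


class ConfigError(ValueError):
    pass


class ModelIOError(RuntimeError):
    pass


@dataclass
class TrainConfig:
    learning_rate: float = 0.01
    l2: float = 1e-8
    seed: int = 0
    max_epochs: int = 100
    patience: int = 10
    fine_tune_words: bool = True
    decoder: str = "crf"              # "crf" | "softmax"
    use_stop: bool = True             # STOP transition column learned (off = fixed 0)
    ridge_as_penalty: bool = True     # False restores the printed sign (ridge added
                                      # to the maximized likelihood)
    shuffle: bool = True
    encoder: EncoderConfig = field(default_factory=EncoderConfig)

    def __post_init__(self):
        if self.learning_rate <= 0:
            raise ConfigError("learning_rate must be > 0")
        if self.l2 < 0:
            raise ConfigError("l2 must be >= 0")
        if self.patience < 1 or self.max_epochs < 1:
            raise ConfigError("patience and max_epochs must be >= 1")
        if self.decoder not in ("crf", "softmax"):
            raise ConfigError(f"unknown decoder {self.decoder!r}")


@dataclass
class ModelParams:
    """Every trainable tensor plus the alphabets needed to apply the model."""

    word_table: EmbeddingTable
    char_table: EmbeddingTable
    word_matrix: Tensor
    char_matrix: Tensor
    attention: Optional[CharAttentionParams]
    lstm_fwd: LSTMParams
    lstm_bwd: Optional[LSTMParams]
    combiner: CombinerParams
    emission_W: Tensor
    emission_b: Tensor
    transitions: Tensor
    config: EncoderConfig
    tag_alphabet: TagAlphabet
    char_alphabet: CharAlphabet
    decoder: str = "crf"
    use_stop: bool = True
    digit_run: bool = True

    @classmethod
    def build(cls, word_table: EmbeddingTable, char_table: EmbeddingTable,
              tag_alphabet: TagAlphabet, char_alphabet: CharAlphabet,
              config: EncoderConfig, seed: int = 0, decoder: str = "crf",
              use_stop: bool = True, fine_tune_words: bool = True,
              digit_run: bool = True) -> "ModelParams":
        rng = np.random.default_rng(seed)
        d_word, d_char = word_table.dim, char_table.dim
        K = len(tag_alphabet)
        attention = CharAttentionParams.init(
            d_char, d_word, config.char_hidden_dim, config.char_window, rng
        ) if config.use_char else None
        rep_dim = (d_char + d_word) if config.use_char else d_word
        in_dim = (2 * config.word_window + 1) * rep_dim
        lstm_fwd = LSTMParams.init(in_dim, config.hidden_dim, rng)
        lstm_bwd = LSTMParams.init(in_dim, config.hidden_dim, rng) if config.bidirectional else None
        comb_in = config.hidden_dim * (2 if config.bidirectional else 1)
        combiner = CombinerParams.init(comb_in, config.combiner_dim, rng)
        emission_W = Tensor(init_layer_weights(K, config.combiner_dim, rng), requires_grad=True)
        emission_b = Tensor(init_bias(K, K, config.combiner_dim, rng), requires_grad=True)
        transitions = Tensor(init_layer_weights(K + 1, K + 1, rng), requires_grad=True)
        if not use_stop:
            transitions.data[:, K] = 0.0
        word_matrix = Tensor(word_table.matrix,
                             requires_grad=word_table.trainable and fine_tune_words)
        char_matrix = Tensor(char_table.matrix, requires_grad=char_table.trainable)
        word_table.matrix = word_matrix.data  # share storage after dtype coercion
        char_table.matrix = char_matrix.data
        return cls(word_table, char_table, word_matrix, char_matrix, attention,
                   lstm_fwd, lstm_bwd, combiner, emission_W, emission_b,
                   transitions, config, tag_alphabet, char_alphabet,
                   decoder=decoder, use_stop=use_stop, digit_run=digit_run)

    # -- parameter enumeration ----------------------------------------------------
    def named_tensors(self) -> Iterator[Tuple[str, Tensor]]:
        yield "word_matrix", self.word_matrix
        yield "char_matrix", self.char_matrix
        if self.attention is not None:
            for name in ("W_c", "b_c", "W_t", "U_t", "b_t"):
                yield f"attention.{name}", getattr(self.attention, name)
        for prefix, block in (("lstm_fwd", self.lstm_fwd), ("lstm_bwd", self.lstm_bwd)):
            if block is None:
                continue
            for name in ("W_i", "W_f", "W_o", "W_g", "b_i", "b_f", "b_o", "b_g"):
                yield f"{prefix}.{name}", getattr(block, name)
        yield "combiner.W_f", self.combiner.W_f
        yield "combiner.b_f", self.combiner.b_f
        yield "emission_W", self.emission_W
        yield "emission_b", self.emission_b
        yield "transitions", self.transitions

    def trainable_tensors(self) -> Iterator[Tuple[str, Tensor]]:
        for name, t in self.named_tensors():
            if t.requires_grad:
                yield name, t

    def zero_grads(self):
        for _, t in self.named_tensors():
            t.grad = None

    def n_parameters(self) -> int:
        return sum(t.data.size for _, t in self.named_tensors())

    def snapshot(self) -> Dict[str, np.ndarray]:
        return {name: t.data.copy() for name, t in self.named_tensors()}

    def restore(self, snap: Dict[str, np.ndarray]):
        for name, t in self.named_tensors():
            np.copyto(t.data, snap[name])


# -- objective and gradients --------------------------------------------------------

def _emissions_t(sentence: TaggedSentence, params: ModelParams) -> Tensor:
    word_ids = np.asarray([t.word_index for t in sentence.tokens])
    char_ids = [np.asarray(t.char_indices) for t in sentence.tokens]
    h = _encode_t(word_ids, char_ids, params.word_matrix, params.char_matrix,
                  params.attention, params.lstm_fwd, params.lstm_bwd,
                  params.combiner, params.config)
    return (h @ params.emission_W.T + params.emission_b).T  # (K, T)


def _loss_t(sentence: TaggedSentence, params: ModelParams, lam: float,
            decoder: str, use_stop: bool, ridge_as_penalty: bool = True) -> Tensor:
    if sentence.tag_ids is None:
        raise ConfigError("sentence is not indexed against the model alphabets")
    F = _emissions_t(sentence, params)
    y = sentence.tag_ids
    if decoder == "crf":
        nll = crf.log_partition_t(F, params.transitions, use_stop) \
            - crf.sentence_score_t(F, params.transitions, y, use_stop)
    else:
        nll = crf.softmax_nll_t(F, y)
    if lam:
        ridge = None
        for _, t in params.trainable_tensors():
            sq = (t * t).sum()
            ridge = sq if ridge is None else ridge + sq
        sign = 1.0 if ridge_as_penalty else -1.0
        nll = nll + (sign * lam / 2.0) * ridge
    return nll


def sentence_loss(sentence: TaggedSentence, params: ModelParams, lam: float = 0.0,
                  decoder: Optional[str] = None, use_stop: Optional[bool] = None,
                  ridge_as_penalty: bool = True) -> float:
    """Negative log-likelihood of the gold path plus the ridge term."""
    decoder = params.decoder if decoder is None else decoder
    use_stop = params.use_stop if use_stop is None else use_stop
    with ad.no_grad():
        return float(_loss_t(sentence, params, lam, decoder, use_stop,
                             ridge_as_penalty).data)


def gradients(sentence: TaggedSentence, params: ModelParams, lam: float = 0.0,
              decoder: Optional[str] = None, use_stop: Optional[bool] = None,
              ridge_as_penalty: bool = True) -> Dict[str, np.ndarray]:
    """Analytic gradient of :func:`sentence_loss` for every parameter block.

    Blocks frozen by the fine-tune flags come back as exact zeros.
    """
    decoder = params.decoder if decoder is None else decoder
    use_stop = params.use_stop if use_stop is None else use_stop
    params.zero_grads()
    loss = _loss_t(sentence, params, lam, decoder, use_stop, ridge_as_penalty)
    loss.backward()
    out: Dict[str, np.ndarray] = {}
    for name, t in params.named_tensors():
        out[name] = t.grad.copy() if t.grad is not None else np.zeros_like(t.data)
    return out


# -- AdaGrad -------------------------------------------------------------------------

def adagrad_step(theta, grad, state, alpha: float):
    """One update per the accumulated-gradient rule (denominator includes the
    current gradient; zero-gradient coordinates are untouched)."""
    if alpha <= 0:
        raise ConfigError("alpha must be > 0")
    theta = np.asarray(theta, dtype=np.float64)
    grad = np.asarray(grad, dtype=np.float64)
    state = np.asarray(state, dtype=np.float64) + grad * grad
    step = np.divide(grad, np.sqrt(state), out=np.zeros_like(state), where=state > 0)
    new_theta = theta - alpha * step
    if new_theta.ndim == 0:
        return float(new_theta), float(state)
    return new_theta, state


class AdaGradOptimizer:
    """In-place vectorized AdaGrad over a model's trainable tensors."""

    def __init__(self, params: ModelParams, alpha: float):
        if alpha <= 0:
            raise ConfigError("alpha must be > 0")
        self.alpha = alpha
        self.state: Dict[str, np.ndarray] = {
            name: np.zeros_like(t.data) for name, t in params.trainable_tensors()
        }
        self._params = list(params.trainable_tensors())

    def step(self):
        for name, t in self._params:
            g = t.grad
            if g is None:
                continue
            s = self.state[name]
            s += g * g
            upd = np.divide(g, np.sqrt(s), out=np.zeros_like(s), where=s > 0)
            t.data -= self.alpha * upd


# -- decoding ------------------------------------------------------------------------

def emission_scores(sentence: TaggedSentence, params: ModelParams) -> np.ndarray:
    with ad.no_grad():
        return _emissions_t(sentence, params).data


def predict_tags(params: ModelParams, sentences: Sequence[TaggedSentence],
                 decoder: Optional[str] = None) -> List[List[str]]:
    """Decode BIEOS tag sequences for indexed sentences."""
    decoder = params.decoder if decoder is None else decoder
    alphabet = params.tag_alphabet
    out = []
    for sent in sentences:
        F = emission_scores(sent, params)
        if decoder == "crf":
            path, _ = crf.viterbi(F, params.transitions.data, params.use_stop)
        else:
            path = crf.softmax_decode(F)
        out.append(alphabet.decode(path))
    return out


# -- training loop -------------------------------------------------------------------

def train(train_corpus: Sequence[TaggedSentence], dev_corpus: Sequence[TaggedSentence],
          params: ModelParams, config: TrainConfig, verbose: int = 0
          ) -> Tuple[ModelParams, List[dict]]:
    """Online AdaGrad training with best-dev model selection.

    Both corpora must already be indexed against the model's alphabets.
    Returns the parameters of the best dev-F1 epoch and the per-epoch log
    (epoch, mean train loss, dev precision/recall/F1).
    """
    if len(train_corpus) == 0:
        raise ConfigError("empty training corpus")
    rng = np.random.default_rng(config.seed)
    optimizer = AdaGradOptimizer(params, config.learning_rate)
    log: List[dict] = []
    best_f1 = -1.0
    best_snap = params.snapshot()
    best_epoch = 0
    bad = 0
    n = len(train_corpus)
    for epoch in range(1, config.max_epochs + 1):
        order = rng.permutation(n) if config.shuffle else np.arange(n)
        total = 0.0
        for idx in order:
            sent = train_corpus[idx]
            params.zero_grads()
            loss = _loss_t(sent, params, config.l2, config.decoder,
                           config.use_stop, config.ridge_as_penalty)
            loss.backward()
            optimizer.step()
            total += float(loss.data)
        dev = dev_corpus if len(dev_corpus) else train_corpus
        pred = predict_tags(params, dev, decoder=config.decoder)
        result = score_tag_sequences([s.tags for s in dev], pred)
        record = {"epoch": epoch, "train_loss": total / n,
                  "dev_precision": result.precision, "dev_recall": result.recall,
                  "dev_f1": result.f1}
        log.append(record)
        if verbose:
            print(f"epoch {epoch}: loss {record['train_loss']:.4f} "
                  f"dev F1 {result.f1:.4f}")
        if result.f1 > best_f1 + 1e-12:
            best_f1 = result.f1
            best_snap = params.snapshot()
            best_epoch = epoch
            bad = 0
        else:
            bad += 1
            if bad >= config.patience:
                break
    params.restore(best_snap)
    for rec in log:
        rec["best_epoch"] = best_epoch
    return params, log


def write_training_log(path, log: Sequence[dict]) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("epoch\ttrain_loss\tdev_precision\tdev_recall\tdev_f1\n")
        for rec in log:
            fh.write(f"{rec['epoch']}\t{rec['train_loss']:.6f}\t"
                     f"{rec['dev_precision']:.6f}\t{rec['dev_recall']:.6f}\t"
                     f"{rec['dev_f1']:.6f}\n")


# -- model archive -------------------------------------------------------------------

def save_model(path, params: ModelParams) -> None:
    """Write a single-file archive: all tensors plus alphabets and config."""
    meta = {
        "version": ARCHIVE_VERSION,
        "encoder": asdict(params.config),
        "decoder": params.decoder,
        "use_stop": params.use_stop,
        "digit_run": params.digit_run,
        "word_vocab": [t for t, _ in sorted(params.word_table.vocab.items(),
                                            key=lambda kv: kv[1])],
        "word_trainable": params.word_table.trainable,
        "char_symbols": [c for c, _ in sorted(params.char_alphabet._index.items(),
                                              key=lambda kv: kv[1])],
        "entity_types": list(params.tag_alphabet.entity_types),
        "fine_tune_words": params.word_matrix.requires_grad,
    }
    arrays = {f"tensor::{name}": t.data for name, t in params.named_tensors()}
    with open(path, "wb") as fh:
        np.savez(fh, meta=np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8),
                 **arrays)


def load_model(path) -> ModelParams:
    try:
        with open(path, "rb") as fh:
            archive = np.load(io.BytesIO(fh.read()), allow_pickle=False)
        meta = json.loads(bytes(archive["meta"]))
    except Exception as err:
        raise ModelIOError(f"cannot read model archive {path}: {err}") from None
    if meta.get("version") != ARCHIVE_VERSION:
        raise ModelIOError(f"unsupported archive version {meta.get('version')}")
    config = EncoderConfig(**meta["encoder"])
    word_vocab = {t: i for i, t in enumerate(meta["word_vocab"])}
    word_table = EmbeddingTable(word_vocab, np.array(archive["tensor::word_matrix"]),
                                trainable=meta["word_trainable"])
    char_symbols = meta["char_symbols"]
    char_alpha = CharAlphabet()
    for c in char_symbols[2:]:  # pad/unk already present
        char_alpha.add(c)
    char_alpha.freeze()
    char_table = EmbeddingTable({CharAlphabet.PAD: 0, "UNKNOWN": 1},
                                np.array(archive["tensor::char_matrix"]))
    tag_alphabet = TagAlphabet(meta["entity_types"])
    params = ModelParams.build(word_table, char_table, tag_alphabet, char_alpha,
                               config, seed=0, decoder=meta["decoder"],
                               use_stop=meta["use_stop"],
                               fine_tune_words=meta["fine_tune_words"],
                               digit_run=meta["digit_run"])
    for name, t in params.named_tensors():
        key = f"tensor::{name}"
        if key not in archive:
            raise ModelIOError(f"archive missing tensor {name}")
        stored = archive[key]
        if stored.shape != t.data.shape:
            raise ModelIOError(f"shape mismatch for {name}: "
                               f"{stored.shape} vs {t.data.shape}")
        np.copyto(t.data, stored)
    return params


def index_for_model(params: ModelParams, sentences: Sequence[TaggedSentence],
                    with_tags: bool = True) -> List[TaggedSentence]:
    """Index raw sentences against a loaded/trained model's alphabets."""
    return index_corpus(sentences, params.word_table.vocab, params.char_alphabet,
                        params.tag_alphabet if with_tags else None,
                        digit_run=params.digit_run)
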