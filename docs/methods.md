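# Methods

## Model

`charner` tags pre-tokenized biomedical sentences with BIEOS labels
(B-/I-/E- for multi-token entity positions, S- for single-token mentions,
O outside) and scores predictions by exact span match.  The model is a
linear-chain CRF over features produced by a recurrent encoder:

**Input layer.**  Each token contributes two views.  The *word* view is a
row of a pre-trained embedding table, looked up by the normalized form
(lowercased, digit runs replaced by the literal `NUM`); tokens outside the
embedding vocabulary map to a dedicated `UNKNOWN` row.  The *character*
view is computed by an attention composition over the token's raw surface
characters c_1..c_n:

    h_c^j = tanh(W_c [e_c^{j-2} ; … ; e_c^{j+2}] + b_c)
    t_c^j = exp(W_t h_c^j + U_t e_w + b_t)
    a_c^j = t_c^j / Σ_j t_c^j            (elementwise)
    R_c   = Σ_j a_c^j ⊙ e_c^j

The attention weights are *vector-valued* — one weight per embedding
dimension, normalized over the characters dimension-wise.  This is the
reading under which the Hadamard product in the composition is meaningful
(a scalar-weight variant would reduce ⊙ to ordinary scaling); the scores
are affine images of vectors, and the normalization divides elementwise.
The exponential is evaluated with a per-dimension max shift, which is
exact for the normalized weights and their gradients.

The token representation R = R_c ⊕ e_w (or e_w alone with `use_char=False`)
is windowed, x_i = R_{i-2} ⊕ … ⊕ R_{i+2}, with zero vectors past the
sentence boundary.  The same zero-pad convention is used for the character
window inside the attention, rather than learned boundary symbols — one
convention everywhere makes the boundary behaviour testable in closed
form.

**Recurrence.**  One LSTM per direction (standard input/forget/output/
candidate gates, no peepholes, h_0 = c_0 = 0) runs over the windowed
inputs; a tanh layer merges the two directions,
h_t = tanh(W_f [h→_t ; h←_t] + b_f).  No gate equations beyond the plain
formulation are assumed, and there is no dropout and no stacking.

**CRF.**  A learned affine map sends each h_t to K tag scores, forming the
emission matrix F (K × T).  Transitions live in a (K+1) × (K+1) matrix
whose extra index doubles as START (row) and STOP (column); a path scores
Σ_t (A[y_{t-1}, y_t] + F[y_t, t]) + A[y_T, STOP].  The START/STOP
augmentation is the standard completion of a path score whose y_0 is
otherwise undefined; `use_stop=False` pins the STOP column at zero for a
minimal variant.  All normalization runs in log space (forward recursion
with log-sum-exp); decoding is Viterbi with ties broken to the lowest tag
index, so outputs are deterministic.  No hard BIEOS constraints are
imposed at decode time — the transitions must learn them — and ill-formed
predictions are repaired deterministically during span extraction (a stray
I-/E- opens a span as if B-; an open span closes at the first incompatible
tag).

**The softmax ablation** (`decoder="softmax"`) replaces the CRF by
independent per-position cross-entropy training and per-position argmax
decoding; the transition matrix is then neither used nor updated.

## Training

The minimized per-sentence loss is −log P(y|x) + (λ/2)‖Θ‖² over all
trainable parameters.  The ridge term is a *penalty*: a formulation that
adds it to the maximized likelihood would reward weight growth, so the
package treats that sign as an error; `ridge_as_penalty=False` restores it
for auditing.  Updates are online (one sentence per step) in a seeded
shuffled order.  AdaGrad divides the base rate α by √(Σ_{τ≤t} g²) —
the accumulator *includes* the current gradient, there is no ε smoothing,
and a coordinate whose accumulator is still zero is left untouched.
Frozen blocks (`fine_tune_words=False`) receive exactly zero gradient and
are excluded from the ridge.

Gradients come from a small reverse-mode autodiff engine over float64
NumPy arrays (`charner.autodiff`); the LSTM layer is a single fused tape
operation with a hand-derived backward pass for speed.  Every block —
attention, both LSTM directions, combiner, emission map, transitions, both
embedding tables — is verified against central finite differences at step
1e-5 (max relative error < 1e-4 in the suite, observed ≈ 5e-6).

Model selection keeps the epoch with the best dev-split span F1 (an
internal seeded 10% split of the training data when no dev set is given)
and stops after `patience` epochs without improvement.  The epoch budget,
stopping rule and shuffle policy are artifact choices (defaults:
`max_epochs=100`, `patience=10`).

## Defaults

| parameter | default | note |
| --- | --- | --- |
| word embedding dim | 50 | matches common 50-dim pre-trained vectors |
| char embedding dim | 30 | init uniform [0, 1); pad row zero |
| char attention hidden | 50 | size unstated in the reference setup; insensitive |
| LSTM hidden / combiner | 100 / 100 | reference sizes |
| word / char window | ±2 / ±2 | zero-padded |
| α (AdaGrad) / λ (L2) | 0.01 / 1e-8 | reference values |
| layer weights & biases | U[±√(6/(nr+nc))] | biases use the owning matrix's bound |
| UNKNOWN word row | same bounded-uniform rule | undefined in the reference setup |

Word2vec *text* format is the only embedding dialect parsed; binary files
should be converted externally (keeps the inputs auditable).  "Each
number" in the normalization is read as every maximal digit run
("IL-2" → "il-NUM"), maximizing vocabulary hits for alphanumeric tokens;
`digit_run=False` switches to whole-token replacement.  To keep
normalization idempotent with the literal `NUM` placeholder, existing
`NUM` substrings are preserved verbatim (an all-caps token containing
"NUM" is the one corner where this shows).

## Synthetic corpora

The generator (`charner.synth`) emulates the *shape* of gene-mention
corpora, not their text: entities of 1–5 tokens (40% single-token, 15%
longer than three — the published span statistics of the JNLPBA-style
data, used as generator defaults, not as claims about real corpora),
type-specific suffix morphemes inside entity tokens, optional trigger
words before mentions, and a filler vocabulary elsewhere.  Tokens are
random letter strings, so no real gene names appear anywhere in the
tests.  Two engineered variants isolate single signals:

* **transition** — entity tokens come from a shared type-neutral
  vocabulary except the *final* token of each mention, which carries the
  only lexical type cue.  The paired experiment decodes with a causal
  encoder (forward LSTM, no context window, no characters) in both arms,
  so per-position argmax is blind to the cue at the earlier entity
  positions — its best strategy is a fixed type guess, capped near the
  coin-flip score — while Viterbi propagates the entity-final cue
  backward through type-consistent transitions.  This is the corpus on
  which CRF decoding must beat softmax decoding.  (An earlier all-neutral
  design, with the type a pure coin flip, turned out not to separate the
  decoders: a collapsed softmax is just as consistent as the CRF there,
  and both sit at the coin-flip ceiling.)
* **morphology** — entity tokens are fresh random strings excluded from
  the embedding vocabulary, carrying a deterministic type suffix; the
  word-only model can find boundaries (everything unknown is an entity)
  but not types.  This is the corpus on which the character
  representation must beat the word-only model.

What passing these tests shows: the implementation can represent and learn
the signals the architecture was designed for, and the ablations point in
the documented directions.  What it does not show: performance on real
biomedical text, whose lexical ambiguity, annotation inconsistency and
long-tail morphology the generator deliberately does not simulate.

## Reference experiments and sizes

`charner.experiments` fixes the benchmark runs: overfitting a 10-sentence
corpus at the default hyperparameters; learnability on the default
2000-sentence corpus (F1 ≥ 0.95 on the held-out split, typically reached
within 3 epochs); and the two ablation contrasts on 400-sentence variant
corpora with a reduced 50-unit network — the separations there are
structural, not capacity-driven, and the smaller network keeps the runs
desk-scale.  All experiments are pure functions of their seed.

## Numerical choices and edge cases

* float64 throughout; log-sum-exp with max shift everywhere an exponential
  appears.
* Viterbi and softmax argmax ties resolve to the lowest tag index.
* Zero-length character sequences are rejected (tokens are never empty);
  empty corpora raise configuration errors.
* Padding rows of both embedding tables are zero, get no data gradient and
  are excluded from the ridge, so they stay exactly zero.
* The AdaGrad guard skips coordinates with a zero accumulator rather than
  adding an ε to the denominator, matching the printed update rule.

## Known limitations

* Desk-scale CPU training only; no mini-batching, no GPU.
* Token-level spans only — no character-offset scoring of the GM
  `GENE.eval` kind.
* Single-layer LSTMs; no stacked or residual variants.
* The scalar-weight reading of the attention (W_t as a row vector) is not
  implemented; the vector reading is the package's interpretation.
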