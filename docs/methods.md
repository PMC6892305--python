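# Methods

## Scope and shape

`medrelex` is a desk-scale implementation of relation extraction by
pre-training a transformer encoder and fine-tuning it through a
convolutional head. The library is organized around a statsmodels-style
pair of objects — `RelationModel` (data + encoder + configuration) whose
`fit()` returns `RelationResults` (fitted model, training history,
held-out metrics, `summary()`) — on top of a functional layer
(`finetune`, `predict`, `cross_validate`) and format/tooling modules
(corpus IO, sample generation, tokenizer, synthetic data, CLI).

All numerics run on a small reverse-mode automatic-differentiation
engine (`medrelex.autodiff`) over float64 NumPy arrays. It implements
exactly the operator set the model needs (broadcast arithmetic, batched
matmul, reductions, `log_softmax`, embedding lookup with scatter-add
backward, slicing/concatenation, GELU/ReLU/tanh/erf, inverted dropout)
plus Adam and global-norm gradient clipping. Gradients are verified
against central finite differences in the test suite.

## Input representation

A relation instance is the sentence pair (entity names, context
document), laid out as `[CLS] A [SEP] B [SEP] [PAD]…` and padded to a
fixed length. Segment ids are 0 through the first `[SEP]` and 1 after
it; the attention mask is 0 exactly on padding. Over-long pairs are
truncated token-by-token from the end of whichever side is currently
longer — a rule that in practice always trims the abstract and
preserves the entity names. The input embedding of a token is the
*exact* elementwise sum of its token, segment and position rows
(`embed` exposes the raw sum; invariants test it cell by cell).

WordPiece tokenization is greedy longest-match-first with `##`
continuations, `[UNK]` for unmatchable words, a 100-character word
cap, lowercasing, stand-alone punctuation and per-character CJK
splitting (the convention of the uncased English models).
`build_vocab` produces a miniature vocabulary: the five specials, one
entry plus one `##` continuation per corpus character (guaranteeing 0%
`[UNK]` on the corpus itself, hence the floor
`target_size ≥ 5 + 2·|alphabet|`), then whole words by descending
frequency with lexicographic tie-breaks.

## Encoder

Standard post-norm transformer layers: multi-head scaled dot-product
attention with an additive −1e9 bias on padded *key* positions,
residual + LayerNorm (ε = 1e-6), position-wise feed-forward
(GELU, inner size F = 4H by default), residual + LayerNorm. Position
embeddings are learned. A LayerNorm is applied over the embedding sum
before the first layer; without it, first-layer attention logits at the
0.02-scale truncated-normal initialization are O(1e-4) and their
gradients vanish — measured, this pinned the miniature benchmark at the
majority-class plateau. A zero-layer encoder therefore returns the
*normalized* embedding sum.

Parameter accounting (`count_parameters`) covers the trunk: embedding
tables (+ their LayerNorm), per-layer attention/FFN/normalization
weights, and the tanh pooler over the first token. At the base geometry
(L=12, H=768, A=12, F=3072, V=30522, P=512) the closed form gives
109,482,240 ≈ 1.10e8, and it equals element-wise enumeration of an
instantiated checkpoint for any configuration. The masked-LM and
next-sentence heads live in separate `mlm/*`, `nsp/*` namespaces and are
excluded from the trunk count; fine-tuned head parameters share the
checkpoint container under `cnn/*` or `lin/*`.

Checkpoints are a directory with a JSON manifest (geometry, shape table,
format version) plus an `.npz` of named arrays; loading cross-checks
every shape.

## Pre-training

Two objectives, summed: (i) masked-token cross-entropy — 15% of
non-special positions (at least one) are selected; 80% become `[MASK]`,
10% a random vocabulary token, 10% stay; the decoder is tied to the
token embedding table; (ii) next-sentence cross-entropy over
consecutive-sentence pairs, half with the second sentence replaced by a
sentence from a *different* document, IsNext/NotNext counts within one
of each other per epoch. The NSP head reads a masked-mean of the final
token states through its own tanh dense layer rather than the `[CLS]`
pooler: at miniature scale the `[CLS]` state is nearly constant at
initialization (its pooled features had standard deviation ~1e-3 across
inputs), an information bottleneck that blocked any NSP learning within
the step budget; mean pooling is content-bearing from step one. The
classification-time pooler over `[CLS]` is unchanged.

Optimization: Adam, fixed learning rate (1e-3 for miniature
pre-training), global-norm clip 1.0, non-finite losses abort with
diagnostics. Everything is driven by one seeded generator.

## Sample generation

Positive samples are the annotated pairs, labeled "1"; the entity name
entering sentence A is the surface form of the concept's *first* mention
(lowercased for uncased models). Negatives are unannotated
chemical × disease concept-id pairs drawn uniformly *without
replacement* at `neg_per_pos` = 1 by default; a short pool is exhausted
with a warning. Two balancing modes exist: per-document (each document's
negatives match its own positive count — the default, and the mode the
worked example's arithmetic follows: 2 positives drawn against a 3-pair
pool) and corpus-wide (the negative budget is drawn from the pooled
unannotated pairs of all documents, covering relation-free documents).
Undirected relation pairs are deduplicated irrespective of order;
directed (temporal) labels pass through `to_multiclass_instances`
unchanged with a sorted label set.

TCM-style tables carry no context; `attach_context_by_cooccurrence`
keeps exactly the instances whose two names both occur (case-insensitive
substring) in some abstract, the first match supplying the context, and
logs the dropped count.

## Fine-tuning

The head consumes the final encoder states: per window length w (3/4/5,
100 maps each), a valid 1-d convolution over full-H slices, bias, ReLU,
then max over the window positions that lie entirely inside the
unpadded sequence (a sequence shorter than a window contributes
ReLU(bias)). Features pass dropout 0.5 and an affine softmax
classifier. The baseline linear head applies dropout + affine + softmax
to the pooled `[CLS]` state.

The ranking loss pairs positives and negatives within each mini-batch
by shuffled index, cycling the shorter side (an all-pairs option
exists); the per-batch loss is normalized by the number of pairs so the
learning rate is batch-size independent; a single-class batch falls back
to cross-entropy. Scores are validated to lie in [0, 1]. Fine-tuning
uses Adam at a fixed learning rate (5e-5 default, following the printed
setting for the full-scale model; the miniature benchmark uses 1e-3, an
appropriate scale for a 2-layer, 64-hidden encoder trained for a few
hundred steps), clip 1.0. With `freeze_encoder` the encoder is excluded
from the optimizer and stays bit-identical; otherwise the head error
back-propagates into every encoder parameter including the embeddings.
The historical static-embedding baseline (AdaDelta ρ = 0.95) is
structurally supported by freezing randomly initialized embeddings; it
is not part of the tested surface.

`cross_validate` wraps scikit-learn's `StratifiedKFold`
(shuffled, seeded); classes smaller than k trigger a warning and plain
`KFold`. Evaluation follows P = TP/(TP+FP), R = TP/(TP+FN),
F1 = 2PR/(P+R) with 0/0 := 0, per class and micro-averaged
(pooled counts); for the binary tasks the report is the positive-class
row, whose micro average coincides with it.

## Synthetic data

`generate_relation_corpus` emulates abstract-level annotated corpora:
documents with typed, offset-exact chemical/disease mentions where a
pair is related *iff* its names are joined by a lexical trigger
("induced"/"caused") inside one sentence; unrelated co-occurring pairs
use a neutral connective instead. A rule-based trigger matcher
(`trigger_oracle_relations`) recovers the gold annotations with F1 = 1.0
on default settings — the separability guarantee the benchmark relies
on. Defaults are one chemical and one disease per document, so an
instance's label is decided by a trigram local to its own context; this
is deliberate: with several pairs per document, positive and negative
samples share sentence B verbatim and the label requires binding the
A-pair to the matching B-sentence through attention, which a 2-layer,
64-hidden encoder trained on ~500 instances could not escape the
majority-class plateau on (measured across learning rates, losses and
epochs). That harder relational regime remains available via
`diseases_per_doc > 1`, and difficulty knobs (`trigger_dropout`,
`distractor_triggers`) corrupt the signal further. Consequently, passing
the miniature benchmark demonstrates the pipeline's mechanics and the
value of pre-training at small scale — not that the architecture solves
multi-pair abstract-level corpora, which in the full-scale setting
relies on a 12-layer encoder pre-trained on billions of words.

`generate_pretrain_corpus` produces sentence-segmented multi-document
text with (i) Zipf-weighted filler (rank-1 : rank-10 frequency ratio
lands in [5, 20]), (ii) a per-document signature — a topic slice of the
vocabulary plus two recurring entity names — giving consecutive
sentences the shared lexical signature next-sentence prediction needs,
and (iii) occasional trigger/connective tokens so their embeddings are
covered. The mixture (20% entities / 5% links / 40% topic / 35% Zipf)
balances the Zipf audit against the NSP signal. English-only; the CJK
code path is exercised with transliterated tokens.

The printed worked-example record ships as `fixture_1601297()`. Its
abstract uses the serial-comma reading ("…ischemia, and bundle branch
block."), under which all nine printed mention offsets verify exactly
against `title + " " + abstract` with a single separating space,
0-based and end-exclusive; the title is reconstructed from the sample
documents that quote it.

## Miniature benchmark and its sizes

The self-contained benchmark (`medrelex.benchmark`) uses: ~880
single-pair documents (500 train / 150 test instances, split by
document so contexts never leak), a 135-token WordPiece vocabulary, an
L=2/H=64/A=2/F=256 encoder, 35 pre-training epochs (~1850 steps, batch
16, length 24) and 5 fine-tuning epochs (batch 20, length 48, ranking
loss). These sizes keep a full three-seed directional comparison —
fine-tuned-unfrozen vs frozen-encoder vs random-initialization — to a
few minutes on one CPU while leaving the claims it tests comfortably
away from thresholds (held-out F1 ≈ 1.0 vs the 0.9 bar; NSP probe
0.57–0.65 vs chance; masked-token perplexity ≈ 30 vs the 135-way
uniform baseline). Ties are allowed in the directional comparison: on
the easy default regime the random-initialization baseline also
solves the task, and the inequality is carried by the frozen-encoder
arm; pre-training's value shows in faster convergence rather than the
ceiling.

## Numerical choices and degenerate inputs

- Attention masking: additive −1e9 on padded keys; padded queries
  produce rows that are ignored downstream (max-pooling and losses mask
  them), and padding invariance of unpadded rows is tested to 1e-6.
- Max-over-time ties split gradient evenly among maximizers.
- LayerNorm ε = 1e-6; GELU is exact (erf-based).
- `prf` defines 0/0 as 0 for P, R and F1.
- Mask selection takes `max(1, ⌊0.15·n⌋)` positions.
- All stage seeds derive from one global seed by hashing the stage name
  (SHA-256, reduced below 2³¹).

## Known limitations

- No warmup/decay schedules, mixed precision or multi-device training;
  runtimes target miniature geometries (the base geometry is supported
  structurally and by parameter accounting, not by desk-scale training).
- The i2b2-style XML dialect is out of scope; multi-class corpora enter
  through the canonical 7-column TSV. Official challenge scorers
  (temporal-closure partial credit) are not reimplemented; aggregation
  is plain micro-averaging.
- Synthetic text is not biomedical language; passing tests demonstrate
  the pipeline's correctness and the pre-training/fine-tuning dynamics,
  not clinical-grade extraction quality.
- Loading external word-embedding files for the static baseline is not
  implemented.
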