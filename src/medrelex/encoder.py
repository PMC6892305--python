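"""Transformer encoder stack with masked-token and next-sentence pre-training.

The input representation sums three learned embeddings per position —
token, segment and position — exactly (:func:`embed`).  Each encoder layer
applies multi-head scaled dot-product self-attention (softmax(QK'/sqrt(d))V
over unpadded positions) with residual connection and layer
normalization, then a position-wise feed-forward network (GELU) with its
own residual and normalization.  Geometry is configurable from miniature
(2 layers, 64 hidden) to the 12-layer / 768-hidden / 12-head base
configuration, whose trunk counts ~110M parameters.

Pre-training optimizes the sum of two cross-entropies: predicting
randomly masked tokens from bidirectional context (15% of positions; of
those 80% become ``[MASK]``, 10% a random token, 10% stay) and deciding
whether sentence B really follows sentence A (IsNext vs NotNext, balanced
50/50 per epoch).  Learned position embeddings, GELU, post-layer
normalization and a layer normalization over the embedding sum follow
the standard recipe (without the embedding normalization, first-layer
attention logits are tiny at initialization and gradients vanish); the
raw additive sum itself is exposed by :func:`embed`.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import numpy as np

from .autodiff import Adam, Tensor, clip_global_norm, concat, embedding, gelu
from .wordpiece import CLS, MASK, SEP, TokenSequence, Vocabulary, encode_pair

__all__ = [
    "EncoderConfig", "EmbeddingTables", "EncoderParams", "PretrainBatch",
    "embed", "encoder_layer", "encode", "count_parameters",
    "mask_tokens", "make_nsp_pairs", "pretrain", "PretrainSchedule",
]

logger = logging.getLogger(__name__)

_NEG_BIG = -1e9  # additive attention bias on padded positions


@dataclass(frozen=True)
class EncoderConfig:
    """Encoder geometry: layers L, hidden H, heads A, feed-forward F."""

    n_layers: int
    hidden: int
    n_heads: int
    vocab_size: int
    max_positions: int
    ff_inner: int | None = None
    dropout: float = 0.1

    def __post_init__(self) -> None:
        if self.n_layers < 0:
            raise ValueError("n_layers must be >= 0")
        if self.hidden % self.n_heads:
            raise ValueError(f"hidden {self.hidden} not divisible by heads {self.n_heads}")
        if self.ff_inner is None:
            object.__setattr__(self, "ff_inner", 4 * self.hidden)

    @property
    def head_dim(self) -> int:
        return self.hidden // self.n_heads


def count_parameters(config: EncoderConfig) -> int:
    """Closed-form element count of the encoder trunk (embeddings,
    attention and feed-forward layers with their normalizations, pooler).

    At the base geometry (12 layers, 768 hidden, 12 heads, 30522-token
    vocabulary, 512 positions) this gives ~1.10e8.
    """
    h, f = config.hidden, config.ff_inner
    emb = config.vocab_size * h + 2 * h + config.max_positions * h + 2 * h
    per_layer = (
        4 * (h * h + h)        # Q, K, V and output projections
        + 2 * h                # attention layer norm
        + h * f + f            # feed-forward in
        + f * h + h            # feed-forward out
        + 2 * h                # feed-forward layer norm
    )
    pooler = h * h + h
    return emb + config.n_layers * per_layer + pooler


@dataclass
class EmbeddingTables:
    """The three input embedding tables (token V x H, segment 2 x H, position P x H)."""

    token: np.ndarray
    segment: np.ndarray
    position: np.ndarray


class EncoderParams:
    """Named parameter tensors for the encoder trunk plus optional head namespaces.

    Trunk names: ``embeddings/*``, ``layer<i>/*`` and ``pooler/*``; the
    pre-training heads live under ``mlm/*`` and ``nsp/*`` and are not part
    of the trunk parameter count.
    """

    def __init__(self, config: EncoderConfig, params: dict[str, Tensor]):
        self.config = config
        self.params = params

    # -- construction ------------------------------------------------------

    @classmethod
    def init(cls, config: EncoderConfig, seed: int = 0, scale: float = 0.02,
             with_pretrain_heads: bool = True) -> "EncoderParams":
        """Truncated-normal initialization (scale 0.02), zeros for biases and
        layer-norm offsets, ones for layer-norm gains."""
        rng = np.random.default_rng(seed)
        h, f, v, p = config.hidden, config.ff_inner, config.vocab_size, config.max_positions

        def tn(*shape) -> Tensor:
            x = rng.standard_normal(shape)
            while True:
                bad = np.abs(x) > 2.0
                if not bad.any():
                    break
                x[bad] = rng.standard_normal(int(bad.sum()))
            return Tensor(x * scale, requires_grad=True)

        def zeros(*shape) -> Tensor:
            return Tensor(np.zeros(shape), requires_grad=True)

        def ones(*shape) -> Tensor:
            return Tensor(np.ones(shape), requires_grad=True)

        d: dict[str, Tensor] = {
            "embeddings/token": tn(v, h),
            "embeddings/segment": tn(2, h),
            "embeddings/position": tn(p, h),
            "embeddings/ln_gain": ones(h),
            "embeddings/ln_bias": zeros(h),
        }
        for i in range(config.n_layers):
            pre = f"layer{i}/"
            for name in ("attn_q", "attn_k", "attn_v", "attn_out"):
                d[pre + name + "_w"] = tn(h, h)
                d[pre + name + "_b"] = zeros(h)
            d[pre + "attn_ln_gain"] = ones(h)
            d[pre + "attn_ln_bias"] = zeros(h)
            d[pre + "ffn_w1"] = tn(h, f)
            d[pre + "ffn_b1"] = zeros(f)
            d[pre + "ffn_w2"] = tn(f, h)
            d[pre + "ffn_b2"] = zeros(h)
            d[pre + "ffn_ln_gain"] = ones(h)
            d[pre + "ffn_ln_bias"] = zeros(h)
        d["pooler/w"] = tn(h, h)
        d["pooler/b"] = zeros(h)
        if with_pretrain_heads:
            d["mlm/dense_w"] = tn(h, h)
            d["mlm/dense_b"] = zeros(h)
            d["mlm/ln_gain"] = ones(h)
            d["mlm/ln_bias"] = zeros(h)
            d["mlm/bias"] = zeros(v)  # decoder weights are tied to the token table
            d["nsp/dense_w"] = tn(h, h)
            d["nsp/dense_b"] = zeros(h)
            d["nsp/w"] = tn(h, 2)
            d["nsp/b"] = zeros(2)
        return cls(config, d)

    # -- bookkeeping -------------------------------------------------------

    TRUNK_PREFIXES = ("embeddings/", "layer", "pooler/")

    def trunk_names(self) -> list[str]:
        return [k for k in self.params if k.startswith(self.TRUNK_PREFIXES)]

    def n_trunk_elements(self) -> int:
        return int(sum(self.params[k].data.size for k in self.trunk_names()))

    def tables(self) -> EmbeddingTables:
        return EmbeddingTables(
            token=self.params["embeddings/token"].data,
            segment=self.params["embeddings/segment"].data,
            position=self.params["embeddings/position"].data,
        )

    def copy(self) -> "EncoderParams":
        return EncoderParams(
            self.config,
            {k: Tensor(v.data.copy(), requires_grad=True) for k, v in self.params.items()},
        )

    def all_tensors(self) -> list[Tensor]:
        return list(self.params.values())

    # -- checkpoint IO -----------------------------------------------------

    def save(self, directory: str | Path) -> None:
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        manifest = {
            "format_version": 1,
            "config": asdict(self.config),
            "pooler": True,
            "shapes": {k: list(v.data.shape) for k, v in self.params.items()},
        }
        (directory / "config.json").write_text(json.dumps(manifest, indent=2))
        np.savez(directory / "weights.npz",
                 **{k.replace("/", "__"): v.data for k, v in self.params.items()})

    @classmethod
    def load(cls, directory: str | Path) -> "EncoderParams":
        directory = Path(directory)
        manifest = json.loads((directory / "config.json").read_text())
        config = EncoderConfig(**manifest["config"])
        with np.load(directory / "weights.npz") as npz:
            params = {k.replace("__", "/"): Tensor(npz[k].copy(), requires_grad=True)
                      for k in npz.files}
        for name, shape in manifest["shapes"].items():
            if name not in params:
                raise ValueError(f"checkpoint missing parameter {name}")
            if list(params[name].data.shape) != shape:
                raise ValueError(
                    f"checkpoint shape mismatch for {name}: manifest {shape}, "
                    f"array {list(params[name].data.shape)}"
                )
        return cls(config, params)


# ---------------------------------------------------------------------------
# forward pass
# ---------------------------------------------------------------------------


def embed(seq: TokenSequence, tables: EmbeddingTables) -> np.ndarray:
    """Input embedding: elementwise sum of token, segment and position rows.

    The sum is exact — row i is ``token[ids[i]] + segment[segment_ids[i]] +
    position[i]`` with no normalization or scaling.
    """
    ids = np.asarray(seq.ids)
    segs = np.asarray(seq.segment_ids)
    pos = np.asarray(seq.positions)
    if ids.max() >= tables.token.shape[0]:
        raise ValueError(f"token id {int(ids.max())} out of range for vocabulary "
                         f"of {tables.token.shape[0]}")
    if pos.max() >= tables.position.shape[0]:
        raise ValueError(f"position {int(pos.max())} exceeds table of "
                         f"{tables.position.shape[0]} positions")
    return tables.token[ids] + tables.segment[segs] + tables.position[pos]


def _layer_norm(x: Tensor, gain: Tensor, bias: Tensor, eps: float = 1e-6) -> Tensor:
    mu = x.mean(axis=-1, keepdims=True)
    centered = x - mu
    var = (centered * centered).mean(axis=-1, keepdims=True)
    return centered * (var + eps).power(-0.5) * gain + bias


def _embed_batch(ids: np.ndarray, segs: np.ndarray, params: EncoderParams,
                 train: bool, rng: np.random.Generator | None) -> Tensor:
    p = params.params
    B, L = ids.shape
    x = (embedding(p["embeddings/token"], ids)
         + embedding(p["embeddings/segment"], segs)
         + embedding(p["embeddings/position"], np.broadcast_to(np.arange(L), (B, L))))
    x = _layer_norm(x, p["embeddings/ln_gain"], p["embeddings/ln_bias"])
    return x.dropout(params.config.dropout, rng, train)


def encoder_layer(hidden: Tensor, mask: np.ndarray, params: EncoderParams, index: int,
                  train: bool = False, rng: np.random.Generator | None = None,
                  return_attention: bool = False):
    """One encoder layer on a (B, L, H) tensor.

    ``mask`` is (B, L) with 1 on real tokens; padded positions are excluded
    as attention *targets* via a large negative additive bias.
    """
    cfg = params.config
    p = params.params
    pre = f"layer{index}/"
    if not np.isfinite(hidden.data).all():
        raise FloatingPointError(f"non-finite activations entering encoder layer {index}")
    B, L, H = hidden.shape
    A, dh = cfg.n_heads, cfg.head_dim

    def heads(t: Tensor) -> Tensor:
        return t.reshape(B, L, A, dh).transpose(0, 2, 1, 3)  # (B, A, L, dh)

    q = heads(hidden @ p[pre + "attn_q_w"] + p[pre + "attn_q_b"])
    k = heads(hidden @ p[pre + "attn_k_w"] + p[pre + "attn_k_b"])
    v = heads(hidden @ p[pre + "attn_v_w"] + p[pre + "attn_v_b"])

    scores = (q @ k.transpose(0, 1, 3, 2)) * (1.0 / np.sqrt(dh))
    bias = (1.0 - mask.astype(np.float64))[:, None, None, :] * _NEG_BIG
    attn = (scores + Tensor(bias)).softmax(axis=-1)
    attn_d = attn.dropout(cfg.dropout, rng, train)
    ctx = (attn_d @ v).transpose(0, 2, 1, 3).reshape(B, L, H)
    out = (ctx @ p[pre + "attn_out_w"] + p[pre + "attn_out_b"]).dropout(cfg.dropout, rng, train)
    h1 = _layer_norm(hidden + out, p[pre + "attn_ln_gain"], p[pre + "attn_ln_bias"])

    ff = gelu(h1 @ p[pre + "ffn_w1"] + p[pre + "ffn_b1"]) @ p[pre + "ffn_w2"] + p[pre + "ffn_b2"]
    ff = ff.dropout(cfg.dropout, rng, train)
    h2 = _layer_norm(h1 + ff, p[pre + "ffn_ln_gain"], p[pre + "ffn_ln_bias"])
    if not np.isfinite(h2.data).all():
        raise FloatingPointError(f"non-finite activations produced by encoder layer {index}")
    if return_attention:
        return h2, attn.data
    return h2


def encode_batch(ids: np.ndarray, segs: np.ndarray, mask: np.ndarray,
                 params: EncoderParams, train: bool = False,
                 rng: np.random.Generator | None = None) -> Tensor:
    """Full encoder on an id batch: embeddings then every layer; (B, L, H)."""
    h = _embed_batch(ids, segs, params, train, rng)
    for i in range(params.config.n_layers):
        h = encoder_layer(h, mask, params, i, train=train, rng=rng)
    return h


def encode(seq: TokenSequence, params: EncoderParams, train: bool = False,
           rng: np.random.Generator | None = None) -> np.ndarray:
    """Encode one sequence; deterministic (dropout off) unless ``train``."""
    ids = np.asarray(seq.ids)[None, :]
    segs = np.asarray(seq.segment_ids)[None, :]
    mask = np.asarray(seq.mask)[None, :]
    return encode_batch(ids, segs, mask, params, train=train, rng=rng).data[0]


def pool_first_token(hidden: Tensor, params: EncoderParams) -> Tensor:
    """Standard pooler: tanh-transformed first-token ([CLS]) state."""
    p = params.params
    return (hidden[:, 0, :] @ p["pooler/w"] + p["pooler/b"]).tanh()


def nsp_logits(hidden: Tensor, mask: np.ndarray, params: EncoderParams) -> Tensor:
    """Next-sentence logits from the masked mean of final token states.

    Mean pooling (rather than the classification-time [CLS] pooler) keeps
    the pre-training head's input content-bearing from the very first
    step, which matters at miniature scale where the [CLS] state is
    nearly constant at initialization.
    """
    p = params.params
    m = np.asarray(mask, dtype=np.float64)
    mean = (hidden * Tensor(m[:, :, None])).sum(axis=1) * Tensor((1.0 / m.sum(axis=1))[:, None])
    pooled = (mean @ p["nsp/dense_w"] + p["nsp/dense_b"]).tanh()
    return pooled @ p["nsp/w"] + p["nsp/b"]


# ---------------------------------------------------------------------------
# pre-training
# ---------------------------------------------------------------------------


@dataclass
class PretrainBatch:
    """Corrupted ids with the bookkeeping needed to score the two objectives."""

    ids: np.ndarray            # (L,) corrupted token ids
    mask_positions: np.ndarray  # positions selected for prediction
    original_ids: np.ndarray   # gold ids at those positions
    is_next: bool | None = None


def mask_tokens(seq: TokenSequence, vocab: Vocabulary, rng: np.random.Generator,
                policy: tuple[float, float, float] = (0.8, 0.1, 0.1),
                rate: float = 0.15) -> PretrainBatch:
    """Select ~15% of maskable positions (never special tokens; at least one).

    Of the selected positions, ``policy`` fractions become ``[MASK]``, a
    random vocabulary token, or stay unchanged; originals are recorded.
    """
    if abs(sum(policy) - 1.0) > 1e-9:
        raise ValueError(f"policy fractions must sum to 1, got {policy}")
    ids = np.asarray(seq.ids).copy()
    special = vocab.special_ids
    maskable = np.array([i for i, (tid, m) in enumerate(zip(seq.ids, seq.mask))
                         if m == 1 and tid not in special], dtype=int)
    if maskable.size == 0:
        raise ValueError("sequence has no maskable token")
    n_sel = max(1, int(rate * maskable.size))
    sel = np.sort(rng.choice(maskable, size=n_sel, replace=False))
    originals = ids[sel].copy()
    mask_id = vocab.token_to_id[MASK]
    for pos in sel:
        u = rng.random()
        if u < policy[0]:
            ids[pos] = mask_id
        elif u < policy[0] + policy[1]:
            ids[pos] = int(rng.integers(0, len(vocab)))
    return PretrainBatch(ids=ids, mask_positions=sel, original_ids=originals)


def make_nsp_pairs(corpus: Sequence[Sequence[str]], rng: np.random.Generator) -> list[tuple[tuple[str, str], bool]]:
    """Consecutive-sentence pairs, half with the second sentence replaced.

    IsNext/NotNext counts differ by at most one per call; NotNext second
    sentences always come from a different document.
    """
    if len(corpus) < 2:
        raise ValueError("next-sentence pairs need at least 2 documents")
    slots: list[tuple[int, str, str]] = []
    for di, doc in enumerate(corpus):
        for a, b in zip(doc, doc[1:]):
            slots.append((di, a, b))
    n = len(slots)
    labels = np.zeros(n, dtype=bool)
    labels[: (n + 1) // 2] = True
    rng.shuffle(labels)
    out: list[tuple[tuple[str, str], bool]] = []
    for (di, a, b), is_next in zip(slots, labels):
        if is_next:
            out.append(((a, b), True))
        else:
            while True:
                dj = int(rng.integers(len(corpus)))
                if dj != di and len(corpus[dj]) > 0:
                    break
            repl = corpus[dj][int(rng.integers(len(corpus[dj])))]
            out.append(((a, repl), False))
    return out


@dataclass(frozen=True)
class PretrainSchedule:
    """Optimization settings for the two unsupervised objectives."""

    epochs: int = 3
    batch_size: int = 16
    learning_rate: float = 1e-3
    max_len: int = 32
    seed: int = 0
    clip_norm: float = 1.0


def _batch_arrays(seqs: Sequence[TokenSequence]):
    ids = np.stack([np.asarray(s.ids) for s in seqs])
    segs = np.stack([np.asarray(s.segment_ids) for s in seqs])
    mask = np.stack([np.asarray(s.mask) for s in seqs])
    return ids, segs, mask


def pretrain_losses(batches: Sequence[PretrainBatch], seqs: Sequence[TokenSequence],
                    params: EncoderParams, train: bool,
                    rng: np.random.Generator | None) -> tuple[Tensor, Tensor]:
    """Masked-token and next-sentence cross-entropies for one mini-batch."""
    p = params.params
    _, segs, mask = _batch_arrays(seqs)
    ids = np.stack([b.ids for b in batches])
    hidden = encode_batch(ids, segs, mask, params, train=train, rng=rng)

    # masked-token objective: transform, project onto the tied token table
    idx0 = np.concatenate([np.full(len(b.mask_positions), i)
                           for i, b in enumerate(batches)])
    idx1 = np.concatenate([b.mask_positions for b in batches])
    gold = np.concatenate([b.original_ids for b in batches])
    states = hidden.take_rows(idx0, idx1)
    t = _layer_norm(gelu(states @ p["mlm/dense_w"] + p["mlm/dense_b"]),
                    p["mlm/ln_gain"], p["mlm/ln_bias"])
    logits = t @ p["embeddings/token"].transpose(1, 0) + p["mlm/bias"]
    logp = logits.log_softmax(axis=-1)
    mlm_loss = -logp.take_rows(np.arange(len(gold)), gold).mean()

    # next-sentence objective on the mean-pooled sequence state
    logits_nsp = nsp_logits(hidden, mask, params)
    nsp_gold = np.array([0 if b.is_next else 1 for b in batches])
    nsp_logp = logits_nsp.log_softmax(axis=-1)
    nsp_loss = -nsp_logp.take_rows(np.arange(len(batches)), nsp_gold).mean()
    return mlm_loss, nsp_loss


def pretrain(corpus: Sequence[Sequence[str]], vocab: Vocabulary, config: EncoderConfig,
             schedule: PretrainSchedule = PretrainSchedule()) -> tuple[EncoderParams, dict]:
    """Optimize the combined masked-token + next-sentence loss on a corpus.

    Returns the trained parameters and a history dict with per-epoch mean
    losses.  Deterministic given the schedule seed; aborts on non-finite
    loss.
    """
    rng = np.random.default_rng(schedule.seed)
    params = EncoderParams.init(config, seed=schedule.seed)
    opt = Adam(params.all_tensors(), lr=schedule.learning_rate)
    history: dict = {"mlm_loss": [], "nsp_loss": [], "total_loss": []}

    for epoch in range(schedule.epochs):
        pairs = make_nsp_pairs(corpus, rng)
        order = rng.permutation(len(pairs))
        epoch_mlm, epoch_nsp, n_batches = 0.0, 0.0, 0
        for start in range(0, len(order), schedule.batch_size):
            chunk = order[start : start + schedule.batch_size]
            seqs, pbatches = [], []
            for j in chunk:
                (a, b), is_next = pairs[j]
                seq = encode_pair(a, b, vocab, schedule.max_len)
                pb = mask_tokens(seq, vocab, rng)
                pb.is_next = is_next
                seqs.append(seq)
                pbatches.append(pb)
            mlm, nsp = pretrain_losses(pbatches, seqs, params, train=True, rng=rng)
            loss = mlm + nsp
            if not np.isfinite(loss.data):
                raise FloatingPointError(
                    f"pre-training diverged at epoch {epoch}, batch {n_batches}: "
                    f"mlm={mlm.item():.4g} nsp={nsp.item():.4g}"
                )
            opt.zero_grad()
            loss.backward()
            clip_global_norm(params.all_tensors(), schedule.clip_norm)
            opt.step()
            epoch_mlm += mlm.item()
            epoch_nsp += nsp.item()
            n_batches += 1
        history["mlm_loss"].append(epoch_mlm / n_batches)
        history["nsp_loss"].append(epoch_nsp / n_batches)
        history["total_loss"].append((epoch_mlm + epoch_nsp) / n_batches)
        logger.info("pretrain epoch %d: mlm %.4f nsp %.4f", epoch,
                    history["mlm_loss"][-1], history["nsp_loss"][-1])
    return params, history
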