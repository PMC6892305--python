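"""Multi-filter 1d-CNN classification head and the margin ranking loss.

Filters of several window lengths (3, 4 and 5 by default, 100 feature
maps each) slide along the token axis of the encoder's final hidden
states, each consuming full hidden-size slices; after bias and ReLU, the
strongest response per map is kept by max-over-time pooling over windows
that lie entirely inside the unpadded sequence.  The concatenated
features (300 by default) pass through dropout and a fully connected
softmax classifier.

Binary tasks train with the margin ranking loss
``sum_pairs max{0, 1 - g(d) + g(d')}`` where ``g`` is the softmax score
of the positive class for a positive (d) and a negative (d') document;
driving the loss to zero forces g(d) toward 1 and g(d') toward 0 with a
unit margin.  Multi-class tasks use softmax cross-entropy.  A plain
linear head over the pooled first-token state is provided as the
comparison baseline.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .autodiff import Tensor, concat, relu

__all__ = [
    "CNNConfig", "init_cnn_params", "init_linear_params",
    "conv_pool", "classify", "linear_head", "ranking_loss", "pair_pos_neg",
]

logger = logging.getLogger(__name__)

_NEG_BIG = -1e9


@dataclass(frozen=True)
class CNNConfig:
    """Head geometry and regularization."""

    windows: tuple[int, ...] = (3, 4, 5)
    maps: int = 100
    dropout: float = 0.5

    def __post_init__(self) -> None:
        if any(w < 1 for w in self.windows):
            raise ValueError(f"window lengths must be >= 1, got {self.windows}")
        if self.maps < 1:
            raise ValueError(f"feature maps must be >= 1, got {self.maps}")

    @property
    def n_features(self) -> int:
        return self.maps * len(self.windows)


def init_cnn_params(cfg: CNNConfig, hidden: int, n_classes: int,
                    seed: int = 0, scale: float = 0.02) -> dict[str, Tensor]:
    """Filter banks (one (w, H, maps) tensor per window), biases, and the
    fully connected classifier."""
    rng = np.random.default_rng(seed)
    d: dict[str, Tensor] = {}
    for w in cfg.windows:
        d[f"cnn/w{w}_filt"] = Tensor(rng.standard_normal((w, hidden, cfg.maps)) * scale,
                                     requires_grad=True)
        d[f"cnn/w{w}_bias"] = Tensor(np.zeros(cfg.maps), requires_grad=True)
    d["cnn/fc_w"] = Tensor(rng.standard_normal((cfg.n_features, n_classes)) * scale,
                           requires_grad=True)
    d["cnn/fc_b"] = Tensor(np.zeros(n_classes), requires_grad=True)
    return d


def init_linear_params(hidden: int, n_classes: int, seed: int = 0,
                       scale: float = 0.02) -> dict[str, Tensor]:
    rng = np.random.default_rng(seed)
    return {
        "lin/fc_w": Tensor(rng.standard_normal((hidden, n_classes)) * scale, requires_grad=True),
        "lin/fc_b": Tensor(np.zeros(n_classes), requires_grad=True),
    }


def conv_pool(hidden: Tensor, mask: np.ndarray, params: dict[str, Tensor],
              cfg: CNNConfig) -> Tensor:
    """Valid 1-d convolution + ReLU + max-over-time pooling; (B, maps * windows).

    Window positions that would overlap padding are excluded from the
    maximum.  A sequence shorter than a window contributes that filter's
    bias through ReLU instead (logged once per call).
    """
    B, L, H = hidden.shape
    mask = np.asarray(mask, dtype=np.float64)
    seq_len = mask.sum(axis=1).astype(int)  # padding is always a suffix
    outputs: list[Tensor] = []
    for w in cfg.windows:
        filt = params[f"cnn/w{w}_filt"]
        bias = params[f"cnn/w{w}_bias"]
        n_win = L - w + 1
        if n_win < 1:
            logger.warning("sequence length %d shorter than window %d; "
                           "filter contributes ReLU(bias) only", L, w)
            outputs.append(relu(bias) * Tensor(np.ones((B, 1))))
            continue
        acc = hidden[:, 0:n_win, :] @ filt[0]
        for i in range(1, w):
            acc = acc + hidden[:, i : n_win + i, :] @ filt[i]
        act = relu(acc + bias)  # (B, n_win, maps)
        valid = (np.arange(n_win)[None, :] + w <= seq_len[:, None]).astype(np.float64)
        has_valid = valid.any(axis=1)
        if not has_valid.all():
            logger.warning("%d sequence(s) shorter than window %d after masking; "
                           "falling back to ReLU(bias)", int((~has_valid).sum()), w)
        pooled = (act + Tensor((1.0 - valid)[:, :, None] * _NEG_BIG)).max(axis=1)
        if has_valid.all():
            outputs.append(pooled)
        else:
            sel = Tensor(has_valid.astype(np.float64)[:, None])
            fallback = relu(bias) * Tensor(np.ones((B, 1)))
            outputs.append(pooled * sel + fallback * (1.0 - sel))
    return concat(outputs, axis=-1)


def classify(features: Tensor, params: dict[str, Tensor], *,
             train: bool = False, rng: np.random.Generator | None = None,
             dropout: float = 0.5, prefix: str = "cnn/fc") -> Tensor:
    """Dropout (training only) + affine map + softmax class distribution."""
    x = features.dropout(dropout, rng, train)
    logits = x @ params[f"{prefix}_w"] + params[f"{prefix}_b"]
    return logits.softmax(axis=-1)


def linear_head(pooled: Tensor, params: dict[str, Tensor], *,
                train: bool = False, rng: np.random.Generator | None = None,
                dropout: float = 0.5) -> Tensor:
    """The baseline sequence classifier: softmax over the pooled [CLS] state."""
    return classify(pooled, params, train=train, rng=rng, dropout=dropout, prefix="lin/fc")


def ranking_loss(pos_scores: Tensor | Sequence[float],
                 neg_scores: Tensor | Sequence[float]) -> Tensor:
    """Margin ranking loss ``sum_i max{0, 1 - g(d_i) + g(d'_i)}``.

    Zero exactly when every pair satisfies g(d) - g(d') >= 1.  Scores must
    be softmax outputs in [0, 1].
    """
    pos = pos_scores if isinstance(pos_scores, Tensor) else Tensor(np.asarray(pos_scores, dtype=float))
    neg = neg_scores if isinstance(neg_scores, Tensor) else Tensor(np.asarray(neg_scores, dtype=float))
    if pos.data.shape != neg.data.shape:
        raise ValueError(f"score sequences must pair up: {pos.data.shape} vs {neg.data.shape}")
    for name, t in (("positive", pos), ("negative", neg)):
        if t.data.size and (t.data.min() < 0.0 or t.data.max() > 1.0):
            raise ValueError(f"{name} scores outside [0, 1]: g is a softmax output")
    return relu(1.0 - pos + neg).sum()


def pair_pos_neg(labels: np.ndarray, rng: np.random.Generator,
                 all_pairs: bool = False) -> tuple[np.ndarray, np.ndarray] | None:
    """Index pairing for the ranking loss within one mini-batch.

    Shuffles positives and negatives independently and cycles the shorter
    side; with ``all_pairs`` every positive meets every negative.  Returns
    None when the batch lacks one of the classes.
    """
    pos_idx = np.flatnonzero(labels == 1)
    neg_idx = np.flatnonzero(labels == 0)
    if pos_idx.size == 0 or neg_idx.size == 0:
        return None
    if all_pairs:
        pi, ni = np.meshgrid(pos_idx, neg_idx, indexing="ij")
        return pi.ravel(), ni.ravel()
    pos_idx = rng.permutation(pos_idx)
    neg_idx = rng.permutation(neg_idx)
    n = max(pos_idx.size, neg_idx.size)
    return (np.resize(pos_idx, n), np.resize(neg_idx, n))
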