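"""Fine-tuning of the pre-trained encoder through a classification head.

The head's training error back-propagates into every encoder parameter
(unless the encoder is frozen, in which case the encoder acts as a fixed
feature extractor and stays bit-identical).  Binary tasks may train with
the margin ranking loss on positive/negative score pairs; multi-class
tasks use softmax cross-entropy.  Optimization is Adam at a fixed
learning rate (5e-5 by default) with global-norm gradient clipping.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import numpy as np

from .autodiff import Adam, Tensor, clip_global_norm
from .cnn import (CNNConfig, classify, conv_pool, init_cnn_params,
                  init_linear_params, linear_head, pair_pos_neg, ranking_loss)
from .encoder import EncoderParams, encode_batch, pool_first_token, _batch_arrays
from .metrics import EvalReport, binary_report, confusion, prf
from .samples import SentencePairSample
from .wordpiece import TokenSequence, Vocabulary, encode_pair

__all__ = [
    "FineTuneConfig", "TrainingHistory", "FineTunedModel",
    "finetune", "predict", "cross_validate",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class FineTuneConfig:
    """Fine-tuning hyperparameters."""

    learning_rate: float = 5e-5
    batch_size: int = 20
    max_len: int = 200
    epochs: int = 3
    head: str = "cnn"              # {"cnn", "linear"}
    loss: str = "ranking"          # {"ranking", "cross_entropy"}
    freeze_encoder: bool = False
    dropout: float = 0.5           # classifier-input dropout
    all_pairs: bool = False        # ranking loss over all pos x neg pairs
    clip_norm: float = 1.0
    seed: int = 0
    cnn: CNNConfig = field(default_factory=CNNConfig)

    def __post_init__(self) -> None:
        if self.learning_rate <= 0:
            raise ValueError("learning rate must be positive")
        if self.batch_size < 1:
            raise ValueError("batch size must be >= 1")
        if self.head not in ("cnn", "linear"):
            raise ValueError(f"unknown head {self.head!r}")
        if self.loss not in ("ranking", "cross_entropy"):
            raise ValueError(f"unknown loss {self.loss!r}")


@dataclass
class TrainingHistory:
    """Per-epoch training loss and held-out metrics."""

    losses: list[float] = field(default_factory=list)
    dev_metrics: list[tuple[float, float, float]] = field(default_factory=list)
    seed: int = 0
    config: dict = field(default_factory=dict)


class FineTunedModel:
    """Encoder + head with a fixed label set; prediction is deterministic."""

    def __init__(self, encoder: EncoderParams, head_params: dict[str, Tensor],
                 cfg: FineTuneConfig, vocab: Vocabulary, label_set: tuple[str, ...]):
        self.encoder = encoder
        self.head_params = head_params
        self.cfg = cfg
        self.vocab = vocab
        self.label_set = label_set

    # -- forward -----------------------------------------------------------

    def encode_samples(self, samples: Sequence[SentencePairSample]) -> list[TokenSequence]:
        return [encode_pair(s.sentence_a, s.sentence_b, self.vocab, self.cfg.max_len)
                for s in samples]

    def forward(self, seqs: Sequence[TokenSequence], *, train: bool = False,
                rng: np.random.Generator | None = None) -> Tensor:
        """Class probability distributions, (B, n_classes)."""
        ids, segs, mask = _batch_arrays(seqs)
        hidden = encode_batch(ids, segs, mask, self.encoder, train=train, rng=rng)
        if self.cfg.head == "cnn":
            feats = conv_pool(hidden, mask, self.head_params, self.cfg.cnn)
            return classify(feats, self.head_params, train=train, rng=rng,
                            dropout=self.cfg.dropout)
        pooled = pool_first_token(hidden, self.encoder)
        return linear_head(pooled, self.head_params, train=train, rng=rng,
                           dropout=self.cfg.dropout)

    # -- checkpoint --------------------------------------------------------

    def save(self, directory: str | Path) -> None:
        directory = Path(directory)
        merged = EncoderParams(self.encoder.config,
                               {**self.encoder.params, **self.head_params})
        merged.save(directory)
        (directory / "head.json").write_text(json.dumps({
            "head": self.cfg.head,
            "label_set": list(self.label_set),
            "config": _config_dict(self.cfg),
        }, indent=2))

    @classmethod
    def load(cls, directory: str | Path, vocab: Vocabulary) -> "FineTunedModel":
        directory = Path(directory)
        merged = EncoderParams.load(directory)
        meta = json.loads((directory / "head.json").read_text())
        cfg_d = dict(meta["config"])
        cfg_d["cnn"] = CNNConfig(windows=tuple(cfg_d["cnn"]["windows"]),
                                 maps=cfg_d["cnn"]["maps"],
                                 dropout=cfg_d["cnn"]["dropout"])
        cfg = FineTuneConfig(**cfg_d)
        head_prefix = "cnn/" if meta["head"] == "cnn" else "lin/"
        head_params = {k: v for k, v in merged.params.items() if k.startswith(head_prefix)}
        trunk = {k: v for k, v in merged.params.items() if not k.startswith(("cnn/", "lin/"))}
        encoder = EncoderParams(merged.config, trunk)
        return cls(encoder, head_params, cfg, vocab, tuple(meta["label_set"]))


def _config_dict(cfg: FineTuneConfig) -> dict:
    d = asdict(cfg)
    d["cnn"] = {"windows": list(cfg.cnn.windows), "maps": cfg.cnn.maps,
                "dropout": cfg.cnn.dropout}
    return d


def _dev_report(model: FineTunedModel, samples: Sequence[SentencePairSample]) -> EvalReport:
    labels, _ = predict(model, samples)
    gold = [s.label for s in samples]
    if set(model.label_set) <= {"0", "1"}:
        return binary_report(gold, labels)
    return prf(confusion(gold, labels, model.label_set))


def finetune(pretrained: EncoderParams, train: Sequence[SentencePairSample],
             dev: Sequence[SentencePairSample], vocab: Vocabulary,
             cfg: FineTuneConfig) -> tuple[FineTunedModel, TrainingHistory]:
    """Train a head on top of (a copy of) the pre-trained encoder.

    With ``freeze_encoder`` the encoder receives no updates and remains
    bit-identical to ``pretrained``; otherwise the classification error
    back-propagates through every encoder layer down to the embeddings.
    """
    if len(vocab) != pretrained.config.vocab_size:
        raise ValueError(f"vocabulary size {len(vocab)} does not match encoder "
                         f"config ({pretrained.config.vocab_size})")
    if cfg.max_len > pretrained.config.max_positions:
        raise ValueError(f"max_len {cfg.max_len} exceeds encoder position table "
                         f"({pretrained.config.max_positions})")
    label_set = tuple(sorted({s.label for s in train} | {s.label for s in dev}))
    if cfg.loss == "ranking" and set(label_set) != {"0", "1"}:
        raise ValueError("ranking loss requires binary '0'/'1' labels; "
                         f"got {label_set}")

    encoder = pretrained.copy()
    n_classes = len(label_set)
    if cfg.head == "cnn":
        head_params = init_cnn_params(cfg.cnn, encoder.config.hidden, n_classes, seed=cfg.seed)
    else:
        head_params = init_linear_params(encoder.config.hidden, n_classes, seed=cfg.seed)
    model = FineTunedModel(encoder, head_params, cfg, vocab, label_set)

    trainable = list(head_params.values())
    if not cfg.freeze_encoder:
        trainable += encoder.all_tensors()
    opt = Adam(trainable, lr=cfg.learning_rate)
    rng = np.random.default_rng(cfg.seed)
    label_to_idx = {lab: i for i, lab in enumerate(label_set)}
    pos_idx = label_to_idx.get("1")

    seqs = model.encode_samples(train)
    gold = np.array([label_to_idx[s.label] for s in train])
    history = TrainingHistory(seed=cfg.seed, config=_config_dict(cfg))

    for epoch in range(cfg.epochs):
        order = rng.permutation(len(seqs))
        epoch_loss, n_batches = 0.0, 0
        for start in range(0, len(order), cfg.batch_size):
            chunk = order[start : start + cfg.batch_size]
            batch_seqs = [seqs[i] for i in chunk]
            batch_gold = gold[chunk]
            probs = model.forward(batch_seqs, train=True, rng=rng)
            loss = None
            if cfg.loss == "ranking":
                pairing = pair_pos_neg((batch_gold == pos_idx).astype(int), rng,
                                       all_pairs=cfg.all_pairs)
                if pairing is not None:
                    pi, ni = pairing
                    g = probs[:, pos_idx]
                    loss = ranking_loss(g[pi], g[ni]) * (1.0 / len(pi))
                # single-class batch: fall through to cross-entropy
            if loss is None:
                picked = probs.take_rows(np.arange(len(chunk)), batch_gold)
                loss = -(picked.log().mean())
            if not np.isfinite(loss.data):
                raise FloatingPointError(f"fine-tuning diverged at epoch {epoch}")
            opt.zero_grad()
            loss.backward()
            clip_global_norm(trainable, cfg.clip_norm)
            opt.step()
            epoch_loss += loss.item()
            n_batches += 1
        history.losses.append(epoch_loss / max(n_batches, 1))
        report = _dev_report(model, dev) if dev else None
        history.dev_metrics.append(report.micro if report else (0.0, 0.0, 0.0))
        logger.info("finetune epoch %d: loss %.4f dev F1 %.4f", epoch,
                    history.losses[-1], history.dev_metrics[-1][2])
    return model, history


def predict(model: FineTunedModel, samples: Sequence[SentencePairSample],
            batch_size: int = 32) -> tuple[list[str], np.ndarray]:
    """Argmax labels and the full score matrix (rows sum to 1); deterministic."""
    seqs = model.encode_samples(samples)
    scores = []
    for start in range(0, len(seqs), batch_size):
        probs = model.forward(seqs[start : start + batch_size], train=False)
        scores.append(probs.data)
    if not scores:
        return [], np.zeros((0, len(model.label_set)))
    mat = np.concatenate(scores, axis=0)
    labels = [model.label_set[i] for i in mat.argmax(axis=1)]
    return labels, mat


def cross_validate(samples: Sequence[SentencePairSample], k: int,
                   pretrained: EncoderParams, vocab: Vocabulary,
                   cfg: FineTuneConfig, seed: int | None = None) -> dict:
    """Stratified k-fold cross-validation; every sample is tested once.

    Returns per-fold reports plus the mean and variance of micro P/R/F1.
    Classes with fewer than k members trigger a warning and plain
    (unstratified) folding.
    """
    from sklearn.model_selection import KFold, StratifiedKFold

    if k < 2:
        raise ValueError("k must be >= 2")
    if len(samples) < k:
        raise ValueError(f"need at least k={k} samples, got {len(samples)}")
    seed = cfg.seed if seed is None else seed
    labels = np.array([s.label for s in samples])
    _, counts = np.unique(labels, return_counts=True)
    if counts.min() < k:
        logger.warning("a class has fewer than %d members; relaxing stratification", k)
        splitter = KFold(n_splits=k, shuffle=True, random_state=seed)
    else:
        splitter = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)

    reports: list[EvalReport] = []
    fold_assignment = np.full(len(samples), -1)
    for fold, (train_idx, test_idx) in enumerate(splitter.split(np.zeros(len(samples)), labels)):
        fold_assignment[test_idx] = fold
        train = [samples[i] for i in train_idx]
        test = [samples[i] for i in test_idx]
        model, _ = finetune(pretrained, train, test, vocab, cfg)
        reports.append(_dev_report(model, test))
    micro = np.array([r.micro for r in reports])
    return {
        "folds": reports,
        "fold_assignment": fold_assignment,
        "mean": tuple(micro.mean(axis=0)),
        "variance": tuple(micro.var(axis=0)),
    }
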