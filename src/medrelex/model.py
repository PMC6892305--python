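"""Model/Results interface over the fine-tuning machinery.

`RelationModel` is built from labeled sentence-pair data plus a
pre-trained encoder; `fit()` runs fine-tuning and returns a
`RelationResults` carrying the fitted model, the training history,
held-out metrics and a `summary()` table.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np

from .corpus import RelationInstance
from .encoder import EncoderParams
from .metrics import EvalReport
from .samples import SentencePairSample, instance_to_sample
from .training import (FineTuneConfig, FineTunedModel, TrainingHistory,
                       _dev_report, finetune, predict)
from .wordpiece import Vocabulary

__all__ = ["RelationModel", "RelationResults"]


class RelationModel:
    """A relation classifier specified by data, encoder and configuration.

    Parameters
    ----------
    train, dev : sequences of SentencePairSample
        Labeled sentence-pair data; ``dev`` drives the per-epoch metrics.
    pretrained : EncoderParams
        Encoder weights to restore before fine-tuning begins (left
        untouched; fitting works on a copy).
    vocab : Vocabulary
        WordPiece vocabulary matching the encoder's embedding table.
    config : FineTuneConfig
        Head choice, loss, learning rate, batch/sequence sizes, seed.
    """

    def __init__(self, train: Sequence[SentencePairSample],
                 dev: Sequence[SentencePairSample],
                 pretrained: EncoderParams, vocab: Vocabulary,
                 config: FineTuneConfig | None = None):
        self.train_samples = list(train)
        self.dev_samples = list(dev)
        self.pretrained = pretrained
        self.vocab = vocab
        self.config = config or FineTuneConfig()

    @classmethod
    def from_instances(cls, train: Sequence[RelationInstance],
                       dev: Sequence[RelationInstance],
                       pretrained: EncoderParams, vocab: Vocabulary,
                       config: FineTuneConfig | None = None) -> "RelationModel":
        """Build from canonical relation instances (entity pair + context)."""
        return cls([instance_to_sample(i) for i in train],
                   [instance_to_sample(i) for i in dev],
                   pretrained, vocab, config)

    def fit(self) -> "RelationResults":
        model, history = finetune(self.pretrained, self.train_samples,
                                  self.dev_samples, self.vocab, self.config)
        report = _dev_report(model, self.dev_samples) if self.dev_samples else None
        return RelationResults(self, model, history, report)


class RelationResults:
    """Fitted estimates: the tuned model, its history and held-out metrics."""

    def __init__(self, spec: RelationModel, model: FineTunedModel,
                 history: TrainingHistory, dev_report: EvalReport | None):
        self.model_spec = spec
        self.model = model
        self.history = history
        self.dev_report = dev_report

    def predict(self, samples: Sequence[SentencePairSample]) -> tuple[list[str], np.ndarray]:
        return predict(self.model, samples)

    @property
    def f1(self) -> float:
        return self.dev_report.f1 if self.dev_report else float("nan")

    def summary(self) -> str:
        cfg = self.model_spec.config
        enc = self.model.encoder.config
        lines = [
            "Relation extraction fine-tuning results",
            "=" * 55,
            f"encoder geometry      L={enc.n_layers} H={enc.hidden} A={enc.n_heads}",
            f"head / loss           {cfg.head} / {cfg.loss}",
            f"encoder frozen        {cfg.freeze_encoder}",
            f"learning rate         {cfg.learning_rate:g}",
            f"batch size / max len  {cfg.batch_size} / {cfg.max_len}",
            f"epochs                {cfg.epochs}",
            f"train / dev samples   {len(self.model_spec.train_samples)} / "
            f"{len(self.model_spec.dev_samples)}",
            f"label set             {', '.join(self.model.label_set)}",
            "-" * 55,
        ]
        for i, (loss, (p, r, f1)) in enumerate(zip(self.history.losses,
                                                   self.history.dev_metrics)):
            lines.append(f"epoch {i:>2}  loss {loss:8.4f}  dev P {p:.4f} "
                         f"R {r:.4f} F1 {f1:.4f}")
        if self.dev_report is not None:
            lines.append("-" * 55)
            lines.append(str(self.dev_report))
        return "\n".join(lines)
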