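"""Run configuration: defaults <- YAML file <- command-line overrides.

Unknown keys are rejected (no silently ignored typos); every pipeline
stage serializes the fully resolved configuration and its seed into a
flat-text manifest next to its outputs, so any artifact can be
reproduced exactly.  One global seed fans out to per-stage seeds by
hashing the stage name, keeping stages independently reproducible.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field, fields, replace
from pathlib import Path
from typing import Any, Mapping

import yaml

from .cnn import CNNConfig
from .encoder import EncoderConfig, PretrainSchedule
from .samples import GenerationConfig
from .synthetic import SynthConfig
from .training import FineTuneConfig

__all__ = ["RunConfig", "load_config", "stage_seed", "write_manifest"]


@dataclass(frozen=True)
class RunConfig:
    """Fully resolved settings for every pipeline stage."""

    seed: int = 0
    # synthetic data
    n_docs: int = 60
    diseases_per_doc: int = 4
    relation_probability: float = 0.5
    # sample generation
    neg_per_pos: float = 1.0
    # vocabulary
    vocab_size: int = 220
    # encoder geometry
    n_layers: int = 2
    hidden: int = 64
    n_heads: int = 2
    max_positions: int = 128
    encoder_dropout: float = 0.1
    # pre-training
    pretrain_epochs: int = 2
    pretrain_batch_size: int = 16
    pretrain_lr: float = 1e-3
    pretrain_max_len: int = 32
    # fine-tuning
    learning_rate: float = 5e-5
    batch_size: int = 20
    max_len: int = 200
    epochs: int = 3
    head: str = "cnn"
    loss: str = "ranking"
    freeze_encoder: bool = False
    dropout: float = 0.5
    windows: tuple[int, ...] = (3, 4, 5)
    maps: int = 100

    # -- stage views -------------------------------------------------------

    def synth_config(self) -> SynthConfig:
        return SynthConfig(n_docs=self.n_docs, diseases_per_doc=self.diseases_per_doc,
                           relation_probability=self.relation_probability,
                           seed=stage_seed(self.seed, "synth"))

    def generation_config(self) -> GenerationConfig:
        return GenerationConfig(neg_per_pos=self.neg_per_pos,
                                seed=stage_seed(self.seed, "prepare"))

    def encoder_config(self, vocab_size: int) -> EncoderConfig:
        return EncoderConfig(n_layers=self.n_layers, hidden=self.hidden,
                             n_heads=self.n_heads, vocab_size=vocab_size,
                             max_positions=self.max_positions,
                             dropout=self.encoder_dropout)

    def pretrain_schedule(self) -> PretrainSchedule:
        return PretrainSchedule(epochs=self.pretrain_epochs,
                                batch_size=self.pretrain_batch_size,
                                learning_rate=self.pretrain_lr,
                                max_len=self.pretrain_max_len,
                                seed=stage_seed(self.seed, "pretrain"))

    def finetune_config(self) -> FineTuneConfig:
        return FineTuneConfig(learning_rate=self.learning_rate,
                              batch_size=self.batch_size, max_len=self.max_len,
                              epochs=self.epochs, head=self.head, loss=self.loss,
                              freeze_encoder=self.freeze_encoder, dropout=self.dropout,
                              seed=stage_seed(self.seed, "finetune"),
                              cnn=CNNConfig(windows=self.windows, maps=self.maps,
                                            dropout=self.dropout))


def stage_seed(global_seed: int, stage: str) -> int:
    """Derive a per-stage seed below 2^31 from the global seed and stage name."""
    digest = hashlib.sha256(f"{global_seed}:{stage}".encode()).digest()
    return int.from_bytes(digest[:4], "big") % (2 ** 31)


def load_config(path: str | Path | None, overrides: Mapping[str, Any] | None = None) -> RunConfig:
    """Merge defaults, an optional YAML file and explicit overrides.

    Precedence: defaults < file < overrides.  Unknown keys and type
    mismatches raise immediately.
    """
    valid = {f.name: f for f in fields(RunConfig)}
    merged: dict[str, Any] = {}
    for source_name, source in (("config file", _read_yaml(path)),
                                ("override", overrides or {})):
        for key, value in source.items():
            if key not in valid:
                raise KeyError(f"unknown {source_name} key {key!r}; "
                               f"valid keys: {', '.join(sorted(valid))}")
            if key == "windows" and isinstance(value, (list, tuple)):
                value = tuple(int(v) for v in value)
            expected = type(getattr(RunConfig(), key))
            if expected in (int, float) and isinstance(value, (int, float)) \
                    and not isinstance(value, bool):
                value = expected(value)
            if not isinstance(value, expected):
                raise TypeError(f"{source_name} key {key!r}: expected "
                                f"{expected.__name__}, got {type(value).__name__}")
            merged[key] = value
    return replace(RunConfig(), **merged)


def _read_yaml(path: str | Path | None) -> dict:
    if path is None:
        return {}
    text = Path(path).read_text(encoding="utf-8")
    data = yaml.safe_load(text) or {}
    if not isinstance(data, dict):
        raise TypeError(f"config file {path} must contain a key-value mapping")
    return data


def write_manifest(directory: str | Path, cfg: RunConfig, stage: str,
                   extra: Mapping[str, Any] | None = None) -> Path:
    """Flat key-value manifest recording config, seed and stage outputs."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    lines = [f"stage\t{stage}", f"stage_seed\t{stage_seed(cfg.seed, stage)}"]
    for f in fields(RunConfig):
        value = getattr(cfg, f.name)
        if isinstance(value, tuple):
            value = ",".join(str(v) for v in value)
        lines.append(f"{f.name}\t{value}")
    for key, value in (extra or {}).items():
        lines.append(f"{key}\t{value}")
    path = directory / "manifest.tsv"
    path.write_text("".join(ln + "\n" for ln in lines), encoding="utf-8")
    return path
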