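"""The miniature end-to-end benchmark: synthetic corpus -> pre-train ->
fine-tune -> evaluate, at desk scale (2 layers, 64 hidden, one CPU).

This is the package's self-contained demonstration of the method's
central claim: restoring pre-trained encoder weights and letting the
classification head's error back-propagate into them beats both freezing
the encoder and training the same architecture from random
initialization.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .encoder import EncoderConfig, EncoderParams, PretrainSchedule, pretrain
from .metrics import binary_report
from .samples import GenerationConfig, SentencePairSample, generate_corpus_samples
from .synthetic import SynthConfig, generate_pretrain_corpus, generate_relation_corpus
from .training import FineTuneConfig, FineTunedModel, TrainingHistory, finetune, predict
from .wordpiece import Vocabulary, build_vocab

__all__ = ["BenchmarkData", "build_benchmark", "pretrain_miniature",
           "finetune_config", "run_variant", "nsp_probe_accuracy", "MINIATURE"]

#: miniature encoder geometry used throughout the benchmark
MINIATURE = dict(n_layers=2, hidden=64, n_heads=2, max_positions=128)


@dataclass
class BenchmarkData:
    train: list[SentencePairSample]
    test: list[SentencePairSample]
    vocab: Vocabulary
    config: EncoderConfig


def build_benchmark(seed: int, n_train: int = 500, n_test: int = 150) -> BenchmarkData:
    """Planted-signal instances split by document (no context leakage).

    Generates enough single-pair documents to fill the requested train and
    test sizes at corpus-wide 1:1 balance, plus the WordPiece vocabulary
    covering both the relation corpus and the pre-training text.
    """
    n_docs = int((n_train + n_test) * 1.35)
    docs = generate_relation_corpus(SynthConfig(n_docs=n_docs, seed=seed))
    split = int(n_docs * n_train / (n_train + n_test))
    gen = GenerationConfig(seed=seed + 1)
    shuffle = np.random.default_rng(seed + 5)

    def draw(doc_subset, size):
        samples = generate_corpus_samples(doc_subset, gen, balance="corpus")
        order = shuffle.permutation(len(samples))
        return [samples[i] for i in order[:size]]

    train = draw(docs[:split], n_train)
    test = draw(docs[split:], n_test)
    pre_corpus = generate_pretrain_corpus(_pretrain_config(seed))
    vocab = build_vocab([s for d in pre_corpus for s in d] + [d.text for d in docs], 220)
    config = EncoderConfig(vocab_size=len(vocab), **MINIATURE)
    return BenchmarkData(train=train, test=test, vocab=vocab, config=config)


def _pretrain_config(seed: int) -> SynthConfig:
    return SynthConfig(n_docs=60, sentences_per_doc=15, seed=seed + 2)


def pretrain_miniature(data: BenchmarkData, seed: int,
                       epochs: int = 35) -> tuple[EncoderParams, dict]:
    """Pre-train the miniature encoder on the synthetic unstructured text."""
    corpus = generate_pretrain_corpus(_pretrain_config(seed))
    schedule = PretrainSchedule(epochs=epochs, batch_size=16, learning_rate=1e-3,
                                max_len=24, seed=seed + 3)
    return pretrain(corpus, data.vocab, data.config, schedule)


def nsp_probe_accuracy(encoder: EncoderParams, vocab: Vocabulary, seed: int,
                       n_pairs: int = 200) -> float:
    """Next-sentence accuracy on pairs from a freshly generated corpus."""
    from .encoder import _batch_arrays, encode_batch, make_nsp_pairs, nsp_logits
    from .wordpiece import encode_pair

    held_out = generate_pretrain_corpus(_pretrain_config(seed * 1000 + 999))
    rng = np.random.default_rng(seed + 7)
    pairs = make_nsp_pairs(held_out, rng)[:n_pairs]
    correct = 0
    for (a, b), is_next in pairs:
        seq = encode_pair(a, b, vocab, 24)
        ids, segs, mask = _batch_arrays([seq])
        hidden = encode_batch(ids, segs, mask, encoder)
        logits = nsp_logits(hidden, mask, encoder).data[0]
        correct += (logits[0] > logits[1]) == is_next
    return correct / len(pairs)


def finetune_config(seed: int, *, freeze: bool = False, epochs: int = 5,
                    loss: str = "ranking") -> FineTuneConfig:
    return FineTuneConfig(learning_rate=1e-3, batch_size=20, max_len=48,
                          epochs=epochs, head="cnn", loss=loss,
                          freeze_encoder=freeze, seed=seed + 4)


def run_variant(data: BenchmarkData, encoder: EncoderParams, seed: int, *,
                freeze: bool = False, epochs: int = 5,
                loss: str = "ranking") -> tuple[float, FineTunedModel, TrainingHistory]:
    """Fine-tune one configuration and return its held-out positive-class F1."""
    cfg = finetune_config(seed, freeze=freeze, epochs=epochs, loss=loss)
    model, history = finetune(encoder, data.train, data.test, data.vocab, cfg)
    labels, _ = predict(model, data.test)
    f1 = binary_report([s.label for s in data.test], labels).f1
    return f1, model, history
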