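"""Precision, recall and F1 from one-vs-rest confusion counts.

P = TP/(TP+FP), R = TP/(TP+FN), F1 = 2PR/(P+R); any 0/0 is defined as 0.
Multi-class runs aggregate by pooling TP/FP/FN across classes before
applying the same formulas (micro average).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterator, Mapping, Sequence

__all__ = ["ClassCounts", "ConfusionCounts", "EvalReport", "confusion", "prf", "micro_average"]


@dataclass(frozen=True)
class ClassCounts:
    tp: int = 0
    fp: int = 0
    fn: int = 0

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.fn) < 0:
            raise ValueError("confusion counts must be non-negative")


@dataclass(frozen=True)
class ConfusionCounts:
    """Per-class one-vs-rest TP/FP/FN counts."""

    per_class: Mapping[str, ClassCounts]

    def __getitem__(self, label: str) -> ClassCounts:
        return self.per_class[label]

    def labels(self) -> list[str]:
        return list(self.per_class)


def confusion(gold: Sequence[str], pred: Sequence[str],
              label_set: Sequence[str] | None = None) -> ConfusionCounts:
    """One-vs-rest confusion counts for each label."""
    if len(gold) != len(pred):
        raise ValueError(f"gold has {len(gold)} items but pred has {len(pred)}")
    if label_set is None:
        label_set = sorted(set(gold) | set(pred))
    known = set(label_set)
    for i, (g, p) in enumerate(zip(gold, pred)):
        if g not in known or p not in known:
            raise ValueError(f"item {i}: label outside the declared set: {g!r}/{p!r}")
    counts: dict[str, ClassCounts] = {}
    for lab in label_set:
        tp = sum(1 for g, p in zip(gold, pred) if g == lab and p == lab)
        fp = sum(1 for g, p in zip(gold, pred) if g != lab and p == lab)
        fn = sum(1 for g, p in zip(gold, pred) if g == lab and p != lab)
        counts[lab] = ClassCounts(tp, fp, fn)
    return ConfusionCounts(counts)


def _prf_from(tp: int, fp: int, fn: int) -> tuple[float, float, float]:
    p = tp / (tp + fp) if tp + fp else 0.0
    r = tp / (tp + fn) if tp + fn else 0.0
    f1 = 2 * p * r / (p + r) if p + r else 0.0
    return p, r, f1


@dataclass(frozen=True)
class EvalReport:
    """Per-class and micro-averaged precision/recall/F1 with supports."""

    per_class: Mapping[str, tuple[float, float, float]]
    support: Mapping[str, int]
    micro: tuple[float, float, float]

    @property
    def precision(self) -> float:
        return self.micro[0]

    @property
    def recall(self) -> float:
        return self.micro[1]

    @property
    def f1(self) -> float:
        return self.micro[2]

    def to_tsv(self) -> Iterator[str]:
        yield "class\tP\tR\tF1\tsupport\n"
        for lab, (p, r, f1) in self.per_class.items():
            yield f"{lab}\t{p:.4f}\t{r:.4f}\t{f1:.4f}\t{self.support[lab]}\n"
        yield f"micro\t{self.micro[0]:.4f}\t{self.micro[1]:.4f}\t{self.micro[2]:.4f}\t" \
              f"{sum(self.support.values())}\n"

    def __str__(self) -> str:
        lines = [f"{'class':<16}{'P':>8}{'R':>8}{'F1':>8}{'support':>9}"]
        for lab, (p, r, f1) in self.per_class.items():
            lines.append(f"{lab:<16}{p:>8.4f}{r:>8.4f}{f1:>8.4f}{self.support[lab]:>9}")
        p, r, f1 = self.micro
        lines.append(f"{'micro':<16}{p:>8.4f}{r:>8.4f}{f1:>8.4f}{sum(self.support.values()):>9}")
        return "\n".join(lines)


def prf(counts: ConfusionCounts) -> EvalReport:
    """Per-class precision/recall/F1 plus the micro average."""
    per_class = {lab: _prf_from(c.tp, c.fp, c.fn) for lab, c in counts.per_class.items()}
    support = {lab: c.tp + c.fn for lab, c in counts.per_class.items()}
    return EvalReport(per_class=per_class, support=support, micro=micro_average(counts))


def micro_average(counts: ConfusionCounts) -> tuple[float, float, float]:
    """Pool TP/FP/FN over classes, then apply the same three formulas."""
    if not counts.per_class:
        raise ValueError("micro average needs at least one class")
    tp = sum(c.tp for c in counts.per_class.values())
    fp = sum(c.fp for c in counts.per_class.values())
    fn = sum(c.fn for c in counts.per_class.values())
    return _prf_from(tp, fp, fn)


def binary_report(gold: Sequence[str], pred: Sequence[str], positive: str = "1") -> EvalReport:
    """Single-positive-class report: micro equals the positive-class P/R/F1."""
    counts = confusion(gold, pred)
    c = counts.per_class.get(positive, ClassCounts())
    per_class = {positive: _prf_from(c.tp, c.fp, c.fn)}
    return EvalReport(per_class=per_class,
                      support={positive: c.tp + c.fn},
                      micro=per_class[positive])
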