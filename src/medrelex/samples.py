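"""Balanced sentence-pair sample generation from annotated documents.

An annotated entity pair becomes a positive sample: the two entity names
joined by a space form the first sentence, the title-plus-abstract
document forms the second.  Negative samples are drawn uniformly, without
replacement, from the document's unannotated typed pairs (by default
Chemical x Disease) at a configurable negative:positive ratio (1:1 by
default, for a balanced classifier).  Corpora that annotate both classes
directly (TCM-style tables, multi-class temporal relations) bypass the
sampler via :func:`to_multiclass_instances`.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

from .corpus import DocumentRecord, RelationInstance

__all__ = [
    "SentencePairSample",
    "GenerationConfig",
    "surface_form",
    "make_positive_samples",
    "make_negative_samples",
    "generate_document_samples",
    "generate_corpus_samples",
    "attach_context_by_cooccurrence",
    "to_multiclass_instances",
    "instance_to_sample",
    "sample_to_instance",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class SentencePairSample:
    """One classification unit: entity-pair sentence, context sentence, label.

    ``id1``/``id2`` keep the concept identifiers for bookkeeping (negative-
    pool audits, deduplication); they do not enter the model input.
    """

    instance_id: str
    sentence_a: str
    sentence_b: str
    label: str
    id1: str = ""
    id2: str = ""

    def __post_init__(self) -> None:
        if not self.sentence_b:
            raise ValueError(f"sample {self.instance_id}: empty context")


@dataclass(frozen=True)
class GenerationConfig:
    """Negative-sampling settings."""

    neg_per_pos: float = 1.0
    seed: int = 0
    pair_rule: tuple[str, str] = ("Chemical", "Disease")

    def __post_init__(self) -> None:
        if self.neg_per_pos < 0:
            raise ValueError(f"neg_per_pos must be >= 0, got {self.neg_per_pos}")


def surface_form(doc: DocumentRecord, concept_id: str, lowercase: bool = True) -> str:
    """Name used for a concept in the pair sentence: its first mention's surface."""
    for m in doc.mentions:
        if m.concept_id == concept_id:
            return m.surface.lower() if lowercase else m.surface
    raise ValueError(f"concept {concept_id} has no mention in document {doc.doc_id}")


def make_positive_samples(doc: DocumentRecord, lowercase: bool = True) -> list[SentencePairSample]:
    """One positively labeled sample per relation annotation of the document."""
    out = []
    for i, rel in enumerate(doc.relations, start=1):
        out.append(
            SentencePairSample(
                instance_id=f"{doc.doc_id}_P{i}",
                sentence_a=f"{surface_form(doc, rel.id1, lowercase)} "
                           f"{surface_form(doc, rel.id2, lowercase)}",
                sentence_b=doc.text,
                label="1",
                id1=rel.id1,
                id2=rel.id2,
            )
        )
    return out


def negative_pool(doc: DocumentRecord, pair_rule: tuple[str, str] = ("Chemical", "Disease")) -> list[tuple[str, str]]:
    """All unannotated typed concept-id pairs of the document, in document order."""
    t1, t2 = pair_rule
    annotated = {(r.id1, r.id2) for r in doc.relations} | {(r.id2, r.id1) for r in doc.relations}
    pool = []
    for id1 in doc.concept_ids(t1):
        for id2 in doc.concept_ids(t2):
            if id1 != id2 and (id1, id2) not in annotated:
                pool.append((id1, id2))
    return pool


def make_negative_samples(doc: DocumentRecord, n_pos: int, cfg: GenerationConfig,
                          rng: np.random.Generator, lowercase: bool = True) -> list[SentencePairSample]:
    """Draw unannotated typed pairs uniformly without replacement.

    Emits ``min(round(n_pos * neg_per_pos), pool size)`` samples; a short
    pool is exhausted with a warning rather than an error.
    """
    pool = negative_pool(doc, cfg.pair_rule)
    want = int(round(n_pos * cfg.neg_per_pos))
    if want > len(pool):
        logger.warning(
            "document %s: negative pool (%d) smaller than requested (%d); emitting all",
            doc.doc_id, len(pool), want,
        )
        want = len(pool)
    chosen = rng.choice(len(pool), size=want, replace=False) if want else []
    out = []
    for j, k in enumerate(sorted(int(i) for i in chosen), start=1):
        id1, id2 = pool[k]
        out.append(
            SentencePairSample(
                instance_id=f"{doc.doc_id}_N{j}",
                sentence_a=f"{surface_form(doc, id1, lowercase)} "
                           f"{surface_form(doc, id2, lowercase)}",
                sentence_b=doc.text,
                label="0",
                id1=id1,
                id2=id2,
            )
        )
    return out


def generate_document_samples(doc: DocumentRecord, cfg: GenerationConfig,
                              rng: np.random.Generator | None = None) -> list[SentencePairSample]:
    """Positive then negative samples for one document."""
    if rng is None:
        rng = np.random.default_rng(cfg.seed)
    pos = make_positive_samples(doc)
    neg = make_negative_samples(doc, len(pos), cfg, rng)
    return pos + neg


def generate_corpus_samples(docs: Sequence[DocumentRecord], cfg: GenerationConfig,
                            balance: str = "document") -> list[SentencePairSample]:
    """Balanced generation over a whole corpus (one seeded stream).

    ``balance="document"`` draws each document's negatives against its own
    positive count.  ``balance="corpus"`` pools every document's
    unannotated typed pairs and draws the corpus-wide negative budget
    (``total positives x neg_per_pos``) uniformly from that pool, which
    also covers documents that carry no relation at all.
    """
    rng = np.random.default_rng(cfg.seed)
    out: list[SentencePairSample] = []
    if balance == "document":
        for doc in docs:
            out.extend(generate_document_samples(doc, cfg, rng))
    elif balance == "corpus":
        for doc in docs:
            out.extend(make_positive_samples(doc))
        n_pos = len(out)
        candidates = [(di, pair) for di, doc in enumerate(docs)
                      for pair in negative_pool(doc, cfg.pair_rule)]
        want = min(int(round(n_pos * cfg.neg_per_pos)), len(candidates))
        if want < int(round(n_pos * cfg.neg_per_pos)):
            logger.warning("corpus-wide negative pool (%d) smaller than requested (%d)",
                           len(candidates), int(round(n_pos * cfg.neg_per_pos)))
        chosen = sorted(int(i) for i in rng.choice(len(candidates), size=want, replace=False))
        counters: dict[int, int] = {}
        for k in chosen:
            di, (id1, id2) = candidates[k]
            doc = docs[di]
            j = counters[di] = counters.get(di, 0) + 1
            out.append(SentencePairSample(
                instance_id=f"{doc.doc_id}_N{j}",
                sentence_a=f"{surface_form(doc, id1)} {surface_form(doc, id2)}",
                sentence_b=doc.text, label="0", id1=id1, id2=id2))
    else:
        raise ValueError(f"balance must be 'document' or 'corpus', got {balance!r}")
    n_pos = sum(1 for s in out if s.label == "1")
    logger.info("generated %d samples (%d positive, %d negative) from %d documents",
                len(out), n_pos, len(out) - n_pos, len(docs))
    return out


def attach_context_by_cooccurrence(instances: Sequence[RelationInstance],
                                   literature: Sequence[str],
                                   case_insensitive: bool = True) -> list[RelationInstance]:
    """Keep instances whose two entity names co-occur in some abstract.

    The first abstract (in file order) containing both names, by exact
    substring match, becomes the instance's context; instances whose names
    never co-occur are dropped (the drop count is logged).
    """
    haystacks = [a.lower() for a in literature] if case_insensitive else list(literature)
    kept: list[RelationInstance] = []
    for inst in instances:
        n1 = inst.name1.lower() if case_insensitive else inst.name1
        n2 = inst.name2.lower() if case_insensitive else inst.name2
        for i, hay in enumerate(haystacks):
            if n1 in hay and n2 in hay:
                kept.append(replace(inst, context=literature[i]))
                break
    dropped = len(instances) - len(kept)
    logger.info("co-occurrence filtering kept %d of %d instances (%d dropped)",
                len(kept), len(instances), dropped)
    return kept


def instance_to_sample(inst: RelationInstance) -> SentencePairSample:
    """Canonical instance -> sentence-pair sample (names joined by a space)."""
    return SentencePairSample(
        instance_id=inst.instance_id,
        sentence_a=f"{inst.name1} {inst.name2}",
        sentence_b=inst.context,
        label=inst.label,
        id1=inst.id1,
        id2=inst.id2,
    )


def sample_to_instance(sample: SentencePairSample) -> RelationInstance:
    name1, _, name2 = sample.sentence_a.partition(" ")
    return RelationInstance(
        instance_id=sample.instance_id,
        name1=name1, id1=sample.id1,
        name2=name2, id2=sample.id2,
        label=sample.label,
        context=sample.sentence_b,
    )


def to_multiclass_instances(instances: Sequence[RelationInstance]) -> tuple[list[SentencePairSample], tuple[str, ...]]:
    """Pass annotated multi-class instances through unchanged.

    Returns the samples and the label set in fixed sorted order (the order
    downstream classifiers use for their output classes).
    """
    samples = [instance_to_sample(inst) for inst in instances]
    label_set = tuple(sorted({s.label for s in samples}))
    return samples, label_set
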