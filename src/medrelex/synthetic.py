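"""Synthetic corpora with the statistical structure the pipeline assumes.

Two generators are provided:

* :func:`generate_relation_corpus` builds abstract-level documents with
  typed chemical/disease mentions (exact character offsets) in which an
  entity pair carries a relation *iff* its two names are linked by a
  lexical trigger ("induced", "caused") inside one sentence.  Unrelated
  co-occurring pairs are joined by a neutral connective instead, so a
  rule-based trigger matcher separates the classes perfectly — that is
  the learnability guarantee the test harness relies on.
* :func:`generate_pretrain_corpus` builds multi-document, sentence-
  segmented text with Zipf-like token frequencies and per-document topic
  vocabulary, so both masked-token prediction and next-sentence
  prediction are learnable at miniature scale.

Both are deterministic given their seed.  :func:`fixture_1601297` returns
the worked-example abstract (a cocaine ECG study with two chemical-induced
disease annotations) used throughout the tests.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np

from .corpus import DocumentRecord, EntityMention, RelationAnnotation

__all__ = [
    "SynthConfig",
    "generate_relation_corpus",
    "generate_pretrain_corpus",
    "trigger_oracle_relations",
    "fixture_1601297",
    "CHEMICAL_NAMES",
    "DISEASE_NAMES",
]

_CHEM_SUFFIXES = ["arin", "odol", "exil", "amun", "ovir", "ipra", "etax", "anta", "ylen", "osin"]
_DIS_SUFFIXES = [
    "algia", "osis", "itis", "emia", "opathy", "oma",
    "plegia", "trophy", "penia", "rrhea", "edema", "uria",
]

#: Global pools of single-token entity names (small, so embeddings recur).
CHEMICAL_NAMES = tuple(f"chem{s}" for s in _CHEM_SUFFIXES)
DISEASE_NAMES = tuple(f"dis{s}" for s in _DIS_SUFFIXES)

_SYLLABLES = ["ba", "de", "ki", "lo", "mu", "ne", "pa", "ri", "so", "tu", "ve", "za"]


def _filler_vocab(size: int) -> list[str]:
    words = [a + b for a, b in itertools.product(_SYLLABLES, _SYLLABLES)]
    return words[:size]


@dataclass(frozen=True)
class SynthConfig:
    """Generator settings.

    Defaults define the easy, separable regime: one chemical and one
    disease per document, so an instance's label is decided by the local
    trigger trigram in its own context.  Raising ``diseases_per_doc``
    produces multi-pair documents whose samples share their context —
    the harder, genuinely relational regime.
    """

    n_docs: int = 200
    chemicals_per_doc: int = 1
    diseases_per_doc: int = 1
    relation_probability: float = 0.5
    trigger_lexicon: tuple[str, ...] = ("induced", "caused")
    connective_lexicon: tuple[str, ...] = ("accompanied", "alongside")
    filler_vocab_size: int = 60
    sentence_length_mean: float = 6.0
    n_filler_sentences: int = 2
    sentences_per_doc: int = 20  # pre-training corpus only
    trigger_dropout: float = 0.0  # difficulty knob: drop the trigger from a related pair
    distractor_triggers: float = 0.0  # difficulty knob: triggers in entity-free filler
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("relation_probability", "trigger_dropout", "distractor_triggers"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {v}")
        if set(self.trigger_lexicon) & set(self.connective_lexicon):
            raise ValueError("trigger and connective lexicons must be disjoint")


def _zipf_weights(n: int) -> np.ndarray:
    w = 1.0 / np.arange(1, n + 1)
    return w / w.sum()


def _filler_tokens(rng: np.random.Generator, vocab: list[str], weights: np.ndarray, k: int) -> list[str]:
    idx = rng.choice(len(vocab), size=k, p=weights)
    return [vocab[i] for i in idx]


def generate_relation_corpus(cfg: SynthConfig) -> list[DocumentRecord]:
    """Generate PubTator-writable documents with planted relation signal.

    Every typed (chemical, disease) pair co-occurring in a document appears
    in exactly one pair sentence: ``<chem> <trigger> <dis> ...`` when the
    pair is annotated as related, ``<chem> <connective> <dis> ...``
    otherwise.  Gold relations are recorded as CID annotations; offsets are
    exact against ``title + " " + abstract``.
    """
    rng = np.random.default_rng(cfg.seed)
    vocab = _filler_vocab(cfg.filler_vocab_size)
    weights = _zipf_weights(len(vocab))
    chem_ids = {name: f"D1{i:03d}" for i, name in enumerate(CHEMICAL_NAMES)}
    dis_ids = {name: f"D2{i:03d}" for i, name in enumerate(DISEASE_NAMES)}

    docs: list[DocumentRecord] = []
    for d in range(cfg.n_docs):
        doc_id = f"S{d:05d}"
        chems = list(rng.choice(CHEMICAL_NAMES, size=cfg.chemicals_per_doc, replace=False))
        dises = list(rng.choice(DISEASE_NAMES, size=cfg.diseases_per_doc, replace=False))

        # title mentions the first chemical
        title_tokens = [chems[0]] + _filler_tokens(rng, vocab, weights, 2)
        sentences: list[list[str]] = []
        related: list[tuple[str, str]] = []
        for c in chems:
            for dis in dises:
                tail = _filler_tokens(rng, vocab, weights, max(1, rng.poisson(cfg.sentence_length_mean - 3)))
                if rng.random() < cfg.relation_probability:
                    related.append((c, dis))
                    if rng.random() < cfg.trigger_dropout:
                        link = rng.choice(cfg.connective_lexicon)
                    else:
                        link = rng.choice(cfg.trigger_lexicon)
                else:
                    link = rng.choice(cfg.connective_lexicon)
                sentences.append([c, link, dis] + tail)
        for _ in range(cfg.n_filler_sentences):
            sent = _filler_tokens(rng, vocab, weights, max(3, rng.poisson(cfg.sentence_length_mean)))
            if cfg.distractor_triggers and rng.random() < cfg.distractor_triggers:
                sent.insert(rng.integers(0, len(sent) + 1), rng.choice(cfg.trigger_lexicon))
            sentences.append(sent)
        order = rng.permutation(len(sentences))
        sentences = [sentences[i] for i in order]

        title = " ".join(title_tokens)
        abstract = " ".join(" ".join(s) for s in sentences)
        text = f"{title} {abstract}"

        mentions: list[EntityMention] = []
        pos = 0
        for tok in text.split(" "):
            if tok in chem_ids:
                mentions.append(EntityMention(doc_id, pos, pos + len(tok), tok, "Chemical", chem_ids[tok]))
            elif tok in dis_ids:
                mentions.append(EntityMention(doc_id, pos, pos + len(tok), tok, "Disease", dis_ids[tok]))
            pos += len(tok) + 1

        relations = tuple(
            RelationAnnotation(doc_id, "CID", chem_ids[c], dis_ids[dis]) for c, dis in related
        )
        doc = DocumentRecord(doc_id, title, abstract, tuple(mentions), relations)
        doc.validate_offsets()
        docs.append(doc)
    return docs


def trigger_oracle_relations(doc: DocumentRecord, trigger_lexicon: tuple[str, ...] = ("induced", "caused")) -> set[tuple[str, str]]:
    """Rule-based reference extractor: (chem_id, dis_id) pairs linked by a trigger.

    Scans each sentence for the literal ``<chemical> <trigger> <disease>``
    token pattern.  On generator output with trigger_dropout = 0 and no
    distractors this recovers the gold annotations exactly.
    """
    chem_by_name = {m.surface: m.concept_id for m in doc.mentions if m.etype == "Chemical"}
    dis_by_name = {m.surface: m.concept_id for m in doc.mentions if m.etype == "Disease"}
    found: set[tuple[str, str]] = set()
    tokens = doc.text.split(" ")
    for i in range(len(tokens) - 2):
        a, link, b = tokens[i], tokens[i + 1], tokens[i + 2]
        if link in trigger_lexicon and a in chem_by_name and b in dis_by_name:
            found.add((chem_by_name[a], dis_by_name[b]))
    return found


def generate_pretrain_corpus(cfg: SynthConfig) -> list[list[str]]:
    """Sentence-segmented multi-document text for masked-token/next-sentence training.

    Each document mixes a shared high-frequency head vocabulary with a
    document-specific topic slice, giving intra-document continuity (a
    next-sentence probe can tell same-document pairs from random ones)
    while overall token frequencies stay approximately Zipfian.  Entity
    names and trigger words are sprinkled in so their embeddings are
    covered by pre-training.
    """
    rng = np.random.default_rng(cfg.seed)
    vocab = _filler_vocab(cfg.filler_vocab_size)
    weights = _zipf_weights(len(vocab))
    links = list(cfg.trigger_lexicon) + list(cfg.connective_lexicon)

    corpus: list[list[str]] = []
    n_topics = max(1, (len(vocab) - 10) // 4)
    for d in range(cfg.n_docs):
        topic = 10 + 4 * (d % n_topics)
        topic_words = vocab[topic : topic + 4] or vocab[10:14]
        # a few entities recur throughout the document, as in real abstracts;
        # their repetition makes masked copies of them predictable and gives
        # consecutive sentences the shared signature next-sentence
        # prediction relies on
        topic_entities = [str(rng.choice(CHEMICAL_NAMES)), str(rng.choice(DISEASE_NAMES))]
        sentences: list[str] = []
        for _ in range(cfg.sentences_per_doc):
            k = max(4, int(rng.poisson(cfg.sentence_length_mean)))
            toks: list[str] = []
            for _ in range(k):
                u = rng.random()
                if u < 0.20:
                    toks.append(topic_entities[rng.integers(len(topic_entities))])
                elif u < 0.25:
                    toks.append(links[rng.integers(len(links))])
                elif u < 0.65:
                    toks.append(topic_words[rng.integers(len(topic_words))])
                else:
                    toks.append(vocab[rng.choice(len(vocab), p=weights)])
            sentences.append(" ".join(toks))
        corpus.append(sentences)
    return corpus


def fixture_1601297() -> DocumentRecord:
    """The worked-example BC5CDR record (PMID 1601297): a cocaine ECG study.

    One chemical concept (D003042, cocaine), five disease concepts and two
    chemical-induced-disease annotations; nine mentions with exact offsets
    into ``title + " " + abstract``.
    """
    doc_id = "1601297"
    title = (
        "Electrocardiographic evidence of myocardial injury in "
        "psychiatrically hospitalized cocaine abusers."
    )
    abstract = (
        "The electrocardiograms (ECG) of 99 cocaine-abusing patients were "
        "compared with the ECGs of 50 schizophrenic controls. Eleven of the "
        "cocaine abusers and none of the controls had ECG evidence of "
        "significant myocardial injury defined as myocardial infarction, "
        "ischemia, and bundle branch block."
    )
    rows = [
        (33, 50, "Myocardial injury", "Disease", "D009202"),
        (83, 90, "Cocaine", "Chemical", "D003042"),
        (135, 142, "Cocaine", "Chemical", "D003042"),
        (194, 207, "Schizophrenic", "Disease", "D012559"),
        (232, 239, "Cocaine", "Chemical", "D003042"),
        (305, 322, "Myocardial injury", "Disease", "D009202"),
        (334, 355, "Myocardial infarction", "Disease", "D009203"),
        (357, 365, "Ischemia", "Disease", "D007511"),
        (371, 390, "Bundle branch block", "Disease", "D002037"),
    ]
    mentions = tuple(EntityMention(doc_id, s, e, surf, et, cid) for s, e, surf, et, cid in rows)
    relations = (
        RelationAnnotation(doc_id, "CID", "D003042", "D009203"),
        RelationAnnotation(doc_id, "CID", "D003042", "D002037"),
    )
    doc = DocumentRecord(doc_id, title, abstract, mentions, relations)
    doc.validate_offsets()
    return doc
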