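"""Corpus readers/writers and the canonical relation-instance format.

Three interchange formats are supported:

* **PubTator** — the text-mining format used by abstract-level
  chemical/disease corpora: ``pid|t|title`` and ``pid|a|abstract`` lines
  followed by tab-delimited mention lines
  (``pid  start  end  surface  type  concept_id``) and relation lines
  (``pid  rtype  id1  id2``), documents separated by a blank line.
* **TCM relation tables** — six tab-separated columns
  (``ID  EntityID1  EntityName1  EntityID2  EntityName2  Label``) with the
  literature that provides context kept in a separate file.
* **Canonical instance TSV** — the seven-column format every downstream
  stage consumes: ``instance_id  name1  id1  name2  id2  label  context``.

Mention offsets are character offsets, 0-based and end-exclusive, counted
against ``title + " " + abstract`` (a single separating space).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Iterator, Mapping, Sequence

__all__ = [
    "EntityMention",
    "RelationAnnotation",
    "DocumentRecord",
    "RelationInstance",
    "PubTatorError",
    "read_pubtator",
    "write_pubtator",
    "read_tcm_table",
    "read_instances_tsv",
    "write_instances_tsv",
]


class PubTatorError(ValueError):
    """Malformed corpus input (carries the offending line number)."""


@dataclass(frozen=True)
class EntityMention:
    """A typed entity mention anchored to character offsets in a document."""

    doc_id: str
    start: int
    end: int
    surface: str
    etype: str
    concept_id: str

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"mention {self.doc_id}:{self.concept_id}: need 0 <= start < end, "
                f"got [{self.start}, {self.end})"
            )
        if self.end - self.start != len(self.surface):
            raise ValueError(
                f"mention {self.doc_id}:{self.concept_id} ({self.surface!r}): span length "
                f"{self.end - self.start} != surface length {len(self.surface)}"
            )
        if not self.etype:
            raise ValueError(f"mention {self.doc_id}:{self.concept_id}: empty entity type")


@dataclass(frozen=True)
class RelationAnnotation:
    """A relation between two concept identifiers within one document."""

    doc_id: str
    rtype: str
    id1: str
    id2: str
    directed: bool = False

    def __post_init__(self) -> None:
        if not self.rtype:
            raise ValueError(f"relation in {self.doc_id}: empty relation type")


@dataclass(frozen=True)
class DocumentRecord:
    """One abstract-level document with its mentions and relations."""

    doc_id: str
    title: str
    abstract: str
    mentions: tuple[EntityMention, ...] = ()
    relations: tuple[RelationAnnotation, ...] = ()

    @property
    def text(self) -> str:
        """Title and abstract joined by a single space; offsets index into this."""
        return f"{self.title} {self.abstract}"

    def validate_offsets(self) -> None:
        """Check every mention span against the document text (case-insensitive)."""
        text = self.text
        for m in self.mentions:
            if m.end > len(text):
                raise ValueError(
                    f"mention {m.concept_id} [{m.start},{m.end}) exceeds document "
                    f"{self.doc_id} length {len(text)}"
                )
            span = text[m.start : m.end]
            if span.lower() != m.surface.lower():
                raise ValueError(
                    f"mention {m.concept_id} in {self.doc_id}: text span {span!r} "
                    f"does not match surface {m.surface!r}"
                )

    def concept_ids(self, etype: str) -> tuple[str, ...]:
        """Distinct concept ids of one entity type, in first-mention order."""
        seen: dict[str, None] = {}
        for m in self.mentions:
            if m.etype == etype:
                seen.setdefault(m.concept_id, None)
        return tuple(seen)


@dataclass(frozen=True)
class RelationInstance:
    """Canonical classification unit: an entity pair, a label and its context."""

    instance_id: str
    name1: str
    id1: str
    name2: str
    id2: str
    label: str
    context: str = ""


# ---------------------------------------------------------------------------
# PubTator
# ---------------------------------------------------------------------------


def read_pubtator(stream: Iterable[str], *, validate: bool = True) -> list[DocumentRecord]:
    """Parse a PubTator stream into :class:`DocumentRecord` objects.

    Documents are separated by blank lines; within a document, mention and
    relation order is preserved.  With ``validate`` (default) every mention
    span is checked against ``title + " " + abstract``.
    """
    docs: list[DocumentRecord] = []
    cur_id: str | None = None
    title = ""
    abstract = ""
    mentions: list[EntityMention] = []
    relations: list[RelationAnnotation] = []

    def flush() -> None:
        nonlocal cur_id, title, abstract, mentions, relations
        if cur_id is None:
            return
        doc = DocumentRecord(cur_id, title, abstract, tuple(mentions), tuple(relations))
        if validate:
            try:
                doc.validate_offsets()
            except ValueError as exc:
                raise PubTatorError(str(exc)) from exc
        docs.append(doc)
        cur_id, title, abstract = None, "", ""
        mentions, relations = [], []

    for lineno, raw in enumerate(stream, start=1):
        line = raw.rstrip("\n")
        if not line.strip():
            flush()
            continue
        if "|t|" in line or "|a|" in line:
            pid, kind, text = line.split("|", 2)
            if cur_id is not None and pid != cur_id:
                flush()
            cur_id = pid
            if kind == "t":
                title = text
            else:
                abstract = text
            continue
        fields = line.split("\t")
        pid = fields[0]
        if cur_id is not None and pid != cur_id:
            flush()
            cur_id = pid
        elif cur_id is None:
            cur_id = pid
        if len(fields) == 6:
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError as exc:
                raise PubTatorError(
                    f"line {lineno}: non-integer offsets in mention line: {line!r}"
                ) from exc
            try:
                mentions.append(
                    EntityMention(pid, start, end, fields[3], fields[4], fields[5])
                )
            except ValueError as exc:
                raise PubTatorError(f"line {lineno}: {exc}") from exc
        elif len(fields) == 4:
            relations.append(RelationAnnotation(pid, fields[1], fields[2], fields[3]))
        else:
            raise PubTatorError(
                f"line {lineno}: expected 6 fields (mention) or 4 fields (relation), "
                f"got {len(fields)}: {line!r}"
            )
    flush()
    return docs


def write_pubtator(docs: Sequence[DocumentRecord]) -> Iterator[str]:
    """Serialize documents to canonical PubTator lines (with trailing newlines).

    Mention lines are emitted sorted by start offset; every record is
    validated before any output is produced.
    """
    for doc in docs:
        doc.validate_offsets()
    for doc in docs:
        yield f"{doc.doc_id}|t|{doc.title}\n"
        yield f"{doc.doc_id}|a|{doc.abstract}\n"
        for m in sorted(doc.mentions, key=lambda m: (m.start, m.end)):
            yield f"{m.doc_id}\t{m.start}\t{m.end}\t{m.surface}\t{m.etype}\t{m.concept_id}\n"
        for r in doc.relations:
            yield f"{r.doc_id}\t{r.rtype}\t{r.id1}\t{r.id2}\n"
        yield "\n"


# ---------------------------------------------------------------------------
# TCM-style relation tables
# ---------------------------------------------------------------------------


def read_tcm_table(relations: Iterable[str]) -> list[RelationInstance]:
    """Read a 6-column relation table; contexts are left empty.

    Columns: ``ID  EntityID1  EntityName1  EntityID2  EntityName2  Label``.
    Labels are preserved verbatim.  Context attachment is a separate step
    (:func:`medrelex.samples.attach_context_by_cooccurrence`).
    """
    out: list[RelationInstance] = []
    for lineno, raw in enumerate(relations, start=1):
        line = raw.rstrip("\n")
        if not line.strip():
            continue
        fields = line.split("\t")
        if len(fields) != 6:
            raise PubTatorError(
                f"line {lineno}: expected 6 tab-separated fields, got {len(fields)}: {line!r}"
            )
        rid, id1, name1, id2, name2, label = fields
        out.append(RelationInstance(rid, name1, id1, name2, id2, label, context=""))
    return out


# ---------------------------------------------------------------------------
# Canonical instance TSV
# ---------------------------------------------------------------------------

_TSV_HEADER = "instance_id\tname1\tid1\tname2\tid2\tlabel\tcontext"


def write_instances_tsv(instances: Sequence[RelationInstance]) -> Iterator[str]:
    """Serialize instances to the 7-column canonical TSV (header included)."""
    yield _TSV_HEADER + "\n"
    for inst in instances:
        for name, value in (("context", inst.context), ("label", inst.label)):
            if "\t" in value or "\n" in value:
                raise ValueError(
                    f"instance {inst.instance_id}: {name} contains a tab or newline; "
                    "replace internal tabs/newlines with spaces before writing"
                )
        yield (
            f"{inst.instance_id}\t{inst.name1}\t{inst.id1}\t{inst.name2}\t{inst.id2}"
            f"\t{inst.label}\t{inst.context}\n"
        )


def read_instances_tsv(stream: Iterable[str]) -> list[RelationInstance]:
    """Read the canonical 7-column instance TSV (header optional)."""
    out: list[RelationInstance] = []
    for lineno, raw in enumerate(stream, start=1):
        line = raw.rstrip("\n")
        if not line.strip():
            continue
        if lineno == 1 and line == _TSV_HEADER:
            continue
        fields = line.split("\t")
        if len(fields) != 7:
            raise PubTatorError(
                f"line {lineno}: expected 7 tab-separated fields, got {len(fields)}: {line!r}"
            )
        out.append(RelationInstance(*fields))
    return out
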