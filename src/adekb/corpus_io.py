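"""Data model and I/O for sentence-level annotated ADE-style corpora.

An ADE-style relation file is pipe-delimited, one drug/adverse-effect
relation per line::

    doc_id|sentence|effect_text|effect_start|effect_end|drug_text|drug_start|drug_end

Offsets in such files may follow any of the four common conventions
(0- or 1-based, half-open or closed); the reader detects the convention
from surface/slice agreement and applies one consistent correction to
the whole file.  Internally all spans are document-level, 0-based,
half-open, where a document's text is its sentences joined by a single
space.
"""

from __future__ import annotations

import random
import re
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Sequence, TextIO

DRUG = "DRUG"
ADVERSE_EFFECT = "ADVERSE_EFFECT"

#: default field order of an ADE-style relation line
ADE_FIELDS = (
    "doc_id",
    "sentence",
    "effect_text",
    "effect_start",
    "effect_end",
    "drug_text",
    "drug_start",
    "drug_end",
)

#: (base, closed_end) candidate offset conventions, tried in this order
_OFFSET_CONVENTIONS = ((0, 0), (1, 0), (0, 1), (1, 1))


@dataclass(frozen=True, order=True)
class TextSpan:
    """A 0-based half-open character interval at document level."""

    start: int
    end: int

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(f"invalid span [{self.start}, {self.end})")

    def overlaps(self, other: "TextSpan") -> bool:
        return self.start < other.end and other.start < self.end

    def contains(self, other: "TextSpan") -> bool:
        return self.start <= other.start and other.end <= self.end

    def shifted(self, delta: int) -> "TextSpan":
        return TextSpan(self.start + delta, self.end + delta)


@dataclass(frozen=True)
class GoldEntity:
    span: TextSpan
    surface: str
    role: str  # DRUG or ADVERSE_EFFECT

    def __post_init__(self) -> None:
        if self.role not in (DRUG, ADVERSE_EFFECT):
            raise ValueError(f"unknown role {self.role!r}")


@dataclass(frozen=True)
class GoldRelation:
    doc_id: str
    sentence_index: int
    drug: GoldEntity
    effect: GoldEntity

    def __post_init__(self) -> None:
        if self.drug.role != DRUG or self.effect.role != ADVERSE_EFFECT:
            raise ValueError("GoldRelation roles are fixed: drug=DRUG, effect=ADVERSE_EFFECT")

    @property
    def nested(self) -> bool:
        """True when one entity span lies inside the other (e.g. the drug
        'lithium' inside the effect 'acute lithium intoxicity')."""
        return self.drug.span.contains(self.effect.span) or self.effect.span.contains(self.drug.span)


@dataclass(frozen=True)
class SentenceRecord:
    doc_id: str
    sentence_index: int
    text: str
    span: TextSpan
    gold_relations: tuple[GoldRelation, ...] = ()

    @property
    def is_positive(self) -> bool:
        return len(self.gold_relations) > 0


@dataclass
class Corpus:
    """Ordered sentences grouped by document."""

    documents: dict[str, list[SentenceRecord]] = field(default_factory=dict)

    @property
    def n_documents(self) -> int:
        return len(self.documents)

    @property
    def n_sentences(self) -> int:
        return sum(len(s) for s in self.documents.values())

    @property
    def n_relations(self) -> int:
        return sum(len(r.gold_relations) for r in self.sentences())

    def sentences(self) -> Iterator[SentenceRecord]:
        for doc_id in self.documents:
            yield from self.documents[doc_id]

    def gold_relations(self) -> Iterator[GoldRelation]:
        for rec in self.sentences():
            yield from rec.gold_relations

    def document_text(self, doc_id: str) -> str:
        """Reconstruct document text (sentences joined by single spaces)."""
        parts: list[str] = []
        pos = 0
        for rec in self.documents[doc_id]:
            parts.append(" " * (rec.span.start - pos))
            parts.append(rec.text)
            pos = rec.span.end
        return "".join(parts)

    def validate(self) -> None:
        """Check span/surface consistency; raises ValueError on violation."""
        for doc_id, records in self.documents.items():
            text = self.document_text(doc_id)
            prev_end = -1
            for rec in records:
                if rec.span.start <= prev_end:
                    raise ValueError(f"{doc_id}: overlapping or unordered sentence spans")
                prev_end = rec.span.end
                if text[rec.span.start : rec.span.end] != rec.text:
                    raise ValueError(f"{doc_id}: sentence text does not match its span")
                for rel in rec.gold_relations:
                    for ent in (rel.drug, rel.effect):
                        if not rec.span.contains(ent.span):
                            raise ValueError(f"{doc_id}: gold entity outside its sentence")
                        if text[ent.span.start : ent.span.end] != ent.surface:
                            raise ValueError(
                                f"{doc_id}: surface {ent.surface!r} does not match slice"
                            )


@dataclass
class CorpusSplit:
    train: Corpus
    test: Corpus
    seed: int


@dataclass
class ParseReport:
    """Per-file diagnostics of an ADE read: non-fatal errors and the
    offset convention that was applied."""

    errors: list[str] = field(default_factory=list)
    offset_base: int = 0
    closed_end: bool = False
    n_lines: int = 0
    n_relations: int = 0


class CorpusFormatError(ValueError):
    pass


def _detect_convention(rows: Sequence[dict[str, str]]) -> tuple[int, int]:
    """Pick the (base, closed_end) correction under which entity surfaces
    agree with the sentence slice on the first parsable rows."""
    for base, closed in _OFFSET_CONVENTIONS:
        ok = True
        for row in rows[:25]:
            sent = row["sentence"]
            for prefix in ("effect", "drug"):
                start = int(row[f"{prefix}_start"]) - base
                end = int(row[f"{prefix}_end"]) - base + closed
                if not (0 <= start < end <= len(sent)) or sent[start:end] != row[f"{prefix}_text"]:
                    ok = False
                    break
            if not ok:
                break
        if ok:
            return base, closed
    raise CorpusFormatError(
        "entity offsets do not match surfaces under any supported convention "
        "(0/1-based x half-open/closed, sentence-relative)"
    )


def read_ade_file(
    stream: Iterable[str],
    fields: Sequence[str] = ADE_FIELDS,
    report: ParseReport | None = None,
) -> Corpus:
    """Read a pipe-delimited ADE-style relation file into a :class:`Corpus`.

    Lines sharing (doc_id, sentence text) merge into one
    :class:`SentenceRecord` carrying multiple gold relations.  Malformed
    lines are collected in *report* and skipped; an unresolvable offset
    convention is fatal.
    """
    if report is None:
        report = ParseReport()
    n_fields = len(fields)
    rows: list[dict[str, str]] = []
    for lineno, line in enumerate(stream, start=1):
        line = line.rstrip("\n")
        if not line.strip():
            continue
        report.n_lines += 1
        parts = line.split("|")
        if len(parts) != n_fields:
            report.errors.append(f"line {lineno}: expected {n_fields} fields, got {len(parts)}")
            continue
        row = dict(zip(fields, parts))
        try:
            for key in ("effect_start", "effect_end", "drug_start", "drug_end"):
                int(row[key])
        except ValueError:
            report.errors.append(f"line {lineno}: non-integer offset field")
            continue
        row["_lineno"] = str(lineno)
        rows.append(row)

    if not rows:
        return Corpus()

    base, closed = _detect_convention(rows)
    report.offset_base, report.closed_end = base, bool(closed)

    # group relations by (doc_id, sentence text), preserving first-seen order
    grouped: dict[tuple[str, str], list[dict[str, str]]] = {}
    doc_order: dict[str, list[tuple[str, str]]] = {}
    for row in rows:
        key = (row["doc_id"], row["sentence"])
        if key not in grouped:
            grouped[key] = []
            doc_order.setdefault(row["doc_id"], []).append(key)
        grouped[key].append(row)

    corpus = Corpus()
    for doc_id, keys in doc_order.items():
        records: list[SentenceRecord] = []
        offset = 0
        for sent_idx, key in enumerate(keys):
            sentence = key[1]
            sent_span = TextSpan(offset, offset + len(sentence))
            relations: list[GoldRelation] = []
            for row in grouped[key]:
                ents = {}
                bad = False
                for prefix, role in (("drug", DRUG), ("effect", ADVERSE_EFFECT)):
                    start = int(row[f"{prefix}_start"]) - base
                    end = int(row[f"{prefix}_end"]) - base + closed
                    surface = row[f"{prefix}_text"]
                    if not (0 <= start < end <= len(sentence)) or sentence[start:end] != surface:
                        report.errors.append(
                            f"line {row['_lineno']}: {prefix} surface does not match offsets"
                        )
                        bad = True
                        break
                    ents[prefix] = GoldEntity(TextSpan(start + offset, end + offset), surface, role)
                if bad:
                    continue
                rel = GoldRelation(doc_id, sent_idx, ents["drug"], ents["effect"])
                if rel not in relations:
                    relations.append(rel)
                    report.n_relations += 1
            records.append(
                SentenceRecord(doc_id, sent_idx, sentence, sent_span, tuple(relations))
            )
            offset = sent_span.end + 1  # single space between sentences
        corpus.documents[doc_id] = records
    return corpus


def read_negative_sentences(stream: Iterable[str], corpus: Corpus | None = None) -> Corpus:
    """Read a `doc_id|sentence` file of relation-free sentences, appending
    to *corpus* (documents may already hold positive sentences)."""
    corpus = corpus if corpus is not None else Corpus()
    for lineno, line in enumerate(stream, start=1):
        line = line.rstrip("\n")
        if not line.strip():
            continue
        parts = line.split("|", 1)
        if len(parts) != 2:
            raise CorpusFormatError(f"line {lineno}: expected doc_id|sentence")
        doc_id, sentence = parts
        records = corpus.documents.setdefault(doc_id, [])
        offset = records[-1].span.end + 1 if records else 0
        records.append(
            SentenceRecord(doc_id, len(records), sentence, TextSpan(offset, offset + len(sentence)))
        )
    return corpus


def write_ade_file(corpus: Corpus, stream: TextIO, negatives_stream: TextIO | None = None) -> None:
    """Write *corpus* in ADE format (sentence-relative 0-based half-open
    offsets).  Relation-free sentences go to *negatives_stream* if given,
    else are omitted.  write∘read is the identity on valid corpora."""
    for rec in corpus.sentences():
        if rec.gold_relations:
            for rel in rec.gold_relations:
                eff, drug = rel.effect, rel.drug
                off = rec.span.start
                stream.write(
                    "|".join(
                        (
                            rec.doc_id,
                            rec.text,
                            eff.surface,
                            str(eff.span.start - off),
                            str(eff.span.end - off),
                            drug.surface,
                            str(drug.span.start - off),
                            str(drug.span.end - off),
                        )
                    )
                    + "\n"
                )
        elif negatives_stream is not None:
            negatives_stream.write(f"{rec.doc_id}|{rec.text}\n")


_ABBREV_EXCEPTIONS = frozenset(
    "e.g. i.e. etc. vs. dr. mr. mrs. ms. fig. al. approx. ca. cf. no. st.".split()
)

_SENT_BOUNDARY = re.compile(r"(?<=[.!?])\s+")


def segment_sentences(text: str) -> list[TextSpan]:
    """Rule-based sentence segmentation: split after terminal punctuation
    followed by whitespace, except after known abbreviations."""
    spans: list[TextSpan] = []
    start = 0
    for m in _SENT_BOUNDARY.finditer(text):
        candidate = text[start : m.start()]
        last_word = candidate.rsplit(None, 1)[-1].lower() if candidate.split() else ""
        if last_word in _ABBREV_EXCEPTIONS:
            continue
        if candidate.strip():
            spans.append(TextSpan(start, m.start()))
        start = m.end()
    if text[start:].strip():
        stripped = text[start:].rstrip()
        spans.append(TextSpan(start, start + len(stripped)))
    return spans


def load_plain_abstracts(stream: Iterable[str]) -> Corpus:
    """Load `doc_id TAB abstract-text` lines, one abstract per line,
    sentence-segmenting each abstract.  Gold annotations are empty."""
    corpus = Corpus()
    for lineno, line in enumerate(stream, start=1):
        line = line.rstrip("\n")
        if not line.strip():
            continue
        parts = line.split("\t", 1)
        if len(parts) != 2:
            raise CorpusFormatError(f"line {lineno}: expected doc_id TAB text")
        doc_id, text = parts
        if doc_id in corpus.documents:
            raise CorpusFormatError(f"line {lineno}: duplicate doc_id {doc_id!r}")
        records = [
            SentenceRecord(doc_id, i, text[s.start : s.end], s)
            for i, s in enumerate(segment_sentences(text))
        ]
        corpus.documents[doc_id] = records
    return corpus


def subset(corpus: Corpus, doc_ids: Iterable[str]) -> Corpus:
    out = Corpus()
    for doc_id in doc_ids:
        out.documents[doc_id] = list(corpus.documents[doc_id])
    return out


def split_corpus(corpus: Corpus, n_train: int, seed: int) -> CorpusSplit:
    """Seeded train/test split at document level.

    Doc ids are sorted before sampling so the split is reproducible
    regardless of storage order.
    """
    ids = sorted(corpus.documents)
    if not (0 <= n_train <= len(ids)):
        raise ValueError(f"n_train={n_train} outside [0, {len(ids)}]")
    rng = random.Random(seed)
    train_ids = set(rng.sample(ids, n_train))
    return CorpusSplit(
        train=subset(corpus, [i for i in ids if i in train_ids]),
        test=subset(corpus, [i for i in ids if i not in train_ids]),
        seed=seed,
    )
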