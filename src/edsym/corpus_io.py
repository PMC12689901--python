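"""Annotated-corpus containers, Doccano JSONL I/O, span validation and guideline linting.

The corpus unit is a short free-text anamnesis narrative.  Annotations are
character-offset spans over three entity classes: symptom mentions, anatomical
references, and negation cues.  Offsets are 0-based, half-open ``[start, end)``
character intervals (Doccano's native convention), and every span carries the
materialised surface string so that downstream code never has to re-slice the
document text.

Annotation-guideline linting encodes two harmonisation rules for German
clinical text:

* compound symptom words ("Kopfschmerzen") must be annotated as a single span,
  never split into an anatomy span plus a symptom span; and
* slash-separated anatomy lists ("Rücken/Hüfte") must be annotated as separate
  anatomy spans, never as one span containing the slash.
"""

from __future__ import annotations

import io
import json
from collections.abc import Iterable, Iterator, Mapping
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import TextIO


class EntityLabel(str, Enum):
    """The closed set of entity classes annotated in the corpus."""

    SYMPTOM = "SYMPTOM"
    ANATOMY = "ANATOMY"
    NEGATION = "NEGATION"


class CorpusError(Exception):
    """Base class for corpus reading/validation failures."""


class DoccanoFormatError(CorpusError):
    """A JSONL line could not be parsed; carries the 1-based line number."""

    def __init__(self, lineno: int, message: str):
        self.lineno = lineno
        super().__init__(f"line {lineno}: {message}")


class SpanBoundsError(CorpusError):
    """A span's offsets fall outside its document; names doc and span."""

    def __init__(self, doc_id: str, start: int, end: int, message: str):
        self.doc_id = doc_id
        self.start = start
        self.end = end
        super().__init__(f"doc {doc_id!r}, span ({start}, {end}): {message}")


@dataclass(frozen=True)
class Document:
    """One narrative: an identifier, its text, and free-form metadata."""

    doc_id: str
    text: str
    metadata: Mapping[str, object] | None = None

    def __post_init__(self) -> None:
        if not self.text:
            raise ValueError(f"document {self.doc_id!r}: text must be non-empty")


@dataclass(frozen=True, order=True)
class Span:
    """A labeled character interval within one document.

    ``surface`` must equal ``text[start:end]`` of the owning document;
    ``confidence`` is an optional backend score in [0, 1].
    """

    doc_id: str
    start: int
    end: int
    label: EntityLabel
    surface: str
    confidence: float | None = field(default=None, compare=False)

    @property
    def triple(self) -> tuple[int, int, EntityLabel]:
        return (self.start, self.end, self.label)

    def overlap(self, other: "Span") -> int:
        """Character overlap length with another span (0 if disjoint)."""
        return max(0, min(self.end, other.end) - max(self.start, other.start))


class Corpus:
    """An ordered collection of documents with unique ids."""

    def __init__(self, documents: Iterable[Document] = ()):
        self._docs: dict[str, Document] = {}
        for doc in documents:
            self.add(doc)

    def add(self, doc: Document) -> None:
        if doc.doc_id in self._docs:
            raise CorpusError(f"duplicate doc_id {doc.doc_id!r}")
        self._docs[doc.doc_id] = doc

    def __getitem__(self, doc_id: str) -> Document:
        return self._docs[doc_id]

    def __contains__(self, doc_id: str) -> bool:
        return doc_id in self._docs

    def __iter__(self) -> Iterator[Document]:
        return iter(self._docs.values())

    def __len__(self) -> int:
        return len(self._docs)

    @property
    def doc_ids(self) -> list[str]:
        return list(self._docs)


class AnnotationSet:
    """Spans from one annotator (or one backend), grouped by document.

    Duplicate ``(start, end, label)`` triples within one document are
    rejected; overlapping spans of *different* labels are allowed (a negation
    cue may abut or overlap a symptom).
    """

    def __init__(self, annotator_id: str, spans: Iterable[Span] = ()):
        self.annotator_id = annotator_id
        self._by_doc: dict[str, list[Span]] = {}
        for span in spans:
            self.add(span)

    def add(self, span: Span) -> None:
        doc_spans = self._by_doc.setdefault(span.doc_id, [])
        if any(s.triple == span.triple for s in doc_spans):
            raise CorpusError(
                f"doc {span.doc_id!r}: duplicate span {span.triple}"
            )
        doc_spans.append(span)
        doc_spans.sort(key=lambda s: (s.start, s.end, s.label.value))

    def for_doc(self, doc_id: str) -> list[Span]:
        return list(self._by_doc.get(doc_id, []))

    @property
    def doc_ids(self) -> list[str]:
        return sorted(self._by_doc)

    def all_spans(self) -> list[Span]:
        return [s for doc_id in sorted(self._by_doc) for s in self._by_doc[doc_id]]

    def __len__(self) -> int:
        return sum(len(v) for v in self._by_doc.values())


@dataclass(frozen=True)
class UnknownLabelSpan:
    """A span whose label string is outside the closed entity set."""

    doc_id: str
    start: int
    end: int
    label: str
    lineno: int


@dataclass
class ReadReport:
    """Side-channel of a Doccano read: what was excluded, not what failed."""

    unknown_label_spans: list[UnknownLabelSpan] = field(default_factory=list)

    @property
    def clean(self) -> bool:
        return not self.unknown_label_spans


def _coerce_lines(source: str | Path | TextIO | Iterable[str]) -> Iterable[str]:
    if isinstance(source, Path):
        return source.read_text(encoding="utf-8").splitlines()
    if isinstance(source, str):
        return io.StringIO(source)
    return source


def read_doccano(
    source: str | Path | TextIO | Iterable[str],
    annotator_id: str = "gold",
) -> tuple[Corpus, AnnotationSet, ReadReport]:
    """Read a Doccano-style JSONL export.

    Each line is one JSON object with ``text`` and either ``label`` or
    ``entities`` holding ``[start, end, label]`` triples.  Surfaces are
    materialised from the text.  Unknown label strings are collected in the
    returned :class:`ReadReport` and excluded from the annotation set rather
    than failing the whole file; malformed JSON and out-of-bounds offsets are
    hard errors naming the line/doc.
    """
    corpus = Corpus()
    annotations = AnnotationSet(annotator_id)
    report = ReadReport()
    known = {label.value for label in EntityLabel}

    for lineno, raw in enumerate(_coerce_lines(source), start=1):
        line = raw.strip()
        if not line:
            continue
        try:
            obj = json.loads(line)
        except json.JSONDecodeError as exc:
            raise DoccanoFormatError(lineno, f"malformed JSON ({exc.msg})") from exc
        if not isinstance(obj, dict) or "text" not in obj:
            raise DoccanoFormatError(lineno, "object lacks a 'text' field")
        doc_id = str(obj.get("id", lineno))
        text = obj["text"]
        if not isinstance(text, str) or not text:
            raise DoccanoFormatError(lineno, f"doc {doc_id!r}: empty or non-string text")
        meta = obj.get("metadata") or obj.get("meta")
        corpus.add(Document(doc_id, text, meta))

        triples = obj.get("label", obj.get("entities", []))
        if triples is None:
            triples = []
        if not isinstance(triples, list):
            raise DoccanoFormatError(lineno, "'label' field is not a list")
        for triple in triples:
            try:
                start, end, label_str = triple
                start, end = int(start), int(end)
            except (TypeError, ValueError) as exc:
                raise DoccanoFormatError(
                    lineno, f"bad label triple {triple!r}"
                ) from exc
            if not (0 <= start < end <= len(text)):
                raise SpanBoundsError(
                    doc_id, start, end,
                    f"offsets out of bounds for text of length {len(text)}",
                )
            if label_str not in known:
                report.unknown_label_spans.append(
                    UnknownLabelSpan(doc_id, start, end, str(label_str), lineno)
                )
                continue
            annotations.add(
                Span(doc_id, start, end, EntityLabel(label_str), text[start:end])
            )
    return corpus, annotations, report


def write_doccano(
    corpus: Corpus,
    annotations: AnnotationSet,
    sink: TextIO | Path | None = None,
) -> str:
    """Write a corpus back to Doccano JSONL (``label`` field dialect).

    Returns the serialised text; also writes it to ``sink`` when given.
    Round trip: reading the output reproduces the same (text, start, end,
    label) tuples line for line.
    """
    lines = []
    for doc in corpus:
        triples = [
            [s.start, s.end, s.label.value] for s in annotations.for_doc(doc.doc_id)
        ]
        obj: dict[str, object] = {"id": doc.doc_id, "text": doc.text, "label": triples}
        if doc.metadata:
            obj["metadata"] = dict(doc.metadata)
        lines.append(json.dumps(obj, ensure_ascii=False))
    out = "\n".join(lines) + ("\n" if lines else "")
    if isinstance(sink, Path):
        sink.write_text(out, encoding="utf-8")
    elif sink is not None:
        sink.write(out)
    return out


@dataclass(frozen=True)
class SpanViolation:
    doc_id: str
    span: Span
    code: str
    message: str


def validate_spans(document: Document, spans: Iterable[Span]) -> list[SpanViolation]:
    """Check the span invariants against a document; violations are data.

    Codes: WRONG_DOC, EMPTY, OUT_OF_BOUNDS, SURFACE_MISMATCH, BAD_CONFIDENCE,
    DUPLICATE.
    """
    violations: list[SpanViolation] = []
    seen: set[tuple[int, int, EntityLabel]] = set()
    for span in spans:
        if span.doc_id != document.doc_id:
            violations.append(
                SpanViolation(document.doc_id, span, "WRONG_DOC",
                              f"span belongs to doc {span.doc_id!r}")
            )
            continue
        if span.start >= span.end:
            violations.append(
                SpanViolation(document.doc_id, span, "EMPTY", "empty span (start >= end)")
            )
            continue
        if span.start < 0 or span.end > len(document.text):
            violations.append(
                SpanViolation(document.doc_id, span, "OUT_OF_BOUNDS",
                              f"offsets outside text of length {len(document.text)}")
            )
            continue
        actual = document.text[span.start:span.end]
        if span.surface != actual:
            violations.append(
                SpanViolation(document.doc_id, span, "SURFACE_MISMATCH",
                              f"surface {span.surface!r} != text slice {actual!r}")
            )
        if span.confidence is not None and not (0.0 <= span.confidence <= 1.0):
            violations.append(
                SpanViolation(document.doc_id, span, "BAD_CONFIDENCE",
                              f"confidence {span.confidence} outside [0, 1]")
            )
        if span.triple in seen:
            violations.append(
                SpanViolation(document.doc_id, span, "DUPLICATE",
                              f"duplicate span {span.triple}")
            )
        seen.add(span.triple)
    return violations


#: Closed set of guideline lint rules.
GUIDELINE_RULES = {
    "COMPOUND_SPLIT": (
        "compound word split into adjacent anatomy+symptom spans; the guideline "
        "requires one span for the whole compound"
    ),
    "SLASH_LIST_MERGED": (
        "slash-separated anatomy list annotated as a single span; the guideline "
        "requires separate spans per anatomy"
    ),
}


@dataclass(frozen=True)
class GuidelineFinding:
    doc_id: str
    rule_id: str
    spans: tuple[Span, ...]
    message: str


def lint_guidelines(document: Document, spans: Iterable[Span]) -> list[GuidelineFinding]:
    """Lint annotations against the harmonised guideline rules.

    COMPOUND_SPLIT fires when an anatomy span and a symptom span are directly
    adjacent and together cover a single whitespace-free token (e.g. "Rücken"
    + "schmerzen" inside "Rückenschmerzen").  SLASH_LIST_MERGED fires when a
    single anatomy span's surface contains "/".
    """
    spans = sorted(spans, key=lambda s: (s.start, s.end))
    findings: list[GuidelineFinding] = []

    for a in spans:
        if a.label is not EntityLabel.ANATOMY:
            continue
        if "/" in a.surface:
            findings.append(
                GuidelineFinding(
                    document.doc_id, "SLASH_LIST_MERGED", (a,),
                    f"anatomy span {a.surface!r} merges a slash-separated list",
                )
            )
        for s in spans:
            if s.label is not EntityLabel.SYMPTOM:
                continue
            lo, hi = (a, s) if a.end == s.start else (s, a) if s.end == a.start else (None, None)
            if lo is None:
                continue
            joined = document.text[lo.start:hi.end]
            if joined and not any(ch.isspace() for ch in joined):
                findings.append(
                    GuidelineFinding(
                        document.doc_id, "COMPOUND_SPLIT", (lo, hi),
                        f"compound token {joined!r} split into "
                        f"{lo.label.value}+{hi.label.value} spans",
                    )
                )
    return findings


def lint_corpus(corpus: Corpus, annotations: AnnotationSet) -> list[GuidelineFinding]:
    """Apply :func:`lint_guidelines` to every document of a corpus."""
    findings: list[GuidelineFinding] = []
    for doc in corpus:
        findings.extend(lint_guidelines(doc, annotations.for_doc(doc.doc_id)))
    return findings
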