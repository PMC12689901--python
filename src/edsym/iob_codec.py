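"""Conversion between character-offset spans and token-level IOB tags.

The tokenizer is deliberately simple and dependency-free: maximal runs of
word characters are tokens, every other non-space character (punctuation,
including "/") is its own token.  This keeps German compounds
("Kopfschmerzen") as single tokens while splitting slash lists
("Rücken/Hüfte") into three.

Encoding follows the usual IOB scheme: the first token overlapped by a span
is tagged ``B-<label>``, subsequent overlapped tokens ``I-<label>``, all
other tokens ``O``.  A span that cuts through a token claims the whole token
(span widening); decoding therefore returns the minimal token-aligned
superset of a non-aligned span, and is an exact inverse for token-aligned
spans.
"""

from __future__ import annotations

import re
from collections.abc import Iterable, Sequence
from dataclasses import dataclass, field

from .corpus_io import Document, EntityLabel, Span

_TOKEN_RE = re.compile(r"\w+|[^\w\s]", re.UNICODE)

O_TAG = "O"


class AmbiguousEncodingError(ValueError):
    """Two same-label spans overlap the same token: no IOB tagging exists."""


@dataclass(frozen=True)
class Token:
    surface: str
    start: int
    end: int


def tokenize(text: str) -> list[Token]:
    """Split text into word tokens and single-character punctuation tokens."""
    return [Token(m.group(), m.start(), m.end()) for m in _TOKEN_RE.finditer(text)]


@dataclass
class IOBSequence:
    """A tokenised document with one IOB tag per token."""

    doc_id: str
    tokens: list[Token]
    tags: list[str]
    text: str | None = None
    #: cross-label token conflicts resolved during encoding, human-readable
    warnings: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if len(self.tokens) != len(self.tags):
            raise ValueError("one tag per token required")

    def is_well_formed(self) -> bool:
        """True iff no I- tag follows O or a tag of a different label."""
        prev = O_TAG
        for tag in self.tags:
            if tag.startswith("I-") and (
                prev == O_TAG or prev[2:] != tag[2:]
            ):
                return False
            prev = tag
        return True


def spans_to_iob(
    doc: Document | str,
    spans: Iterable[Span],
    doc_id: str | None = None,
) -> IOBSequence:
    """Encode spans over a document as an IOB tag sequence.

    A token receives the B-/I- tag of a span iff it overlaps that span; the
    first overlapping token gets B-.  Two same-label spans overlapping one
    token make the encoding ambiguous and raise; for cross-label conflicts
    the earlier-starting (then longer) span claims the token and a warning is
    recorded.
    """
    if isinstance(doc, Document):
        text, doc_id = doc.text, doc.doc_id
    else:
        text = doc
        doc_id = doc_id or ""
    tokens = tokenize(text)
    tags = [O_TAG] * len(tokens)
    owner: list[Span | None] = [None] * len(tokens)
    warnings: list[str] = []

    for span in sorted(spans, key=lambda s: (s.start, -(s.end - s.start))):
        first = True
        for i, tok in enumerate(tokens):
            if tok.start < span.end and span.start < tok.end:
                prev = owner[i]
                if prev is not None:
                    if prev.label is span.label:
                        raise AmbiguousEncodingError(
                            f"doc {doc_id!r}: same-label spans {prev.triple} and "
                            f"{span.triple} overlap token {tok.surface!r}"
                        )
                    warnings.append(
                        f"token {tok.surface!r} at {tok.start} claimed by "
                        f"{prev.label.value}; {span.label.value} span "
                        f"({span.start},{span.end}) truncated"
                    )
                    first = False  # span continues past the conflict
                    continue
                owner[i] = span
                tags[i] = ("B-" if first else "I-") + span.label.value
                first = False
    return IOBSequence(doc_id, tokens, tags, text=text, warnings=warnings)


def repair_tags(tags: Sequence[str]) -> tuple[list[str], list[str]]:
    """Repair an ill-formed tag sequence; returns (tags, repair messages).

    The single repair is the standard tolerant one: an orphan I- (following
    O, nothing, or a different label) is rewritten to B-.
    """
    repaired: list[str] = []
    messages: list[str] = []
    prev = O_TAG
    for i, tag in enumerate(tags):
        if tag.startswith("I-") and (prev == O_TAG or prev[2:] != tag[2:]):
            messages.append(f"position {i}: orphan {tag} treated as B-{tag[2:]}")
            tag = "B-" + tag[2:]
        repaired.append(tag)
        prev = tag
    return repaired, messages


def iob_to_spans(seq: IOBSequence) -> tuple[list[Span], list[str]]:
    """Decode an IOB sequence back to spans; returns (spans, repair messages).

    Each maximal B-/I- run of one label becomes a span from the first token's
    start to the last token's end.  Ill-formed input is repaired first
    (orphan I- becomes B-) and the repairs are reported.
    """
    tags, repairs = repair_tags(seq.tags)
    spans: list[Span] = []
    run_start: int | None = None
    run_end = 0
    run_label: EntityLabel | None = None

    def flush() -> None:
        nonlocal run_start, run_label
        if run_start is not None and run_label is not None:
            surface = (
                seq.text[run_start:run_end]
                if seq.text is not None
                else " ".join(
                    t.surface for t in seq.tokens if run_start <= t.start < run_end
                )
            )
            spans.append(Span(seq.doc_id, run_start, run_end, run_label, surface))
        run_start, run_label = None, None

    for tok, tag in zip(seq.tokens, tags):
        if tag == O_TAG:
            flush()
            continue
        label = EntityLabel(tag[2:])
        if tag.startswith("B-"):
            flush()
            run_start, run_label = tok.start, label
        run_end = tok.end
    flush()
    return spans, repairs


def to_conll(sequences: Iterable[IOBSequence]) -> str:
    """CoNLL-style export: ``surface<TAB>tag`` lines, blank line between docs."""
    blocks = []
    for seq in sequences:
        blocks.append(
            "\n".join(f"{tok.surface}\t{tag}" for tok, tag in zip(seq.tokens, seq.tags))
        )
    return "\n\n".join(blocks) + ("\n" if blocks else "")


def from_conll(text: str) -> list[IOBSequence]:
    """Read CoNLL-style two-column text back into tag sequences.

    Character offsets are reconstructed by joining tokens with single spaces;
    they are consistent within the sequence but need not match the original
    document (the format does not store offsets).
    """
    sequences: list[IOBSequence] = []
    for i, block in enumerate(text.strip("\n").split("\n\n")):
        if not block.strip():
            continue
        tokens: list[Token] = []
        tags: list[str] = []
        pos = 0
        for line in block.splitlines():
            surface, _, tag = line.partition("\t")
            tokens.append(Token(surface, pos, pos + len(surface)))
            tags.append(tag or O_TAG)
            pos += len(surface) + 1
        sequences.append(IOBSequence(str(i + 1), tokens, tags))
    return sequences
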