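"""NER backend contract and the shipped reference implementations.

Any object with a ``name``, capability flags and a
``predict(document) -> list[Span]`` method is a backend.  Two
implementations ship:

* :class:`LexiconBackend` — deterministic longest-match lexicon scanner.
  It needs no model weights and, run on a corpus generated from the same
  lexicon, recovers the gold annotation exactly — the end-to-end smoke test
  of the whole harness.
* :class:`PromptBackend` — the zero-shot generative route: a three-part
  prompt (entity definitions, worked examples, a fixed instruction asking
  for reasoning plus a Python-list answer) is sent to a user-supplied
  completion callable (e.g. a thin client for a locally hosted LLM); the
  bracketed list in the response is parsed and each entity string is
  grounded back to character offsets by case-insensitive search.

A third adapter, :class:`TokenClassifierBackend`, wraps any token-tagging
callable (such as a fine-tuned transformer token classifier) behind the same
contract via the IOB codec; no weights or training code ship with the
package.
"""

from __future__ import annotations

import ast
import re
from collections.abc import Callable, Iterable, Mapping, Sequence
from dataclasses import dataclass, field
from typing import Protocol, runtime_checkable

from .corpus_io import Document, EntityLabel, Span
from .iob_codec import IOBSequence, iob_to_spans, tokenize


@runtime_checkable
class NERBackend(Protocol):
    """The uniform backend contract."""

    name: str
    emits_confidence: bool
    emits_offsets: bool

    def predict(self, document: Document) -> list[Span]: ...


def _is_word_char(ch: str) -> bool:
    return ch.isalnum() or ch == "_"


class LexiconBackend:
    """Longest-match, case-insensitive lexicon scanner.

    The lexicon maps each entity label to a list of surface forms (possibly
    multi-word).  Matches must align with word boundaries, so "Schmerzen"
    never fires inside "Kopfschmerzen"; at each position the longest entry
    wins, and emitted spans never overlap.  Confidence is 1.0 for an exact
    case match and 0.8 for a case-insensitive one.
    """

    emits_confidence = True
    emits_offsets = True

    def __init__(self, lexicon: Mapping[EntityLabel, Iterable[str]], name: str = "lexicon"):
        self.name = name
        self._entries: list[tuple[str, EntityLabel]] = []
        for label, surfaces in lexicon.items():
            for surface in surfaces:
                if surface:
                    self._entries.append((surface, EntityLabel(label)))
        # longest first so the first hit at a position is the longest match
        self._entries.sort(key=lambda e: (-len(e[0]), e[0]))

    @classmethod
    def from_tsv(cls, text: str, name: str = "lexicon") -> "LexiconBackend":
        """TSV dialect: ``label<TAB>surface`` per line."""
        lexicon: dict[EntityLabel, list[str]] = {}
        for line in text.splitlines():
            if not line.strip() or line.startswith("#"):
                continue
            label, _, surface = line.partition("\t")
            lexicon.setdefault(EntityLabel(label.strip()), []).append(surface.strip())
        return cls(lexicon, name=name)

    def predict(self, document: Document) -> list[Span]:
        text = document.text
        lowered = text.lower()
        spans: list[Span] = []
        i = 0
        n = len(text)
        while i < n:
            if not _is_word_char(text[i]):
                i += 1
                continue
            if i > 0 and _is_word_char(text[i - 1]):
                i += 1
                continue
            hit = None
            for surface, label in self._entries:
                end = i + len(surface)
                if end > n or lowered[i:end] != surface.lower():
                    continue
                if end < n and _is_word_char(text[end]) and _is_word_char(surface[-1]):
                    continue
                hit = (surface, label, end)
                break
            if hit is None:
                i += 1
                continue
            surface, label, end = hit
            actual = text[i:end]
            spans.append(
                Span(document.doc_id, i, end, label, actual,
                     confidence=1.0 if actual == surface else 0.8)
            )
            i = end
        return spans


@dataclass(frozen=True)
class PromptSchema:
    """The three-part zero-shot prompt schema.

    Part 1 defines the entities to recognise (symptoms, anatomic position,
    negation); part 2 gives a few worked narrative→entity-list examples;
    part 3 is the fixed instruction asking the model to reason about
    candidate entities and return them in a Python list without comments.
    """

    part1_definitions: str
    part2_examples: tuple[tuple[str, tuple[str, ...]], ...]
    part3_instruction: str

    def __post_init__(self) -> None:
        if not self.part1_definitions.strip():
            raise ValueError("part 1 (entity definitions) must be non-empty")
        if not self.part2_examples:
            raise ValueError("part 2 (worked examples) must be non-empty")
        if not self.part3_instruction.strip():
            raise ValueError("part 3 (instruction) must be non-empty")


#: The fixed part-3 instruction, German original with English alternative.
INSTRUCTION_DE = (
    "Ermittele anhand des obigen Absatzes eine Liste möglicher Entities und "
    "erkläre, warum es sich entweder um ein Entity handelt oder nicht. Gebe "
    "alle gefundenen Entities auch in einer Python Liste wie folgt zurück, "
    "füge keine Kommentare hinzu:"
)
INSTRUCTION_EN = (
    "Use the paragraph above to determine a list of possible entities and "
    "explain why it is either an entity or not. Return all found entities "
    "also in a Python list like this, don't add comments:"
)

_DEFAULT_DEFINITIONS = (
    "Erkenne in klinischen Anamnesetexten die folgenden Entities:\n"
    "- SYMPTOM: vom Patienten berichtete Beschwerden (z.B. Fieber, Husten, "
    "Dyspnoe, Kopfschmerzen).\n"
    "- ANATOMIE: anatomische Positionen, die ein Symptom lokalisieren "
    "(z.B. Kopf, Rücken, Thorax).\n"
    "- NEGATION: Verneinungen, die ein Symptom ausschließen "
    "(z.B. kein, keine, nicht)."
)

_DEFAULT_EXAMPLES: tuple[tuple[str, tuple[str, ...]], ...] = (
    (
        "Seit Tagen deutliche Schwellung des rechten Unterschenkels mit "
        "Rötung und Überwärmung. Keine Dyspnoe, keine Thoraxschmerzen.",
        (
            "Schwellung:SYMPTOM", "Rötung:SYMPTOM", "Überwärmung:SYMPTOM",
            "Keine:NEGATION", "Dyspnoe:SYMPTOM",
            "keine:NEGATION", "Thoraxschmerzen:SYMPTOM",
        ),
    ),
    (
        "Patient klagt über Schmerzen im Rücken, kein Fieber.",
        (
            "Schmerzen:SYMPTOM", "Rücken:ANATOMIE",
            "kein:NEGATION", "Fieber:SYMPTOM",
        ),
    ),
)


def default_schema(language: str = "de") -> PromptSchema:
    """The shipped default three-part schema (German instruction verbatim)."""
    instruction = INSTRUCTION_DE if language == "de" else INSTRUCTION_EN
    return PromptSchema(_DEFAULT_DEFINITIONS, _DEFAULT_EXAMPLES, instruction)


def build_prompt(schema: PromptSchema, narrative: str) -> str:
    """Deterministic concatenation of the three parts around the narrative."""
    if not narrative.strip():
        raise ValueError("empty narrative")
    example_blocks = [
        f"Beispiel:\n{text}\nEntities: {list(entities)!r}"
        for text, entities in schema.part2_examples
    ]
    return "\n\n".join(
        [
            schema.part1_definitions,
            "\n\n".join(example_blocks),
            f"Text:\n{narrative}",
            schema.part3_instruction,
        ]
    )


_QUOTED_RE = re.compile(r"""["']([^"']+)["']""")

_LABEL_ALIASES = {
    "SYMPTOM": EntityLabel.SYMPTOM,
    "ANATOMY": EntityLabel.ANATOMY,
    "ANATOMIE": EntityLabel.ANATOMY,
    "NEGATION": EntityLabel.NEGATION,
}


@dataclass
class ParsedEntityList:
    entities: list[tuple[str, EntityLabel | None]] = field(default_factory=list)
    parse_failed: bool = False


def _bracketed_chunks(response: str) -> list[str]:
    """All balanced top-level ``[...]`` chunks, left to right."""
    chunks = []
    depth = 0
    start = -1
    for i, ch in enumerate(response):
        if ch == "[":
            if depth == 0:
                start = i
            depth += 1
        elif ch == "]" and depth > 0:
            depth -= 1
            if depth == 0:
                chunks.append(response[start : i + 1])
    return chunks


def parse_entity_list(response: str) -> ParsedEntityList:
    """Extract the entity list from a free-text model response.

    The *last* bracketed list literal wins (models often restate examples
    first); elements are quoted strings, optionally ``surface:label`` pairs.
    Free-text reasoning before the list is discarded.  A response with no
    parseable list yields an empty result with ``parse_failed`` set — parse
    failures are data, not exceptions.
    """
    result = ParsedEntityList()
    chunks = _bracketed_chunks(response)
    if not chunks:
        result.parse_failed = True
        return result
    chunk = chunks[-1]
    try:
        items = ast.literal_eval(chunk)
        if not isinstance(items, (list, tuple)):
            raise ValueError
        strings = [str(x) for x in items]
    except (ValueError, SyntaxError):
        strings = _QUOTED_RE.findall(chunk)
        if not strings:
            result.parse_failed = True
            return result
    for item in strings:
        surface, sep, label_str = item.rpartition(":")
        if sep and label_str.strip().upper() in _LABEL_ALIASES:
            result.entities.append(
                (surface.strip(), _LABEL_ALIASES[label_str.strip().upper()])
            )
        else:
            result.entities.append((item.strip(), None))
    return result


@dataclass
class GroundingReport:
    spans: list[Span] = field(default_factory=list)
    ungrounded: list[str] = field(default_factory=list)
    parse_failed: bool = False


def ground_entities(
    entities: Sequence[tuple[str, EntityLabel | None]] | Sequence[str],
    document: Document,
    default_label: EntityLabel = EntityLabel.SYMPTOM,
) -> GroundingReport:
    """Locate entity strings in the document text by case-insensitive search.

    Every non-overlapping occurrence becomes a span; strings absent from the
    text are reported as ungrounded (excluded from the span list — whether
    the evaluation then counts them as spurious is the caller's policy).
    """
    report = GroundingReport()
    text_lower = document.text.lower()
    taken: list[tuple[int, int]] = []
    for entry in entities:
        if isinstance(entry, str):
            surface, label = entry, None
        else:
            surface, label = entry
        if not surface:
            continue
        needle = surface.lower()
        found = False
        pos = 0
        while True:
            i = text_lower.find(needle, pos)
            if i < 0:
                break
            j = i + len(needle)
            if not any(i < e and s < j for s, e in taken):
                taken.append((i, j))
                report.spans.append(
                    Span(document.doc_id, i, j, label or default_label,
                         document.text[i:j])
                )
                found = True
            pos = j
        if not found:
            report.ungrounded.append(surface)
    report.spans.sort(key=lambda s: (s.start, s.end))
    return report


class PromptBackend:
    """Zero-shot backend: prompt → completion → list parsing → grounding.

    ``completion`` is any ``prompt text -> response text`` callable, e.g. a
    client for a locally hosted instruction-tuned model (the pipeline's
    privacy posture assumes on-premises inference).  Grounding reports are
    kept per document in :attr:`last_report`.
    """

    emits_confidence = False
    emits_offsets = True

    def __init__(
        self,
        completion: Callable[[str], str],
        schema: PromptSchema | None = None,
        name: str = "prompt",
        default_label: EntityLabel = EntityLabel.SYMPTOM,
    ):
        self.name = name
        self.completion = completion
        self.schema = schema or default_schema()
        self.default_label = default_label
        self.last_report: GroundingReport | None = None

    def predict(self, document: Document) -> list[Span]:
        response = self.completion(build_prompt(self.schema, document.text))
        parsed = parse_entity_list(response)
        report = ground_entities(parsed.entities, document, self.default_label)
        report.parse_failed = parsed.parse_failed
        self.last_report = report
        return report.spans


class TokenClassifierBackend:
    """Adapter for token-tagging models (e.g. a fine-tuned transformer).

    ``tagger`` maps a list of token surfaces to one IOB tag per token; the
    adapter handles tokenization and tag→span decoding.  Supply your own
    model; none ships with the package.
    """

    emits_confidence = False
    emits_offsets = True

    def __init__(self, tagger: Callable[[list[str]], list[str]], name: str = "token_classifier"):
        self.name = name
        self.tagger = tagger

    def predict(self, document: Document) -> list[Span]:
        tokens = tokenize(document.text)
        tags = self.tagger([t.surface for t in tokens])
        if len(tags) != len(tokens):
            raise ValueError(
                f"tagger returned {len(tags)} tags for {len(tokens)} tokens"
            )
        seq = IOBSequence(document.doc_id, tokens, list(tags), text=document.text)
        spans, _ = iob_to_spans(seq)
        return spans


#: name → constructor registry for config-driven backend selection
BACKENDS: dict[str, Callable[..., object]] = {
    "lexicon": LexiconBackend,
    "prompt": PromptBackend,
    "token_classifier": TokenClassifierBackend,
}


def register_backend(name: str, constructor: Callable[..., object]) -> None:
    BACKENDS[name] = constructor


def create_backend(name: str, /, **kwargs) -> object:
    try:
        constructor = BACKENDS[name]
    except KeyError:
        raise KeyError(
            f"unknown backend {name!r}; registered: {sorted(BACKENDS)}"
        ) from None
    return constructor(**kwargs)
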