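"""From raw predicted spans to standardized, affirmed symptom records.

The pipeline applies, in order:

1. **confidence filtering** — spans scoring below a threshold τ are dropped;
   unscored spans are retained and flagged;
2. **negation detection** — a symptom is negated when a negation cue
   ("kein", "keine", "no", …) precedes it within a token window inside the
   same clause; one cue distributes over coordinated symptoms ("no X, no Y"
   as well as "keine X und Y");
3. **anatomy–pain fusion** — a bare pain mention ("Schmerzen") is combined
   with the nearest anatomical reference among the adjacent extracted
   entities ("Kopf" + "Schmerzen" → "Kopfschmerzen"); existing compounds are
   left untouched;
4. **surface standardization** — punctuation stripped, whitespace collapsed,
   lower-cased with the first letter capitalized;
5. **dictionary normalization** — synonym and inflection variants are mapped
   to one canonical term ("Verstopfung" → "Obstipation", "gehustet" →
   "Husten"); unmatched terms keep their original name.

Negated symptoms are excluded from the affirmed output but remain available
for audit.  The negation-scope rule is intentionally shallow and auditable
(window + clause boundary), not a dependency parse.
"""

from __future__ import annotations

import json
import re
from collections.abc import Iterable, Mapping
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

from .corpus_io import Document, EntityLabel, Span
from .iob_codec import tokenize

#: clause/sentence boundary tokens that block negation scope
CLAUSE_BOUNDARIES = frozenset({".", ";", ":", "!", "?"})
#: coordinators skipped when counting the cue-to-symptom token gap
COORDINATORS = frozenset({",", "und", "oder", "sowie", "/", "bzw", "and"})


@dataclass(frozen=True)
class PostprocessConfig:
    """Tunables of the extraction pipeline.

    ``confidence_threshold``: minimum backend confidence τ in [0, 1].
    ``negation_window``: maximum number of tokens (coordinators and other
    symptom tokens excluded) between a preceding cue and a symptom.
    ``clause_bounded``: whether a clause boundary between cue and symptom
    cancels the negation.  ``fusion_window``: how many adjacent extracted
    entities to inspect on each side when attaching anatomy to a bare pain
    mention.  ``pain_lexemes``: lower-cased lexemes counting as bare pain.
    """

    confidence_threshold: float = 0.5
    negation_window: int = 3
    clause_bounded: bool = True
    fusion_window: int = 1
    pain_lexemes: tuple[str, ...] = ("schmerzen", "schmerz")

    def __post_init__(self) -> None:
        if not (0.0 <= self.confidence_threshold <= 1.0):
            raise ValueError("confidence_threshold must be in [0, 1]")
        if self.negation_window < 0 or self.fusion_window < 0:
            raise ValueError("windows must be >= 0")


DEFAULT_CONFIG = PostprocessConfig()


@dataclass
class ConfidenceFilterResult:
    kept: list[Span]
    unscored: list[Span]  # retained but flagged: no confidence to compare


def filter_confidence(spans: Iterable[Span], threshold: float) -> ConfidenceFilterResult:
    """Retain spans with confidence >= threshold; unscored spans are kept and flagged."""
    if not (0.0 <= threshold <= 1.0):
        raise ValueError(f"confidence threshold {threshold} outside [0, 1]")
    kept: list[Span] = []
    unscored: list[Span] = []
    for span in spans:
        if span.confidence is None:
            kept.append(span)
            unscored.append(span)
        elif span.confidence >= threshold:
            kept.append(span)
    return ConfidenceFilterResult(kept, unscored)


@dataclass(frozen=True)
class NegationMark:
    span: Span
    negated: bool
    cue: Span | None = None


def detect_negated(
    document: Document,
    spans: Iterable[Span],
    config: PostprocessConfig = DEFAULT_CONFIG,
) -> list[NegationMark]:
    """Mark each symptom span as negated or affirmed.

    A symptom is negated iff some negation-cue span ends at or before the
    symptom's start, lies in the same clause (no ``. ; : ! ?`` token
    between), and the gap between cue and symptom contains at most
    ``negation_window`` tokens once coordinators and tokens inside other
    symptom spans are discounted — this lets one cue scope over a
    coordinated list of symptoms.
    """
    spans = sorted(spans, key=lambda s: (s.start, s.end))
    symptoms = [s for s in spans if s.label is EntityLabel.SYMPTOM]
    cues = [s for s in spans if s.label is EntityLabel.NEGATION]
    tokens = tokenize(document.text)

    def in_symptom(tok_start: int, tok_end: int) -> bool:
        return any(s.start <= tok_start and tok_end <= s.end for s in symptoms)

    marks: list[NegationMark] = []
    for sym in symptoms:
        found: Span | None = None
        for cue in cues:
            if cue.end > sym.start:
                continue
            gap_tokens = [
                t for t in tokens if cue.end <= t.start and t.end <= sym.start
            ]
            if config.clause_bounded and any(
                t.surface in CLAUSE_BOUNDARIES for t in gap_tokens
            ):
                continue
            gap = sum(
                1
                for t in gap_tokens
                if t.surface.lower() not in COORDINATORS
                and not in_symptom(t.start, t.end)
            )
            if gap <= config.negation_window:
                found = cue
                break
        marks.append(NegationMark(sym, negated=found is not None, cue=found))
    return marks


@dataclass(frozen=True)
class Mention:
    """A symptom span with its effective (possibly fused) surface."""

    span: Span
    surface: str
    fused_anatomy: Span | None = None
    #: bare pain mention with no anatomy found in the fusion window
    generic_pain: bool = False


def _clause_index(document: Document, offset: int) -> int:
    """Index of the clause (sentence) an offset falls in."""
    idx = 0
    for tok in tokenize(document.text):
        if tok.end > offset:
            break
        if tok.surface in CLAUSE_BOUNDARIES:
            idx += 1
    return idx


def is_compound_pain(surface: str, config: PostprocessConfig = DEFAULT_CONFIG) -> bool:
    """True for surfaces like "Kopfschmerzen": a pain lexeme with a prefix."""
    lowered = surface.strip().lower()
    return any(
        lowered.endswith(lex) and len(lowered) > len(lex) for lex in config.pain_lexemes
    )


def fuse_pain_anatomy(
    document: Document,
    spans: Iterable[Span],
    config: PostprocessConfig = DEFAULT_CONFIG,
) -> list[Mention]:
    """Attach anatomy to bare pain mentions; returns one Mention per symptom.

    A symptom whose cleaned surface *is* a pain lexeme (not a compound) is
    fused with the nearest anatomy span within ``fusion_window`` extracted
    entities before or after it, in the same clause; preceding anatomy wins
    ties.  The fused surface is ``anatomy + pain-lexeme.lower()``, matching
    how German writes the closed compound.  Bare pain with no anatomy in
    reach is kept unchanged and flagged generic.
    """
    entities = sorted(spans, key=lambda s: (s.start, s.end))
    mentions: list[Mention] = []
    for idx, span in enumerate(entities):
        if span.label is not EntityLabel.SYMPTOM:
            continue
        bare = span.surface.strip().strip(".,:;!?").lower() in config.pain_lexemes
        if not bare:
            mentions.append(Mention(span, span.surface))
            continue
        clause = _clause_index(document, span.start)
        best: tuple[int, int, Span] | None = None  # (distance, order, anatomy)
        for offset in range(1, config.fusion_window + 1):
            for order, j in ((0, idx - offset), (1, idx + offset)):
                if not (0 <= j < len(entities)):
                    continue
                cand = entities[j]
                if cand.label is not EntityLabel.ANATOMY:
                    continue
                if _clause_index(document, cand.start) != clause:
                    continue
                key = (offset, order, cand)
                if best is None or key[:2] < best[:2]:
                    best = key
        if best is None:
            mentions.append(Mention(span, span.surface, generic_pain=True))
        else:
            anatomy = best[2]
            fused = anatomy.surface.strip().strip("./,:;") + span.surface.strip().lower()
            mentions.append(Mention(span, fused, fused_anatomy=anatomy))
    return mentions


_PUNCT_RE = re.compile(r"[.:,;!?]+")
_WS_RE = re.compile(r"\s+")


def standardize_surface(term: str) -> str:
    """Clean a symptom surface: strip punctuation, collapse whitespace,
    lowercase, capitalize the first letter.  Raises if nothing remains."""
    if not term:
        raise ValueError("empty term")
    cleaned = _WS_RE.sub(" ", _PUNCT_RE.sub("", term)).strip()
    if not cleaned:
        raise ValueError(f"term {term!r} empty after cleaning")
    cleaned = cleaned.lower()
    first = cleaned[0].upper()
    if len(first) > 1:  # e.g. "ß" -> "SS" would break idempotence
        first = cleaned[0]
    return first + cleaned[1:]


class DictionaryError(ValueError):
    """The normalization dictionary violates its invariants."""


class NormalizationDictionary:
    """Canonical symptom terms with enumerated synonym/inflection variants.

    Matching is case-insensitive.  Each canonical is implicitly a variant of
    its own entry; a variant mapping to two different canonicals is a load
    error.  No stemming: inflections are enumerated, keeping the mapping
    auditable.
    """

    def __init__(self, entries: Mapping[str, Iterable[str]]):
        self.entries: dict[str, tuple[str, ...]] = {}
        self._variant_to_canonical: dict[str, str] = {}
        for canonical, variants in entries.items():
            if not canonical:
                raise DictionaryError("empty canonical term")
            all_variants = tuple(dict.fromkeys([canonical, *variants]))
            self.entries[canonical] = all_variants
            for variant in all_variants:
                key = variant.lower()
                owner = self._variant_to_canonical.get(key)
                if owner is not None and owner != canonical:
                    raise DictionaryError(
                        f"variant {variant!r} maps to both {owner!r} and {canonical!r}"
                    )
                self._variant_to_canonical[key] = canonical

    def normalize(self, term: str) -> str:
        """Canonical for a matching variant; unmatched terms are unchanged."""
        return self._variant_to_canonical.get(term.lower(), term)

    def __len__(self) -> int:
        return len(self.entries)

    @classmethod
    def from_json(cls, source: str | Path) -> "NormalizationDictionary":
        if isinstance(source, Path):
            data = json.loads(source.read_text(encoding="utf-8"))
        else:
            data = json.loads(source)
        return cls(data)

    @classmethod
    def from_tsv(cls, source: str | Path) -> "NormalizationDictionary":
        """TSV dialect: ``canonical<TAB>variant1<TAB>variant2...`` per line."""
        text = source.read_text(encoding="utf-8") if isinstance(source, Path) else source
        entries: dict[str, list[str]] = {}
        for line in text.splitlines():
            if not line.strip() or line.startswith("#"):
                continue
            canonical, *variants = line.rstrip("\n").split("\t")
            entries.setdefault(canonical, []).extend(v for v in variants if v)
        return cls(entries)


def default_dictionary() -> NormalizationDictionary:
    """The shipped German symptom dictionary (synonyms + attested inflections)."""
    data = resources.files("edsym.data").joinpath("symptom_dictionary.json")
    return NormalizationDictionary.from_json(data.read_text(encoding="utf-8"))


def normalize_symptom(term: str, dictionary: NormalizationDictionary) -> str:
    """Map a surface-standardized term to its canonical dictionary form."""
    return dictionary.normalize(term)


@dataclass(frozen=True)
class SymptomRecord:
    """One structured output row: a standardized symptom in one document."""

    doc_id: str
    standardized_term: str
    raw_surface: str
    negated: bool
    start: int
    end: int
    confidence: float | None = None

    def to_dict(self) -> dict:
        return {
            "doc_id": self.doc_id,
            "standardized_term": self.standardized_term,
            "raw_surface": self.raw_surface,
            "negated": self.negated,
            "start": self.start,
            "end": self.end,
            "confidence": self.confidence,
        }


@dataclass
class ExtractionResult:
    affirmed: list[SymptomRecord] = field(default_factory=list)
    negated: list[SymptomRecord] = field(default_factory=list)
    unscored_spans: list[Span] = field(default_factory=list)


def extract_affirmed(
    document: Document,
    spans: Iterable[Span],
    config: PostprocessConfig = DEFAULT_CONFIG,
    dictionary: NormalizationDictionary | None = None,
) -> ExtractionResult:
    """Run the full pipeline on one document's predicted spans.

    Stage order: confidence filter → negation detection → anatomy–pain
    fusion → surface standardization → dictionary normalization.  Every
    symptom span surviving the confidence filter yields exactly one record,
    in the affirmed or the negated list.
    """
    if dictionary is None:
        dictionary = default_dictionary()
    filtered = filter_confidence(spans, config.confidence_threshold)
    marks = detect_negated(document, filtered.kept, config)
    negated_spans = {m.span for m in marks if m.negated}
    mentions = fuse_pain_anatomy(document, filtered.kept, config)

    result = ExtractionResult(unscored_spans=filtered.unscored)
    for mention in mentions:
        term = normalize_symptom(standardize_surface(mention.surface), dictionary)
        record = SymptomRecord(
            doc_id=document.doc_id,
            standardized_term=term,
            raw_surface=mention.span.surface,
            negated=mention.span in negated_spans,
            start=mention.span.start,
            end=mention.span.end,
            confidence=mention.span.confidence,
        )
        (result.negated if record.negated else result.affirmed).append(record)
    return result
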