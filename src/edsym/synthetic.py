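"""Synthetic German-style anamnesis corpora with known gold annotations.

The generator emulates the phenomena that make short emergency-department
narratives hard for span NER — affirmed and negated symptom mentions,
closed compounds fusing anatomy and pain ("Kopfschmerzen"), analytic pain
phrases ("Schmerzen in Rücken"), and slash-separated anatomy lists
("Rücken/Hüfte") — using a small embedded lexicon.  It makes no claim of
clinical realism; its purpose is exact, seed-deterministic gold spans.

``corrupt_annotations`` degrades a gold annotation into synthetic
"predictions" under independent per-span error rates (miss, boundary shift,
type flip) plus a Poisson rate of spurious spans, and
``expected_metrics`` gives the closed-form precision/recall/F1 the evaluator
must converge to.  Error branches chain conditionally: a span is dropped
with probability ``p_miss``; *otherwise* boundary-shifted with probability
``p_shift``; *otherwise* type-flipped with probability ``p_type``; otherwise
copied exactly.  Shifted spans keep their label and always still overlap
their gold span; spurious spans never overlap gold spans.  Both constraints
keep the closed forms exact (see docs/methods.md for the derivation).

Closed forms (m = p_miss, s = p_shift, t = p_type, c = partial credit)::

    R_strict  = (1-m)(1-s)(1-t)        boundary and type must survive
    R_exact   = (1-m)(1-s)             type flips keep exact boundaries
    R_partial = (1-m)((1-s) + c*s)     shifted spans earn partial credit
    R_type    = (1-m)((1-s)(1-t) + s)  shifts keep the label and overlap

    P_g = R_g * G / ((1-m)*G + S)      with G gold spans, S expected spurious
"""

from __future__ import annotations

import math
import random
from dataclasses import dataclass, field, replace

from .corpus_io import AnnotationSet, Corpus, Document, EntityLabel, Span
from .iob_codec import tokenize
from .span_eval import GRANULARITIES, Granularity

_SYMPTOMS = (
    "Fieber", "Husten", "Dyspnoe", "Übelkeit", "Erbrechen", "Schwindel",
    "Durchfall", "Schwellung", "Rötung", "Überwärmung", "Luftnot",
)
_ANATOMIES = ("Kopf", "Rücken", "Thorax", "Bauch", "Hüfte", "Knie", "Schulter")
#: grammatical compound per anatomy (linking forms differ, so enumerated)
_COMPOUNDS = {
    "Kopf": "Kopfschmerzen",
    "Rücken": "Rückenschmerzen",
    "Thorax": "Thoraxschmerzen",
    "Bauch": "Bauchschmerzen",
    "Hüfte": "Hüftschmerzen",
    "Knie": "Knieschmerzen",
    "Schulter": "Schulterschmerzen",
}
_CUES = ("Keine", "Kein")
_PREFIXES = (
    "Seit gestern", "Seit Tagen", "Zunehmend", "Aktuell", "Seit heute Morgen",
)
_PAIN = "Schmerzen"


@dataclass(frozen=True)
class GeneratorConfig:
    """Study conditions of the synthetic corpus.

    Defaults mirror a small annotated ED corpus: 150 documents of 1–5
    clauses.  ``p_negation`` is the probability a symptom clause is negated,
    ``p_pain`` the probability a clause is a pain clause, ``p_compound`` the
    probability a pain mention is written as a closed compound, and
    ``p_slash_list`` the probability an analytic pain clause lists two
    anatomies separated by a slash.  ``guideline_conformant=False`` emits
    the two annotation-guideline violations (split compounds, merged slash
    lists) on purpose, for lint testing.
    """

    n_documents: int = 150
    seed: int = 0
    min_clauses: int = 1
    max_clauses: int = 5
    p_negation: float = 0.3
    p_pain: float = 0.4
    p_compound: float = 0.5
    p_slash_list: float = 0.1
    guideline_conformant: bool = True
    symptoms: tuple[str, ...] = _SYMPTOMS
    anatomies: tuple[str, ...] = _ANATOMIES
    negation_cues: tuple[str, ...] = _CUES
    pain_lexeme: str = _PAIN

    def __post_init__(self) -> None:
        for name in ("p_negation", "p_pain", "p_compound", "p_slash_list"):
            if not (0.0 <= getattr(self, name) <= 1.0):
                raise ValueError(f"{name} must be in [0, 1]")
        if self.n_documents < 1 or self.min_clauses < 1:
            raise ValueError("need at least one document and one clause")
        if not (self.symptoms and self.anatomies and self.negation_cues):
            raise ValueError("lexicons must be non-empty")

    def backend_lexicon(self) -> dict[EntityLabel, list[str]]:
        """A lexicon covering every surface the generator can emit, for the
        end-to-end smoke test with the lexicon backend."""
        return {
            EntityLabel.SYMPTOM: sorted(
                {*self.symptoms, self.pain_lexeme, *_COMPOUNDS.values()}
            ),
            EntityLabel.ANATOMY: sorted(self.anatomies),
            EntityLabel.NEGATION: sorted(self.negation_cues),
        }


# A clause part: (piece, label, glued) — glued parts attach to the previous
# piece without a space (compound halves, slash-list segments).
_Part = tuple[str, EntityLabel | None, bool]


def _part(piece: str, label: EntityLabel | None = None, glued: bool = False) -> _Part:
    return (piece, label, glued)


def _emit(parts: list[_Part], offset: int, doc_id: str):
    """Materialise clause parts into (text, spans) starting at offset."""
    text = ""
    spans: list[Span] = []
    for piece, label, glued in parts:
        if text and not glued:
            text += " "
        start = offset + len(text)
        text += piece
        if label is not None:
            spans.append(Span(doc_id, start, start + len(piece), label, piece))
    return text, spans


def _pain_clause(rng: random.Random, cfg: GeneratorConfig, negated: bool) -> list[_Part]:
    parts: list[_Part] = []
    if negated:
        parts.append(_part(rng.choice(cfg.negation_cues), EntityLabel.NEGATION))
    if rng.random() < cfg.p_compound:
        anatomy = rng.choice(sorted(_COMPOUNDS))
        compound = _COMPOUNDS[anatomy]
        if cfg.guideline_conformant:
            parts.append(_part(compound, EntityLabel.SYMPTOM))
        else:
            # deliberate COMPOUND_SPLIT: anatomy prefix + glued pain suffix
            split = len(compound) - len("schmerzen")
            parts.append(_part(compound[:split], EntityLabel.ANATOMY))
            parts.append(_part(compound[split:], EntityLabel.SYMPTOM, glued=True))
        if not negated:
            parts.append(_part("seit Tagen"))
    else:
        if not negated and rng.random() < 0.5:
            parts.append(_part(rng.choice(_PREFIXES)))
        parts.append(_part(cfg.pain_lexeme, EntityLabel.SYMPTOM))
        parts.append(_part("in"))
        if rng.random() < cfg.p_slash_list:
            a1, a2 = rng.sample(cfg.anatomies, 2)
            if cfg.guideline_conformant:
                parts.append(_part(a1, EntityLabel.ANATOMY))
                parts.append(_part("/", glued=True))
                parts.append(_part(a2, EntityLabel.ANATOMY, glued=True))
            else:
                # deliberate SLASH_LIST_MERGED: one span across the slash
                parts.append(_part(f"{a1}/{a2}", EntityLabel.ANATOMY))
        else:
            parts.append(_part(rng.choice(cfg.anatomies), EntityLabel.ANATOMY))
    return parts


def _symptom_clause(rng: random.Random, cfg: GeneratorConfig, negated: bool) -> list[_Part]:
    sym = rng.choice(cfg.symptoms)
    parts: list[_Part] = []
    if negated:
        parts.append(_part(rng.choice(cfg.negation_cues), EntityLabel.NEGATION))
    else:
        parts.append(_part(rng.choice(_PREFIXES)))
    parts.append(_part(sym, EntityLabel.SYMPTOM))
    return parts


def generate_corpus(config: GeneratorConfig) -> tuple[Corpus, AnnotationSet]:
    """Generate a seed-deterministic corpus with exact gold spans.

    Each document is 1–5 clauses (each a short sentence ending in a period)
    drawn from the affirmed-symptom, negated-symptom, compound-pain,
    analytic anatomy+pain, and slash-anatomy-list templates.
    """
    rng = random.Random(config.seed)
    corpus = Corpus()
    gold = AnnotationSet("gold")
    for i in range(1, config.n_documents + 1):
        doc_id = str(i)
        n_clauses = rng.randint(config.min_clauses, config.max_clauses)
        text = ""
        spans: list[Span] = []
        for _ in range(n_clauses):
            negated = rng.random() < config.p_negation
            if rng.random() < config.p_pain:
                parts = _pain_clause(rng, config, negated)
            else:
                parts = _symptom_clause(rng, config, negated)
            offset = len(text) + 1 if text else 0
            clause_text, clause_spans = _emit(parts, offset, doc_id)
            text = f"{text} {clause_text}." if text else f"{clause_text}."
            spans.extend(clause_spans)
        metadata = {
            "sex": rng.choice(["F", "M"]),
            "age_group": rng.choice(["18-39", "40-64", "65+"]),
        }
        corpus.add(Document(doc_id, text, metadata))
        for span in spans:
            gold.add(span)
    return corpus, gold


@dataclass(frozen=True)
class CorruptionConfig:
    """Per-span error rates of the synthetic prediction model.

    ``p_miss``: drop the span.  ``p_shift``: move one boundary to the
    adjacent token edge (character mode moves it by one character).
    ``p_type``: flip the label to one of the other two.  ``p_spurious``:
    expected number of spurious spans per document (Poisson).  The branches
    chain conditionally in that order.
    """

    p_miss: float = 0.0
    p_shift: float = 0.0
    p_type: float = 0.0
    p_spurious: float = 0.0
    seed: int = 0
    token_aligned_shift: bool = True

    def __post_init__(self) -> None:
        for name in ("p_miss", "p_shift", "p_type", "p_spurious"):
            if getattr(self, name) < 0 or (name != "p_spurious" and getattr(self, name) > 1):
                raise ValueError(f"{name} out of range")
        if self.p_miss + self.p_shift + self.p_type > 1 + 1e-9:
            raise ValueError("p_miss + p_shift + p_type must be <= 1")


def _overlaps_any(start: int, end: int, spans: list[Span], skip: Span | None = None) -> bool:
    return any(s is not skip and start < s.end and s.start < end for s in spans)


def _shift_span(
    rng: random.Random, doc: Document, span: Span, gold_spans: list[Span],
    token_aligned: bool,
) -> Span:
    """Perturb one boundary so the span still overlaps the original but is no
    longer exact, without touching any other gold span."""
    candidates: list[tuple[int, int]] = []
    if token_aligned:
        tokens = tokenize(doc.text)
        before = [t for t in tokens if t.end <= span.start]
        after = [t for t in tokens if t.start >= span.end]
        inside = [t for t in tokens if t.start >= span.start and t.end <= span.end]
        if after and not _overlaps_any(span.start, after[0].end, gold_spans, skip=span):
            candidates.append((span.start, after[0].end))      # widen end
        if before and not _overlaps_any(before[-1].start, span.end, gold_spans, skip=span):
            candidates.append((before[-1].start, span.end))    # widen start
        if len(inside) >= 2:
            candidates.append((span.start, inside[-2].end))    # shrink end
            candidates.append((inside[1].start, span.end))     # shrink start
    if not candidates:
        # character fallback: shrink from the left (entity surfaces are >1 char)
        if span.end - span.start >= 2:
            candidates.append((span.start + 1, span.end))
        elif span.end < len(doc.text) and not _overlaps_any(
            span.start, span.end + 1, gold_spans, skip=span
        ):
            candidates.append((span.start, span.end + 1))
        else:
            candidates.append((span.start - 1, span.end))
    start, end = rng.choice(candidates)
    return Span(span.doc_id, start, end, span.label, doc.text[start:end])


def _poisson(rng: random.Random, lam: float) -> int:
    if lam <= 0:
        return 0
    # inverse-CDF sampling; lam is small (spurious spans per document)
    u = rng.random()
    k, p, cum = 0, math.exp(-lam), math.exp(-lam)
    while u > cum and k < 100:
        k += 1
        p *= lam / k
        cum += p
    return k


def corrupt_annotations(
    corpus: Corpus,
    gold: AnnotationSet,
    config: CorruptionConfig,
    annotator_id: str = "corrupted",
) -> AnnotationSet:
    """Degrade gold annotations into seed-deterministic synthetic predictions."""
    rng = random.Random(config.seed)
    other_labels = {
        lab: [o for o in EntityLabel if o is not lab] for lab in EntityLabel
    }
    pred = AnnotationSet(annotator_id)
    for doc in corpus:
        doc_gold = gold.for_doc(doc.doc_id)
        for span in doc_gold:
            if rng.random() < config.p_miss:
                continue
            if rng.random() < config.p_shift:
                pred.add(_shift_span(rng, doc, span, doc_gold, config.token_aligned_shift))
            elif rng.random() < config.p_type:
                flipped = rng.choice(other_labels[span.label])
                pred.add(replace(span, label=flipped))
            else:
                pred.add(span)
        n_spurious = _poisson(rng, config.p_spurious)
        if n_spurious:
            taken = list(doc_gold)
            free = [
                t for t in tokenize(doc.text)
                if len(t.surface) >= 2 and not _overlaps_any(t.start, t.end, doc_gold)
            ]
            for _ in range(n_spurious):
                rng.shuffle(free)
                placed = next(
                    (t for t in free if not _overlaps_any(t.start, t.end, taken)), None
                )
                if placed is None:
                    continue
                label = rng.choice(list(EntityLabel))
                span = Span(doc.doc_id, placed.start, placed.end, label, placed.surface)
                pred.add(span)
                taken.append(span)
    return pred


@dataclass(frozen=True)
class ExpectedMetrics:
    precision: float
    recall: float
    f1: float


def expected_metrics(
    corruption: CorruptionConfig,
    gold_spans: int | None = None,
    documents: int | None = None,
    partial_credit: float = 0.5,
) -> dict[Granularity, ExpectedMetrics]:
    """Closed-form expected precision/recall/F1 under the corruption model.

    ``gold_spans`` and ``documents`` are required when ``p_spurious > 0``
    (the spurious rate is per document, so precision depends on the
    spans-per-document ratio).  Derivation in the module docstring and in
    docs/methods.md.
    """
    m, s, t, c = corruption.p_miss, corruption.p_shift, corruption.p_type, partial_credit
    recalls = {
        Granularity.STRICT: (1 - m) * (1 - s) * (1 - t),
        Granularity.EXACT: (1 - m) * (1 - s),
        Granularity.PARTIAL: (1 - m) * ((1 - s) + c * s),
        Granularity.TYPE: (1 - m) * ((1 - s) * (1 - t) + s),
    }
    if corruption.p_spurious > 0:
        if gold_spans is None or documents is None:
            raise ValueError(
                "gold_spans and documents are required when p_spurious > 0"
            )
        spurious = corruption.p_spurious * documents
        pred_per_gold = (1 - m) + spurious / gold_spans
    else:
        pred_per_gold = 1 - m
    out: dict[Granularity, ExpectedMetrics] = {}
    for gran in GRANULARITIES:
        recall = recalls[gran]
        precision = recall / pred_per_gold if pred_per_gold > 0 else 0.0
        f1 = (
            0.0 if precision + recall == 0
            else 2 * precision * recall / (precision + recall)
        )
        out[gran] = ExpectedMetrics(precision, recall, f1)
    return out


def _outcome_distribution(
    corruption: CorruptionConfig, granularity: Granularity, partial_credit: float
) -> list[tuple[float, float]]:
    """(credit, probability) outcomes of a single gold span."""
    m, s, t, c = corruption.p_miss, corruption.p_shift, corruption.p_type, partial_credit
    p_drop = m
    p_shift = (1 - m) * s
    p_flip = (1 - m) * (1 - s) * t
    p_copy = (1 - m) * (1 - s) * (1 - t)
    credit_shift = {
        Granularity.STRICT: 0.0, Granularity.EXACT: 0.0,
        Granularity.PARTIAL: c, Granularity.TYPE: 1.0,
    }[granularity]
    credit_flip = {
        Granularity.STRICT: 0.0, Granularity.EXACT: 1.0,
        Granularity.PARTIAL: 1.0, Granularity.TYPE: 0.0,
    }[granularity]
    return [(0.0, p_drop), (credit_shift, p_shift), (credit_flip, p_flip), (1.0, p_copy)]


def sampling_se(
    corruption: CorruptionConfig,
    granularity: Granularity,
    gold_spans: int,
    documents: int = 0,
    partial_credit: float = 0.5,
) -> tuple[float, float, float]:
    """Monte-Carlo standard errors (se_P, se_R, se_F1) of the measured metrics.

    Recall: mean of i.i.d. per-span credits, exact variance from the outcome
    distribution.  Precision: delta method for the ratio (total credit) /
    (surviving spans + Poisson spurious), including the credit–survival
    covariance.  F1 is bounded by the larger of the two (its partial
    derivatives in P and R sum to at most one near P ≈ R).
    """
    outcomes = _outcome_distribution(corruption, granularity, partial_credit)
    mean = sum(x * p for x, p in outcomes)
    var_x = sum(x * x * p for x, p in outcomes) - mean**2
    se_r = math.sqrt(var_x / gold_spans)

    m = corruption.p_miss
    surv = 1 - m
    spurious = corruption.p_spurious * documents
    e_num = mean * gold_spans
    e_den = surv * gold_spans + spurious
    var_num = var_x * gold_spans
    var_den = surv * (1 - surv) * gold_spans + spurious  # binomial + Poisson
    cov = (mean - mean * surv) * gold_spans  # per span: E[X·surv] = E[X]
    if e_den <= 0:
        return 0.0, se_r, se_r
    var_p = (
        var_num / e_den**2
        + (e_num**2) * var_den / e_den**4
        - 2 * e_num * cov / e_den**3
    )
    se_p = math.sqrt(max(var_p, 0.0))
    return se_p, se_r, max(se_p, se_r)
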