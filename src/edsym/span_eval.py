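"""Entity-level span scoring at four matching granularities.

Predicted spans are compared with gold spans under four regimes, from
strictest to most lenient:

* ``STRICT``  — boundaries and entity type must both match exactly;
* ``EXACT``   — boundaries must match exactly, type is ignored;
* ``PARTIAL`` — any character overlap earns partial credit (default 0.5),
  exact boundaries earn full credit, type is ignored;
* ``TYPE``    — type must match and the intervals must overlap by at least a
  configurable number of characters (default 1).

Scoring uses the MUC/SemEval five-category bookkeeping: COR (correct), INC
(exact boundaries but wrong type, STRICT only), PAR (partial boundary
overlap, PARTIAL only), MIS (gold span left unmatched) and SPU (predicted
span left unmatched).  Precision and recall give a matched pair credit
``COR + 0.5*PAR`` over the number of predicted resp. gold spans in scope.

Gold and predicted spans of one document are put in one-to-one
correspondence by an optimal assignment: a weight matrix (1 for a
COR-eligible pair, the partial credit for a PAR-eligible pair, a tie-break
epsilon for INC) is solved exactly with the Hungarian algorithm.  Among
equally weighted optima the choice of pairs cannot change precision, recall
or F1, because the numerator equals the total matched weight and the
denominators are the fixed gold/pred counts.  ``exhaustive_match_score``
re-derives the optimum by brute-force enumeration and serves as an
independent cross-check on small instances.

Inter-annotator agreement is the same machinery with one annotator taken as
reference: the entity-level F1 is symmetric in the two annotators, while
precision and recall swap when the arguments swap.
"""

from __future__ import annotations

from collections.abc import Iterable, Sequence
from dataclasses import dataclass, field
from enum import Enum

import numpy as np
import pandas as pd
from scipy.optimize import linear_sum_assignment

from .corpus_io import AnnotationSet, EntityLabel, Span

#: tie-break weight for exact-boundary wrong-type pairs under STRICT: never
#: displaces a real match, only fills otherwise-unmatched pairs.
_INC_EPS = 1e-6

ALL = "ALL"


class Granularity(str, Enum):
    STRICT = "strict"
    EXACT = "exact"
    PARTIAL = "partial"
    TYPE = "entity_type"


GRANULARITIES = tuple(Granularity)


@dataclass(frozen=True)
class MatchConfig:
    """Tunables of the matcher.

    ``partial_credit`` is the credit a boundary-overlapping but inexact pair
    earns under PARTIAL (0.5 by default; 1.0 gives full credit).
    ``type_overlap_min`` is the minimum character overlap required under
    TYPE ("some overlap" is not otherwise quantified).
    """

    partial_credit: float = 0.5
    type_overlap_min: int = 1

    def __post_init__(self) -> None:
        if not (0.0 < self.partial_credit <= 1.0):
            raise ValueError("partial_credit must be in (0, 1]")
        if self.type_overlap_min < 1:
            raise ValueError("type_overlap_min must be >= 1")


DEFAULT_CONFIG = MatchConfig()


@dataclass
class MatchResult:
    """Five-category counts for one granularity and label scope."""

    granularity: Granularity
    label_scope: str = ALL
    cor: int = 0
    inc: int = 0
    par: int = 0
    mis: int = 0
    spu: int = 0

    @property
    def n_gold(self) -> int:
        return self.cor + self.inc + self.par + self.mis

    @property
    def n_pred(self) -> int:
        return self.cor + self.inc + self.par + self.spu

    def __iadd__(self, other: "MatchResult") -> "MatchResult":
        if other.granularity is not self.granularity:
            raise ValueError("cannot pool counts across granularities")
        self.cor += other.cor
        self.inc += other.inc
        self.par += other.par
        self.mis += other.mis
        self.spu += other.spu
        return self


@dataclass(frozen=True)
class Metrics:
    precision: float
    recall: float
    f1: float
    support: int
    #: True when a zero denominator forced the corresponding metric to 0
    empty_scope: bool = False


def _pair_weight(g: Span, p: Span, granularity: Granularity, config: MatchConfig) -> float:
    """Matching weight of a gold/pred pair under one granularity; 0 = no match."""
    exact = g.start == p.start and g.end == p.end
    overlap = g.overlap(p)
    if granularity is Granularity.STRICT:
        if exact:
            return 1.0 if g.label is p.label else _INC_EPS
        return 0.0
    if granularity is Granularity.EXACT:
        return 1.0 if exact else 0.0
    if granularity is Granularity.PARTIAL:
        if exact:
            return 1.0
        return config.partial_credit if overlap > 0 else 0.0
    # TYPE
    return 1.0 if (g.label is p.label and overlap >= config.type_overlap_min) else 0.0


def _classify(g: Span, p: Span, granularity: Granularity) -> str:
    """Category of a matched pair (the pair is known to have weight > 0)."""
    exact = g.start == p.start and g.end == p.end
    if granularity is Granularity.STRICT:
        return "cor" if g.label is p.label else "inc"
    if granularity is Granularity.PARTIAL:
        return "cor" if exact else "par"
    return "cor"


def match_spans(
    gold: Sequence[Span],
    pred: Sequence[Span],
    granularity: Granularity,
    config: MatchConfig = DEFAULT_CONFIG,
    label_scope: str = ALL,
) -> MatchResult:
    """Optimal one-to-one matching of one document's gold and predicted spans.

    All spans must come from the same document.  Unassigned gold spans count
    MIS, unassigned predictions SPU.
    """
    docs = {s.doc_id for s in gold} | {s.doc_id for s in pred}
    if len(docs) > 1:
        raise ValueError(f"spans from mixed documents: {sorted(docs)!r}")
    result = MatchResult(granularity, label_scope)
    gold = sorted(gold, key=lambda s: (s.start, s.end, s.label.value))
    pred = sorted(pred, key=lambda s: (s.start, s.end, s.label.value))
    if not gold or not pred:
        result.mis = len(gold)
        result.spu = len(pred)
        return result

    weights = np.array(
        [[_pair_weight(g, p, granularity, config) for p in pred] for g in gold]
    )
    rows, cols = linear_sum_assignment(weights, maximize=True)
    matched_gold: set[int] = set()
    matched_pred: set[int] = set()
    for i, j in zip(rows, cols):
        if weights[i, j] <= 0.0:
            continue
        matched_gold.add(i)
        matched_pred.add(j)
        category = _classify(gold[i], pred[j], granularity)
        setattr(result, category, getattr(result, category) + 1)
    result.mis = len(gold) - len(matched_gold)
    result.spu = len(pred) - len(matched_pred)
    return result


def compute_metrics(result: MatchResult, config: MatchConfig = DEFAULT_CONFIG) -> Metrics:
    """Precision, recall and F1 from five-category counts.

    ``P = (COR + c*PAR) / (COR+INC+PAR+SPU)`` and
    ``R = (COR + c*PAR) / (COR+INC+PAR+MIS)`` with partial credit ``c``;
    zero denominators yield 0 with the ``empty_scope`` flag set.
    """
    matched = result.cor + config.partial_credit * result.par
    empty = False
    if result.n_pred == 0:
        precision, empty = 0.0, True
    else:
        precision = matched / result.n_pred
    if result.n_gold == 0:
        recall, empty = 0.0, True
    else:
        recall = matched / result.n_gold
    f1 = 0.0 if precision + recall == 0 else 2 * precision * recall / (precision + recall)
    return Metrics(precision, recall, f1, support=result.n_gold, empty_scope=empty)


def exhaustive_match_score(
    gold: Sequence[Span],
    pred: Sequence[Span],
    granularity: Granularity,
    config: MatchConfig = DEFAULT_CONFIG,
) -> float:
    """Maximum total credit over *all* one-to-one assignments, by enumeration.

    Independent optimality oracle for :func:`match_spans` on small instances
    (exponential in ``len(pred)``; intended for <= ~12 predictions).  The
    credit of a pair is recomputed here from first principles: 1 for an
    exact-boundary same-type pair under every granularity, 1 for an
    exact-boundary pair under EXACT/PARTIAL regardless of type, the partial
    credit for an inexact overlap under PARTIAL, 1 for a type-matching
    overlap under TYPE, else 0.  INC pairs carry no credit.
    """
    def credit(g: Span, p: Span) -> float:
        exact = g.start == p.start and g.end == p.end
        ov = max(0, min(g.end, p.end) - max(g.start, p.start))
        same = g.label is p.label
        if granularity is Granularity.STRICT:
            return 1.0 if exact and same else 0.0
        if granularity is Granularity.EXACT:
            return 1.0 if exact else 0.0
        if granularity is Granularity.PARTIAL:
            if exact:
                return 1.0
            return config.partial_credit if ov > 0 else 0.0
        return 1.0 if same and ov >= config.type_overlap_min else 0.0

    n_pred = len(pred)
    if n_pred > 20:
        raise ValueError("exhaustive oracle limited to small instances")
    # DP over subsets of predictions, one gold span at a time.
    best = {0: 0.0}
    for g in gold:
        nxt = dict(best)
        for used, score in best.items():
            for j in range(n_pred):
                if used >> j & 1:
                    continue
                w = credit(g, pred[j])
                if w <= 0.0:
                    continue
                key = used | 1 << j
                cand = score + w
                if cand > nxt.get(key, -1.0):
                    nxt[key] = cand
        best = nxt
    return max(best.values())


def matched_credit(result: MatchResult, config: MatchConfig = DEFAULT_CONFIG) -> float:
    """Total credit of a match result, comparable to the exhaustive oracle."""
    return result.cor + config.partial_credit * result.par


class MetricReport:
    """Per-label, per-granularity counts and metrics for a whole corpus.

    Micro aggregation: five-category counts are pooled over documents before
    precision/recall/F1 are computed.  Layout mirrors the usual validation
    tables — one block per entity label plus an ALL block, with the four
    granularities as columns.
    """

    def __init__(self, config: MatchConfig = DEFAULT_CONFIG):
        self.config = config
        self._results: dict[tuple[str, Granularity], MatchResult] = {}

    def pool(self, result: MatchResult) -> None:
        key = (result.label_scope, result.granularity)
        if key in self._results:
            self._results[key] += result
        else:
            self._results[key] = result

    def counts(self, label_scope: str, granularity: Granularity) -> MatchResult:
        return self._results[(label_scope, granularity)]

    def metrics(self, label_scope: str, granularity: Granularity) -> Metrics:
        return compute_metrics(self.counts(label_scope, granularity), self.config)

    @property
    def label_scopes(self) -> list[str]:
        order = [ALL] + [lab.value for lab in EntityLabel]
        present = {scope for scope, _ in self._results}
        return [s for s in order if s in present]

    def to_frame(self) -> pd.DataFrame:
        """Long-format table: one row per (entity, granularity) with metrics."""
        rows = []
        for scope in self.label_scopes:
            for gran in GRANULARITIES:
                if (scope, gran) not in self._results:
                    continue
                c = self.counts(scope, gran)
                m = self.metrics(scope, gran)
                rows.append(
                    {
                        "entity": scope,
                        "granularity": gran.value,
                        "precision": m.precision,
                        "recall": m.recall,
                        "f1": m.f1,
                        "support": m.support,
                        "cor": c.cor,
                        "inc": c.inc,
                        "par": c.par,
                        "mis": c.mis,
                        "spu": c.spu,
                    }
                )
        return pd.DataFrame(rows)

    def to_json(self) -> dict:
        out: dict[str, dict] = {}
        for scope in self.label_scopes:
            out[scope] = {}
            for gran in GRANULARITIES:
                if (scope, gran) not in self._results:
                    continue
                m = self.metrics(scope, gran)
                out[scope][gran.value] = {
                    "precision": round(m.precision, 4),
                    "recall": round(m.recall, 4),
                    "f1": round(m.f1, 4),
                    "support": m.support,
                }
        return out

    def summary(self) -> str:
        """Printable table, one metric row per entity block, 2 decimals."""
        lines = []
        grans = [g.value for g in GRANULARITIES]
        header = "metric".ljust(12) + "".join(g.rjust(13) for g in grans)
        for scope in self.label_scopes:
            lines.append(f"[{scope}]")
            lines.append(header)
            for name in ("f1", "precision", "recall"):
                row = name.ljust(12)
                for gran in GRANULARITIES:
                    m = self.metrics(scope, gran)
                    row += f"{getattr(m, name):13.2f}"
                lines.append(row)
            lines.append("")
        return "\n".join(lines)


def evaluate_corpus(
    gold: AnnotationSet,
    pred: AnnotationSet,
    config: MatchConfig = DEFAULT_CONFIG,
    granularities: Iterable[Granularity] = GRANULARITIES,
    doc_ids: Iterable[str] | None = None,
) -> MetricReport:
    """Micro-aggregated evaluation of predictions against gold annotations.

    Per-label rows restrict both sides to that label before matching; the
    ALL rows pool every label.  ``doc_ids``, when given, restricts the
    evaluation to those documents (e.g. a held-out validation split); spans
    on other documents are ignored.
    """
    if doc_ids is None:
        ids = sorted(set(gold.doc_ids) | set(pred.doc_ids))
    else:
        ids = sorted(doc_ids)
    granularities = tuple(granularities)
    report = MetricReport(config)
    scopes: list[tuple[str, EntityLabel | None]] = [(ALL, None)] + [
        (lab.value, lab) for lab in EntityLabel
    ]
    for doc_id in ids:
        g_spans = gold.for_doc(doc_id)
        p_spans = pred.for_doc(doc_id)
        for scope_name, label in scopes:
            g = g_spans if label is None else [s for s in g_spans if s.label is label]
            p = p_spans if label is None else [s for s in p_spans if s.label is label]
            for gran in granularities:
                report.pool(match_spans(g, p, gran, config, label_scope=scope_name))
    return report


def interannotator_agreement(
    annotations_a: AnnotationSet,
    annotations_b: AnnotationSet,
    config: MatchConfig = DEFAULT_CONFIG,
) -> MetricReport:
    """Entity-level agreement between two annotators.

    Annotator A is taken as reference and B as prediction; the F1 values are
    invariant under swapping the arguments, while precision and recall
    exchange.
    """
    return evaluate_corpus(annotations_a, annotations_b, config)
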