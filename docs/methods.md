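# Methods

This note documents the models and procedures implemented in `edsym`, the
parameters that matter, the synthetic data the tests run on, and the design
choices made where more than one reasonable option existed.

## Annotation model

A corpus is a set of documents (short clinical narratives); annotations are
character-offset spans with one of three labels: SYMPTOM, ANATOMY, NEGATION.
Offsets are 0-based half-open intervals, Doccano's native convention; the
surface string is materialised on every span and must equal the text slice
(checked by `validate_spans`). Spans are contiguous — discontinuous
entities are not representable. Overlapping spans of *different* labels are
allowed (a negation cue may overlap a symptom phrase); identical
(start, end, label) duplicates are rejected. Unknown label strings found in
an input file are collected into a read report and excluded rather than
failing the file, so a corpus annotated with a richer tag set degrades
gracefully to the three labels this pipeline models.

Two guideline lint rules encode the harmonised annotation policy for German
clinical text. COMPOUND_SPLIT fires when an anatomy span and a symptom span
are directly adjacent and jointly cover a single whitespace-free token —
the policy is that closed compounds like "Rückenschmerzen" get one span.
SLASH_LIST_MERGED fires when one anatomy span's surface contains "/" — the
policy is that slash lists like "Rücken/Hüfte" get one span per anatomy.

## Tokenization and IOB encoding

The tokenizer is deterministic and dependency-free: maximal runs of word
characters are tokens; every other non-space character, including "/", is a
single-character token. This keeps compounds whole and splits slash lists,
which is what both the linter and the negation scoper need. No claim is
made that it matches any model's subword tokenizer; subword alignment is a
backend concern.

Encoding tags a token with `B-`/`I-` of a span iff the token overlaps the
span; a span that cuts a token claims the whole token. Decoding turns every
maximal `B-/I-` run into one span, so decoding an encoded span set returns
the minimal token-aligned superset of each original span (the identity for
token-aligned spans — property-tested). Two same-label spans overlapping
one token have no IOB encoding and raise; a cross-label conflict is
resolved in favour of the earlier-starting span with a recorded warning.
The decoder repairs orphan `I-` tags to `B-` and reports the repair, which
makes it tolerant to imperfect model output without silently inventing
structure.

## Span matching and metrics

Matching is per document and one-to-one. Pair eligibility and weight under
the four granularities:

| granularity | eligible pairs                       | weight |
|-------------|--------------------------------------|--------|
| strict      | exact boundaries, same type          | 1      |
|             | exact boundaries, different type     | ε (counted INC) |
| exact       | exact boundaries, any type           | 1      |
| partial     | exact boundaries, any type           | 1      |
|             | any character overlap, any type      | c (counted PAR) |
| entity type | ≥ `type_overlap_min` chars, same type | 1     |

`c` is the partial credit, default 0.5 (configurable to 1.0 for full
credit); `type_overlap_min` defaults to 1 character because "some overlap"
is not otherwise quantified. ε = 1e-6 lets an exact-boundary wrong-type
pair be recorded as INC without ever displacing a true match. Pairs outside
the table are unmatchable: a boundary-overlapping pair under the strict and
exact regimes contributes MIS + SPU, not INC. INC versus MIS+SPU is pure
bookkeeping — both add one to each metric denominator — so this choice
cannot move precision, recall or F1.

The assignment maximises total weight, solved exactly with the Hungarian
algorithm (`scipy.optimize.linear_sum_assignment`). A greedy
exactness-then-overlap pairing was considered and rejected: for equal-weight
overlap tiers greedy matching is not always optimal (one prediction
overlapping two golds while a second prediction overlaps only one is the
minimal counterexample, kept as a regression test). Among equally weighted
optimal assignments the realised COR/PAR split can differ, but the metrics
cannot: the numerator `COR + c·PAR` equals the total matched weight, and the
denominators are the fixed gold and prediction counts. An independent
exhaustive bitmask-DP oracle re-derives the optimum on small instances and
is compared against the matcher on 1,000 random documents.

Micro aggregation (counts pooled across documents before ratios) is used
throughout; it is the NER standard and keeps rare labels stable. Per-label
rows filter both sides to the label before matching, so a cross-type match
can only appear in the ALL rows. Reports print two decimals; computation
keeps full precision. Zero denominators yield 0 with an `empty_scope` flag
rather than NaN.

Consequences worth knowing: F1 is monotone non-decreasing along
strict → exact → partial (proved by pointwise weight dominance and identical
denominators; property-tested on 10,000 random cases), and inter-annotator
F1 is symmetric in the annotators while precision and recall swap.

## Postprocessing pipeline

Stage order: confidence filter → negation detection → anatomy–pain fusion →
surface standardization → dictionary normalization. Every symptom span
surviving the filter yields exactly one record, affirmed or negated.

**Confidence filter.** Keep spans with confidence ≥ τ, default τ = 0.5
(no published threshold exists; 0.5 is the natural midpoint and is
configurable). Unscored spans are kept and flagged — dropping them would
silently discard the whole output of backends that emit no scores. The
filter applies to all three entity types for consistency.

**Negation.** A symptom is negated iff a negation cue ends at or before the
symptom start, no clause boundary (`. ; : ! ?`) intervenes, and the gap
contains at most `negation_window` tokens (default 3) after discounting
coordinators (",", "und", "oder", "sowie", "/") and tokens inside other
symptom spans. The discounting is what lets one cue distribute over a
coordinated list ("keine Übelkeit, Erbrechen oder Fieber" negates all
three) while the window still blocks long-range false scoping. This is a
deliberately shallow, auditable rule — no dependency parsing; post-posed
negation ("Fieber besteht nicht") is out of scope and is the main known
limitation.

**Anatomy–pain fusion.** A symptom whose surface is a bare pain lexeme
("Schmerzen"/"Schmerz", list configurable) is fused with the nearest
anatomy among the adjacent extracted entities — default window one entity
on each side, same clause, preceding wins ties. The fused surface is
`anatomy + lexeme.lower()`, the closed-compound spelling. A surface already
ending in a pain lexeme with a prefix is a compound and is never touched;
bare pain with no anatomy in reach is kept and flagged generic. Fusion
changes surfaces only, never the number of symptom records.

**Standardization and normalization.** Cleaning strips `. : , ; ! ?`,
collapses whitespace, lowercases and capitalizes the first letter
(idempotent; "ß" is left unchanged rather than expanded to "SS" to preserve
idempotence). The normalization dictionary maps enumerated variants —
synonyms and inflections — case-insensitively to one canonical term; no
stemmer is used, so the mapping is fully auditable. The shipped dictionary
covers a small common-symptom set (Obstipation/Verstopfung, Husten/gehustet,
Dyspnoe/Luftnot, …); unmatched terms keep their original name by design.

## Backends

The backend contract is `predict(document) -> spans` plus capability flags.
The lexicon backend does longest-match case-insensitive scanning at word
boundaries (confidence 1.0 on exact case, 0.8 otherwise) and exists to make
every downstream component testable without model weights. The prompt
backend composes the three-part zero-shot schema — entity definitions,
worked examples, and a fixed instruction requesting reasoning plus a Python
list without comments — deterministically around the narrative, parses the
*last* bracketed list in the response (models often restate examples
first), and grounds each entity string by case-insensitive search, one span
per non-overlapping occurrence. Ungrounded strings are excluded and
reported rather than scored as spurious, because no published policy exists
for aligning list output to boundaries; the report keeps them available if
a caller wants the harsher accounting. Parse failures are flagged data, not
exceptions. The token-classifier adapter wraps any tokens→tags callable via
the IOB codec; no weights or training code ship.

## Synthetic corpus and corruption model

The generator emits 1–5 clause documents from five templates — affirmed
symptom, negated symptom (cue directly before the symptom), compound pain,
analytic pain ("Schmerzen in <anatomy>") and slash anatomy lists — over a
small embedded German lexicon, with uniform sex/age-group metadata. Default
conditions: 150 documents (the size of a realistically annotatable clinical
validation corpus), p_negation = 0.3 (negation is pervasive in ED notes),
p_pain = 0.4, p_compound = 0.5, p_slash_list = 0.1. Generation is
seed-deterministic (`random.Random`). All gold spans are token-aligned
single tokens or whole phrases, so IOB round trips are exact. What the
generator does *not* model: spelling noise, abbreviations, post-posed or
morphological negation, discontinuous mentions, and real lexical diversity
— so green tests certify the machinery, not clinical-grade accuracy on real
narratives.

The corruption model chains per-span branches: drop with probability
`p_miss`; otherwise shift one boundary with `p_shift`; otherwise flip the
label with `p_type`; otherwise copy exactly. Spurious spans are added per
document at Poisson rate `p_spurious` on non-entity tokens. Two structural
constraints keep the mathematics exact: shifted spans still overlap their
own gold span but never any other, and spurious spans never overlap gold.
Hence each prediction is matchable to at most its own gold span and the
optimal matching decomposes per span, giving

```
R_strict  = (1−m)(1−s)(1−t)
R_exact   = (1−m)(1−s)          # a flipped copy keeps exact boundaries
R_partial = (1−m)((1−s) + c·s)  # type-blind: flips count, shifts earn c
R_type    = (1−m)((1−s)(1−t) + s)  # shifts keep label and overlap
P_g       = R_g·G / ((1−m)·G + E[spurious])
```

with G gold spans. Boundary shifts move to the adjacent token edge by
default (widen into a free neighbouring token, else shrink, else a
one-character fallback) so shifted spans stay token-aligned. `sampling_se`
provides the Monte-Carlo standard errors used by the convergence tests:
exact outcome-distribution variance for recall, delta method (including the
credit–survival covariance and the Poisson spurious term) for precision,
and the larger of the two as a bound for F1 (its partial derivatives in P
and R sum to at most about one near P ≈ R). Convergence is asserted at
three standard errors on corpora of ≥ 1,000 gold spans — roughly 300
generated documents, a size chosen to keep the full suite under a few
seconds while leaving the standard errors around 0.01.

## Numerical and degenerate-input choices

- Matching is deterministic: spans are sorted before the weight matrix is
  built and the Hungarian solver is deterministic given the matrix.
- Empty gold or prediction sets short-circuit to pure MIS/SPU counts.
- Metric reports round only at the printing boundary.
- The validation split uses seeded sampling without replacement and floor
  rounding (15% of 150 documents → 22).
- CLI outputs embed the seed and a SHA-256 hash of the effective
  configuration; exit codes are 0 (success), 1 (validation), 2 (I/O).

## Known limitations

- Negation scoping is pre-posed-cue only; scope terminators ("aber"),
  post-posed and morphological negation are unmodelled.
- The tokenizer splits internal punctuation ("z.B." becomes four tokens);
  acceptable for scoring and scoping, wrong for linguistic analysis.
- Dictionary normalization is enumeration-based; unseen inflections pass
  through unchanged.
- The synthetic corpus is template-bound; measured scores on it say nothing
  quantitative about performance on real clinical text.
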