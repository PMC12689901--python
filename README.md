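# edsym

Symptom NER evaluation and affirmed-symptom extraction for German-style
clinical free text.

Emergency-department (ED) anamnesis notes are short, telegraphic narratives
written under time pressure. They carry the symptom picture of the visit —
but locked in free text, with German-specific obstacles: closed compounds
that fuse anatomy and symptom into one token ("Kopfschmerzen"), slash-listed
anatomies ("Rücken/Hüfte"), and pervasive negation ("keine Dyspnoe") that
turns a mention into an *exclusion* rather than a finding. `edsym` is a
toolkit for teams building or auditing NER pipelines over such text. It
provides:

- **Corpus I/O and annotation QA** — Doccano-style JSONL with character
  offsets, span validation, and a linter for the two classic annotation
  guideline pitfalls (split compounds, merged slash lists).
- **IOB codec** — lossless conversion between character-offset spans and
  token-level IOB tags (CoNLL export), with documented widening/repair
  behaviour for imperfect input.
- **Span-level evaluation at four granularities** — strict (boundaries +
  type), exact (boundaries only), partial (overlap, half credit) and entity
  type (type + overlap), using MUC/SemEval-style COR/INC/PAR/MIS/SPU
  bookkeeping and an *optimal* one-to-one span assignment. The same
  machinery measures inter-annotator agreement as entity-level F1.
- **Negation-aware postprocessing** — confidence filtering, clause-bounded
  negation scoping, anatomy–pain fusion ("Kopf" + "Schmerzen" →
  "Kopfschmerzen"), surface cleaning and dictionary normalization
  ("Verstopfung" → "Obstipation"), producing structured affirmed-symptom
  records.
- **Pluggable backends** — a deterministic lexicon scanner, a zero-shot
  prompt backend (three-part prompt schema, Python-list answer parsing, span
  grounding) for locally hosted LLMs, and an adapter for token classifiers.
- **A synthetic corpus generator** with exact gold spans and a calibrated
  corruption model whose expected precision/recall/F1 are known in closed
  form — so the whole evaluation stack is testable without any clinical data.

## The scoring model

For one document, gold spans `G` and predicted spans `P` are put in
one-to-one correspondence. Under granularity `g`, a pair `(i, j)` earns
weight `w_g(i, j) ∈ {1, ½, 0}` (1 for a correct match, ½ for a partial
boundary overlap under the partial regime, 0 if unmatchable), and the
matching maximises the total weight (Hungarian assignment; a brute-force
enumeration oracle guards optimality in the tests). With pooled counts over
documents,

```
P = (COR + ½·PAR) / (COR + INC + PAR + SPU)
R = (COR + ½·PAR) / (COR + INC + PAR + MIS)
F1 = 2PR / (P + R)
```

where MIS are unmatched gold spans and SPU unmatched predictions.
Aggregation is micro (counts pooled before ratios), per entity label and
overall. Inter-annotator agreement is the same score with one annotator as
reference; F1 is symmetric under swapping annotators.

## Worked example

The narrative below contains three affirmed findings and two negated ones
("No dyspnea, no thoracic pain"). With its span annotations in
`example.jsonl`:

```bash
edsym extract example.jsonl --out-dir demo
# 3 affirmed / 2 negated records from 1 documents
cat demo/frequency.tsv
# term    count
# Overheating     1
# Redness 1
# Swelling        1
```

The affirmed records keep provenance offsets and the negated mentions land
in `demo/negated.csv` instead of the affirmed table — exclusion of negated
symptoms is the point of the pipeline, since "no thoracic pain" must never
be counted as thoracic pain.

Evaluating corrupted synthetic predictions against their gold corpus shows
the four granularities at work (precision/recall/F1 per entity and overall):

```bash
edsym simulate --out-dir sim --n-documents 150 --seed 1 --p-miss 0.2 --p-shift 0.1
edsym evaluate sim/gold.jsonl sim/pred.jsonl --out-dir simeval
# [ALL]
# metric             strict        exact      partial  entity_type
# f1                   0.80         0.80         0.85         0.90
# precision            0.89         0.89         0.94         1.00
# recall               0.73         0.73         0.78         0.82
# ...
```

With 20% of spans dropped and 10% boundary-shifted, strict recall lands near
(1−0.2)·(1−0.1) ≈ 0.72, partial recall recovers half credit for the shifted
spans, and the entity-type score ignores the boundary damage entirely —
exactly the behaviour the closed-form corruption model predicts.

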