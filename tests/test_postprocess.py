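import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from edsym.corpus_io import Document, EntityLabel, Span
from edsym.postprocess import (
    DictionaryError,
    NormalizationDictionary,
    PostprocessConfig,
    default_dictionary,
    detect_negated,
    extract_affirmed,
    filter_confidence,
    fuse_pain_anatomy,
    normalize_symptom,
    standardize_surface,
)
from edsym.synthetic import GeneratorConfig, generate_corpus


def make_spans(text, doc="d", **surfaces):
    """surfaces: surface -> label; spans located by first occurrence."""
    spans = []
    for surface, label in surfaces.items():
        start = text.index(surface)
        spans.append(Span(doc, start, start + len(surface), label, surface))
    return spans


class TestFilterConfidence:
    def spans(self, *confs):
        return [
            Span("d", i * 2, i * 2 + 1, EntityLabel.SYMPTOM, "x", confidence=c)
            for i, c in enumerate(confs)
        ]

    def test_threshold_drops_low_confidence(self):
        result = filter_confidence(self.spans(0.9, 0.4), 0.5)
        assert [s.confidence for s in result.kept] == [0.9]

    def test_zero_threshold_keeps_everything(self):
        spans = self.spans(0.9, 0.4, 0.0)
        assert filter_confidence(spans, 0.0).kept == spans

    def test_unscored_spans_retained_and_flagged(self):
        spans = self.spans(None, None)
        result = filter_confidence(spans, 0.7)
        assert result.kept == spans
        assert result.unscored == spans

    def test_invalid_threshold_rejected(self):
        with pytest.raises(ValueError):
            filter_confidence([], 1.2)

    def test_monotone_in_threshold(self):
        spans = self.spans(0.1, 0.3, 0.5, 0.7, 0.9, None)
        kept_sets = [
            {s for s in filter_confidence(spans, tau).kept}
            for tau in (0.0, 0.25, 0.5, 0.75, 1.0)
        ]
        for lower, higher in zip(kept_sets, kept_sets[1:]):
            assert higher <= lower


class TestDetectNegated:
    def negations(self, doc, spans, **kw):
        marks = detect_negated(doc, spans, PostprocessConfig(**kw))
        return {m.span.surface: m.negated for m in marks}

    def test_each_cue_negates_its_symptom(self):
        text = "No dyspnea, no thoracic pain."
        doc = Document("d", text)
        spans = [
            Span("d", 0, 2, EntityLabel.NEGATION, "No"),
            Span("d", 3, 10, EntityLabel.SYMPTOM, "dyspnea"),
            Span("d", 12, 14, EntityLabel.NEGATION, "no"),
            Span("d", 15, 28, EntityLabel.SYMPTOM, "thoracic pain"),
        ]
        assert self.negations(doc, spans) == {"dyspnea": True, "thoracic pain": True}

    def test_no_cue_means_affirmed(self):
        text = "Swelling of the right lower leg with redness"
        doc = Document("d", text)
        spans = make_spans(
            text, Swelling=EntityLabel.SYMPTOM, redness=EntityLabel.SYMPTOM
        )
        assert self.negations(doc, spans) == {"Swelling": False, "redness": False}

    def test_sentence_boundary_blocks_scope(self):
        text = "Keine Übelkeit. Fieber."
        doc = Document("d", text)
        spans = make_spans(
            text,
            Keine=EntityLabel.NEGATION,
            Übelkeit=EntityLabel.SYMPTOM,
            Fieber=EntityLabel.SYMPTOM,
        )
        assert self.negations(doc, spans) == {"Übelkeit": True, "Fieber": False}

    def test_cue_distributes_over_coordination(self):
        text = "Keine Übelkeit, Erbrechen oder Fieber."
        doc = Document("d", text)
        spans = make_spans(
            text,
            Keine=EntityLabel.NEGATION,
            Übelkeit=EntityLabel.SYMPTOM,
            Erbrechen=EntityLabel.SYMPTOM,
            Fieber=EntityLabel.SYMPTOM,
        )
        assert all(self.negations(doc, spans).values())

    def test_window_limits_scope(self):
        text = "Keine Besserung nach langer ausgiebiger Behandlung bei Fieber."
        doc = Document("d", text)
        spans = make_spans(
            text, Keine=EntityLabel.NEGATION, Fieber=EntityLabel.SYMPTOM
        )
        assert self.negations(doc, spans) == {"Fieber": False}

    def test_soundness_on_synthetic_corpus(self):
        """Generator-known negation structure is recovered exactly."""
        corpus, gold = generate_corpus(GeneratorConfig(n_documents=120, seed=9))
        tp = fp = fn = 0
        for doc in corpus:
            spans = gold.for_doc(doc.doc_id)
            marks = detect_negated(doc, spans)
            # independent truth: a cue in the same sentence before the symptom
            sentences = []
            pos = 0
            for chunk in doc.text.split("."):
                sentences.append((pos, pos + len(chunk) + 1))
                pos += len(chunk) + 1
            cues = [s for s in spans if s.label is EntityLabel.NEGATION]
            for mark in marks:
                sent = next(se for se in sentences if se[0] <= mark.span.start < se[1])
                truth = any(
                    sent[0] <= c.start and c.end <= mark.span.start for c in cues
                )
                tp += mark.negated and truth
                fp += mark.negated and not truth
                fn += truth and not mark.negated
        assert tp > 0
        assert fp == 0 and fn == 0  # precision and recall both 1.0


class TestFusePainAnatomy:
    def test_preceding_anatomy_fused(self):
        text = "Kopf Schmerzen seit gestern."
        doc = Document("d", text)
        spans = make_spans(
            text, Kopf=EntityLabel.ANATOMY, Schmerzen=EntityLabel.SYMPTOM
        )
        mentions = fuse_pain_anatomy(doc, spans)
        assert [m.surface for m in mentions] == ["Kopfschmerzen"]
        assert mentions[0].fused_anatomy is not None

    def test_following_anatomy_fused(self):
        text = "Schmerzen in Rücken."
        doc = Document("d", text)
        spans = make_spans(
            text, Schmerzen=EntityLabel.SYMPTOM, Rücken=EntityLabel.ANATOMY
        )
        assert [m.surface for m in fuse_pain_anatomy(doc, spans)] == ["Rückenschmerzen"]

    def test_existing_compound_untouched(self):
        text = "Kopfschmerzen seit gestern. Rücken frei."
        doc = Document("d", text)
        spans = make_spans(
            text, Kopfschmerzen=EntityLabel.SYMPTOM, Rücken=EntityLabel.ANATOMY
        )
        mentions = fuse_pain_anatomy(doc, spans)
        assert [m.surface for m in mentions] == ["Kopfschmerzen"]
        assert mentions[0].fused_anatomy is None

    def test_bare_pain_without_anatomy_flagged_generic(self):
        text = "Schmerzen seit gestern."
        doc = Document("d", text)
        mentions = fuse_pain_anatomy(doc, make_spans(text, Schmerzen=EntityLabel.SYMPTOM))
        assert mentions[0].surface == "Schmerzen"
        assert mentions[0].generic_pain

    def test_anatomy_in_other_clause_not_fused(self):
        text = "Rücken unauffällig. Schmerzen seit gestern."
        doc = Document("d", text)
        spans = make_spans(
            text, Rücken=EntityLabel.ANATOMY, Schmerzen=EntityLabel.SYMPTOM
        )
        mentions = fuse_pain_anatomy(doc, spans)
        assert mentions[0].surface == "Schmerzen"

    def test_fusion_preserves_symptom_count(self, small_synthetic):
        corpus, gold = small_synthetic
        for doc in corpus:
            spans = gold.for_doc(doc.doc_id)
            n_sym = sum(1 for s in spans if s.label is EntityLabel.SYMPTOM)
            assert len(fuse_pain_anatomy(doc, spans)) == n_sym


class TestStandardizeSurface:
    @pytest.mark.parametrize(
        "raw, cleaned",
        [
            ("HUSTEN:", "Husten"),
            ("fieber", "Fieber"),
            ("Husten", "Husten"),
            ("  thoracic   pain. ", "Thoracic pain"),
        ],
    )
    def test_examples(self, raw, cleaned):
        assert standardize_surface(raw) == cleaned

    def test_empty_after_cleaning_is_error(self):
        with pytest.raises(ValueError):
            standardize_surface("...")

    @given(st.text(alphabet=st.characters(categories=["L", "Zs"]), min_size=1, max_size=30))
    @settings(max_examples=200, deadline=None)
    def test_idempotent(self, term):
        try:
            once = standardize_surface(term)
        except ValueError:
            return
        assert standardize_surface(once) == once


class TestNormalizationDictionary:
    def test_shipped_synonyms_and_inflections(self):
        dictionary = default_dictionary()
        assert normalize_symptom("Verstopfung", dictionary) == "Obstipation"
        assert normalize_symptom("Gehustet", dictionary) == "Husten"
        assert normalize_symptom("Xyzalgie", dictionary) == "Xyzalgie"

    def test_canonical_is_own_variant(self):
        dictionary = NormalizationDictionary({"Fieber": ["febril"]})
        assert dictionary.normalize("fieber") == "Fieber"

    def test_conflicting_variant_rejected_at_load(self):
        with pytest.raises(DictionaryError):
            NormalizationDictionary({"A": ["x"], "B": ["X"]})

    def test_idempotent(self):
        dictionary = default_dictionary()
        for canonical in dictionary.entries:
            assert dictionary.normalize(dictionary.normalize(canonical)) == canonical

    def test_tsv_loader(self):
        dictionary = NormalizationDictionary.from_tsv("Husten\tgehustet\thustet\n")
        assert dictionary.normalize("hustet") == "Husten"


class TestExtractAffirmed:
    def test_worked_example_three_affirmed_two_negated(self, worked_example):
        doc, spans = worked_example
        result = extract_affirmed(doc, spans)
        assert sorted(r.standardized_term for r in result.affirmed) == [
            "Overheating", "Redness", "Swelling",
        ]
        assert sorted(r.raw_surface for r in result.negated) == ["dyspnea", "thoracic pain"]

    def test_no_symptom_spans_empty_output(self):
        doc = Document("d", "Keine Auffälligkeiten.")
        result = extract_affirmed(doc, [])
        assert result.affirmed == [] and result.negated == []

    def test_fusion_yields_single_compound_record(self):
        text = "Kopf Schmerzen seit gestern."
        doc = Document("d", text)
        spans = make_spans(text, Kopf=EntityLabel.ANATOMY, Schmerzen=EntityLabel.SYMPTOM)
        result = extract_affirmed(doc, spans)
        assert [r.standardized_term for r in result.affirmed] == ["Kopfschmerzen"]

    def test_record_count_invariant(self, small_synthetic):
        corpus, gold = small_synthetic
        config = PostprocessConfig()
        for doc in corpus:
            spans = gold.for_doc(doc.doc_id)
            result = extract_affirmed(doc, spans, config)
            surviving = filter_confidence(spans, config.confidence_threshold).kept
            n_sym = sum(1 for s in surviving if s.label is EntityLabel.SYMPTOM)
            assert len(result.affirmed) + len(result.negated) == n_sym

    def test_affirmed_set_shrinks_with_threshold(self):
        text = "Fieber und Husten und Schwindel."
        doc = Document("d", text)
        spans = [
            Span("d", 0, 6, EntityLabel.SYMPTOM, "Fieber", confidence=0.9),
            Span("d", 11, 17, EntityLabel.SYMPTOM, "Husten", confidence=0.6),
            Span("d", 22, 31, EntityLabel.SYMPTOM, "Schwindel", confidence=0.3),
        ]
        previous = None
        for tau in (0.0, 0.5, 0.8, 1.0):
            config = PostprocessConfig(confidence_threshold=tau)
            terms = {r.standardized_term for r in extract_affirmed(doc, spans, config).affirmed}
            if previous is not None:
                assert terms <= previous
            previous = terms
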