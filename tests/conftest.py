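import pytest

from edsym.corpus_io import Document, EntityLabel, Span
from edsym.synthetic import GeneratorConfig, generate_corpus


@pytest.fixture(scope="session")
def small_synthetic():
    """A small seed-fixed synthetic corpus with gold annotations."""
    return generate_corpus(GeneratorConfig(n_documents=20, seed=20))


@pytest.fixture(scope="session")
def large_synthetic():
    """A corpus big enough for Monte-Carlo convergence checks (>=1000 spans)."""
    corpus, gold = generate_corpus(GeneratorConfig(n_documents=300, seed=7))
    assert len(gold) >= 1000
    return corpus, gold


@pytest.fixture()
def worked_example():
    """The leg-swelling narrative with affirmed and negated symptom mentions.

    Gold entities: Swelling, redness, overheating (affirmed), dyspnea and
    thoracic pain (each preceded by a "No"/"no" cue).
    """
    text = (
        "4 weeks ago surgery for colon Ca with artificial exit on the right. "
        "In case of closure, resurgery with inpatient stay up to 2 weeks ago. "
        "For days significant Swelling of the right lower leg with redness "
        "and overheating. No dyspnea, no thoracic pain."
    )
    doc = Document("T2", text)

    def span(surface, label, occurrence=0):
        start = -1
        for _ in range(occurrence + 1):
            start = text.index(surface, start + 1)
        return Span("T2", start, start + len(surface), label, surface)

    spans = [
        span("Swelling", EntityLabel.SYMPTOM),
        span("redness", EntityLabel.SYMPTOM),
        span("overheating", EntityLabel.SYMPTOM),
        span("No", EntityLabel.NEGATION),
        span("dyspnea", EntityLabel.SYMPTOM),
        span("no ", EntityLabel.NEGATION),
        span("thoracic pain", EntityLabel.SYMPTOM),
    ]
    # trim the trailing space grabbed to disambiguate the lowercase cue
    cue = spans[5]
    spans[5] = Span("T2", cue.start, cue.end - 1, cue.label, cue.surface.strip())
    return doc, spans
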