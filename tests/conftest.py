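"""Shared fixtures: a hand-built worked-example sentence with a known
dependency tree, small handcrafted documents, and synthetic corpora."""

from __future__ import annotations

import pytest

from biomek.corpus_io import (
    AnnotatedDocument,
    DependencyGraph,
    Event,
    Sentence,
    Span,
    TextBound,
    Token,
    validate_document,
)
from biomek.scheme import MetaKnowledge
from biomek.synthetic_corpus import SynthConfig, generate_corpus

#: worked-example sentence: token surfaces, lemmas, POS, head (0 = root), rel
WORKED_ROWS = [
    ("IEXC29S", "iexc29s", "NN", 2, "SUB"),
    ("were", "be", "VBD", 0, "ROOT"),
    ("unable", "unable", "JJ", 2, "PRD"),
    ("to", "to", "TO", 6, "VMOD"),
    ("significantly", "significantly", "RB", 6, "VMOD"),
    ("transactivate", "transactivate", "VB", 3, "AMOD"),
    ("the", "the", "DT", 9, "NMOD"),
    ("c-sis/PDGF-B", "c-sis/pdgf-b", "NN", 9, "NMOD"),
    ("promoter", "promoter", "NN", 6, "OBJ"),
]


def build_sentence(rows, start: int = 0, index: int = 1, parser: str = "gdep"):
    """Build a Sentence (+ text) from (surface, lemma, pos, head, rel) rows."""
    text = ""
    tokens = []
    for i, (surface, lemma, pos, _, _) in enumerate(rows):
        if i:
            text += " "
        tok_start = start + len(text)
        text += surface
        tokens.append(Token(i + 1, surface, lemma, pos, Span(tok_start, tok_start + len(surface))))
    edges = [
        (head, i + 1, rel) for i, (_, _, _, head, rel) in enumerate(rows) if head != 0
    ]
    sent = Sentence(index=index, span=Span(start, start + len(text)), tokens=tokens)
    sent.graphs[parser] = DependencyGraph(parser=parser, tokens=tokens, edges=edges)
    return sent, text


@pytest.fixture
def worked_example():
    """The shortest-dependency-path worked example as a one-sentence doc."""
    sent, text = build_sentence(WORKED_ROWS)
    doc = AnnotatedDocument(doc_id="worked", text=text, sentences=[sent])
    return doc


@pytest.fixture
def worked_graph(worked_example):
    return worked_example.sentences[0].graphs["gdep"]


def token_by_surface(sent: Sentence, surface: str) -> Token:
    return next(t for t in sent.tokens if t.surface == surface)


@pytest.fixture
def tiny_doc() -> AnnotatedDocument:
    """p53 expression event with a nested regulation, hand-annotated."""
    rows = [
        ("TNF-alpha", "tnf-alpha", "NN", 3, "SUB"),
        ("can", "can", "MD", 3, "VMOD"),
        ("activate", "activate", "VB", 0, "ROOT"),
        ("the", "the", "DT", 5, "NMOD"),
        ("expression", "expression", "NN", 3, "OBJ"),
        ("of", "of", "IN", 5, "NMOD"),
        ("p53", "p53", "NN", 6, "PMOD"),
        (".", ".", ".", 3, "PUN"),
    ]
    sent, text = build_sentence(rows)
    doc = AnnotatedDocument(doc_id="tiny", text=text, sentences=[sent])

    def tb(tb_id, kind, surface):
        start = text.index(surface)
        doc.text_bounds[tb_id] = TextBound(
            tb_id, kind, [Span(start, start + len(surface))], surface
        )

    tb("T1", "Protein", "TNF-alpha")
    tb("T2", "Protein", "p53")
    tb("T3", "Gene_expression", "expression")
    tb("T4", "Positive_regulation", "activate")
    tb("T5", "CL-cue", "can")
    doc.events["E1"] = Event("E1", "Gene_expression", "T3", [("Theme", "T2")])
    doc.events["E2"] = Event(
        "E2", "Positive_regulation", "T4", [("Theme", "E1"), ("Cause", "T1")]
    )
    doc.mk["E1"] = MetaKnowledge()
    doc.mk["E2"] = MetaKnowledge(cl="L2", cues={"CL": ["T5"]})
    validate_document(doc)
    return doc


@pytest.fixture(scope="session")
def small_corpus():
    """Deterministic 40-document separable corpus shared across tests."""
    return generate_corpus(SynthConfig(n_documents=40, seed=11))


@pytest.fixture(scope="session")
def trained_small(small_corpus):
    """Lexicon + model trained on the small corpus (session-cached)."""
    from biomek.cue_lexicon import build_cue_lexicon
    from biomek.mk_pipeline import train_mk

    train_docs = small_corpus[:32]
    lexicon = build_cue_lexicon(train_docs)
    model = train_mk(train_docs, lexicon)
    return train_docs, small_corpus[32:], lexicon, model
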