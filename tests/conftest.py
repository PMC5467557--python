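"""Shared fixtures: deterministic thesaurus, worked-example sentence, corpora."""

import pytest

from sentmark import (
    Corpus,
    Document,
    FeaturePipeline,
    GazetteerRecognizer,
    Model,
    ModelParams,
    RegionKey,
    Sentence,
    StaticThesaurus,
    bundled_lexicon,
)

EXAMPLE_TOKENS = (
    ("We", "PRP"),
    ("studied", "VBD"),
    ("29", "CD"),
    ("patients", "NNS"),
    ("with", "IN"),
    ("FTD", "NNP"),
    (".", "."),
)
EXAMPLE_PARSE = (
    "(S (NP (PRP We)) (VP (VBD studied) (NP (CD 29) (NNS patients)) "
    "(PP (IN with) (NP (NNP FTD)))))"
)


@pytest.fixture
def fixture_thesaurus():
    """Deterministic mini-thesaurus used instead of a full lexical database."""
    return StaticThesaurus(
        {
            "investigate": ["study", "examine"],
            "study": ["investigate", "examine"],
            "use": ["employ", "utilize"],
            "employ": ["use"],
            "show": ["demonstrate", "reveal"],
            "demonstrate": ["show"],
            "patient": ["subject", "participant"],
            "subject": ["patient"],
        }
    )


@pytest.fixture
def empty_thesaurus():
    return StaticThesaurus({})


@pytest.fixture
def gazetteer():
    return GazetteerRecognizer({"FTD": "", "MoCA": "", "hippocampus": ""})


@pytest.fixture
def example_sentence():
    """A sentence shaped like the published worked example: second sentence
    of an 80-sentence paper, one cardinal-noun, one entity, one sp pair."""
    return Sentence(
        doc_id="wex",
        index=1,
        text="We studied 29 patients with FTD.",
        section_title="",
        section_type="other",
        tokens=EXAMPLE_TOKENS,
        parse=EXAMPLE_PARSE,
        gold_highlight=None,
    )


@pytest.fixture
def example_region():
    return RegionKey(0, "other")


@pytest.fixture
def worked_example_model(fixture_thesaurus, gazetteer, example_region):
    """Model carrying the worked example's component weights and boost with
    the reconciled coefficient assignment (0.2 cardinal / 0.4 entity /
    0.4 subject-predicate)."""
    params = ModelParams(coefficient_assignment="reconciled")
    pipeline = FeaturePipeline(bundled_lexicon(), fixture_thesaurus, [gazetteer])
    weights = {
        ("cd:patient", example_region): 1.00,
        ("ne:ftd", example_region): 0.22,
        ("sp:we|studied", example_region): 1.00,
    }
    boosts = {("sp:we|studied", example_region): 0.75}
    return Model.from_tables(params, pipeline, weights, boosts)


def make_sentence(doc_id, index, text="Filler sentence text.", section="other",
                  highlighted=False, tokens=None, parse=None):
    return Sentence(
        doc_id=doc_id,
        index=index,
        text=text,
        section_title=section.capitalize(),
        section_type=section,
        tokens=tokens,
        parse=parse,
        gold_highlight=highlighted,
    )


def make_document(doc_id, n, highlighted_indices=(), section="other"):
    return Document(
        doc_id,
        tuple(
            make_sentence(doc_id, i, f"Sentence number {i} of {doc_id}.",
                          section=section, highlighted=i in highlighted_indices)
            for i in range(n)
        ),
    )


@pytest.fixture
def small_corpus():
    return Corpus(
        (
            make_document("paper-a", 10, highlighted_indices={1, 4}),
            make_document("paper-b", 8, highlighted_indices={0}),
        ),
        split_tag="test",
    )
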