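"""Pattern statistics, weight formulas, boosting, scoring and prediction."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from sentmark import (
    Corpus,
    Document,
    FeaturePipeline,
    Model,
    ModelParams,
    RegionKey,
    boost,
    bundled_lexicon,
    estimate_pattern_stats,
    pattern_weight,
    predict,
    regional_weight,
    score_sentence,
    train_model,
    tune_threshold,
)
from sentmark.features import SentenceFeatures, CardinalMention, NamedEntityMention
from sentmark.model import PatternStats, global_weight

from conftest import make_sentence

EPS = 0.015


@pytest.fixture
def pipeline(fixture_thesaurus, gazetteer):
    return FeaturePipeline(bundled_lexicon(), fixture_thesaurus, [gazetteer])


def doc_from_texts(doc_id, rows, section="other"):
    """rows: list of (text, highlighted)."""
    return Document(
        doc_id,
        tuple(
            make_sentence(doc_id, i, text, section=section, highlighted=h)
            for i, (text, h) in enumerate(rows)
        ),
    )


class TestPatternWeight:
    def test_equal_ratios_give_zero(self):
        assert pattern_weight(0.4, 0.4, EPS) == 0.0

    def test_enriched_pattern_value(self):
        assert pattern_weight(0.5, 0.1, EPS) == pytest.approx(
            math.log2(0.515 / 0.115), abs=1e-12
        )
        assert pattern_weight(0.5, 0.1, EPS) == pytest.approx(2.1630, abs=5e-4)

    def test_exclusive_pattern_hits_epsilon_cap(self):
        assert pattern_weight(1.0, 0.0, EPS) == pytest.approx(
            math.log2(1.015 / 0.015), abs=1e-12
        )
        assert pattern_weight(1.0, 0.0, EPS) == pytest.approx(6.0803, abs=5e-4)

    @given(
        rht=st.floats(0, 1),
        rnh=st.floats(0, 1),
        eps=st.floats(1e-4, 0.5),
    )
    @settings(max_examples=300, derandomize=True)
    def test_antisymmetry_and_bound(self, rht, rnh, eps):
        w = pattern_weight(rht, rnh, eps)
        assert w == pytest.approx(-pattern_weight(rnh, rht, eps), abs=1e-9)
        assert abs(w) <= math.log2((1 + eps) / eps) + 1e-9

    def test_monotone_in_both_arguments(self):
        grid = np.linspace(0, 1, 21)
        for lo, hi in zip(grid, grid[1:]):
            assert pattern_weight(hi, 0.3, EPS) > pattern_weight(lo, 0.3, EPS)
            assert pattern_weight(0.3, hi, EPS) < pattern_weight(0.3, lo, EPS)

    def test_invalid_inputs_rejected(self):
        with pytest.raises(ValueError):
            pattern_weight(1.2, 0.0, EPS)
        with pytest.raises(ValueError):
            pattern_weight(0.5, 0.5, 0.0)


class TestEstimateStats:
    def test_half_half_fixture(self, pipeline):
        # 4 sentences, 2 highlighted; "FTD" in one highlighted and one not:
        # RHT = RNH = 0.5
        doc = doc_from_texts(
            "d",
            [
                ("The FTD cohort was large.", True),
                ("Plain highlighted sentence here.", True),
                ("Another FTD mention appears.", False),
                ("Nothing of note happens.", False),
            ],
        )
        stats = estimate_pattern_stats(Corpus((doc,)), pipeline)
        assert stats.n_highlighted == 2 and stats.n_nonhighlighted == 2
        assert stats.pattern_highlighted["ne:ftd"] == 1
        assert stats.pattern_nonhighlighted["ne:ftd"] == 1
        assert global_weight(stats, "ne:ftd", EPS) == 0.0

    def test_pattern_occurring_twice_in_sentence_counts_once(self, pipeline):
        doc = doc_from_texts("d", [("FTD versus FTD comparison.", True)])
        stats = estimate_pattern_stats(Corpus((doc,)), pipeline)
        assert stats.pattern_highlighted["ne:ftd"] == 1

    def test_exclusive_pattern_ratios(self, pipeline):
        doc = doc_from_texts(
            "d",
            [("MoCA declined sharply.", True), ("No testing happened.", False)],
        )
        stats = estimate_pattern_stats(Corpus((doc,)), pipeline)
        assert stats.pattern_highlighted["ne:moca"] == 1
        assert "ne:moca" not in stats.pattern_nonhighlighted
        assert global_weight(stats, "ne:moca", EPS) == pytest.approx(
            math.log2(1.015 / 0.015), abs=1e-12
        )

    def test_no_highlighted_sentences_is_an_error(self, pipeline):
        doc = doc_from_texts("d", [("Some text.", False), ("More text.", False)])
        with pytest.raises(ValueError, match="no highlighted"):
            estimate_pattern_stats(Corpus((doc,)), pipeline)

    def test_missing_gold_label_is_an_error(self, pipeline):
        doc = Document("d", (make_sentence("d", 0, "Text.", highlighted=None),))
        with pytest.raises(ValueError, match="gold"):
            estimate_pattern_stats(Corpus((doc,)), pipeline)


class TestRegionalWeight:
    def test_region_conditioning_matches_hand_count(self, pipeline):
        # r0 of a 2-sentence doc is sentence 0, r1.. hold the rest
        doc = doc_from_texts(
            "d",
            [
                ("FTD appears early.", True),
                ("FTD appears later too.", False),
                ("Nothing here.", True),
                ("Nothing there.", False),
            ],
        )
        stats = estimate_pattern_stats(Corpus((doc,)), pipeline)
        r0 = RegionKey(0, "other")
        # region r0: 1 highlighted sentence, 1 with the pattern
        assert regional_weight(stats, "ne:ftd", r0, EPS) == pytest.approx(
            math.log2((1.0 + EPS) / EPS), abs=1e-12
        )

    def test_unseen_region_falls_back_to_global(self, pipeline):
        doc = doc_from_texts("d", [("FTD cohort.", True), ("Filler.", False)])
        stats = estimate_pattern_stats(Corpus((doc,)), pipeline)
        unseen = RegionKey(4, "conclusion")
        assert regional_weight(stats, "ne:ftd", unseen, EPS) == global_weight(
            stats, "ne:ftd", EPS
        )

    def test_pattern_absent_from_region_is_nonpositive(self, pipeline):
        doc = doc_from_texts(
            "d",
            [
                ("Nothing in the first half.", True),
                ("FTD only later.", False),
            ],
        )
        stats = estimate_pattern_stats(Corpus((doc,)), pipeline)
        assert regional_weight(stats, "ne:ftd", RegionKey(0, "other"), EPS) <= 0


class TestBoost:
    @pytest.fixture
    def stats(self):
        s = PatternStats(n_highlighted=7, n_nonhighlighted=10)
        r0, r1 = RegionKey(0, "other"), RegionKey(1, "other")
        s.region_highlighted = {r0: 4, r1: 3}
        s.pattern_region_highlighted = {
            ("sp:we|studied", r0): 4,
            ("sp:we|studied", r1): 3,
        }
        return s

    def test_modal_region_is_one(self, stats):
        assert boost(stats, "sp:we|studied", RegionKey(0, "other"), k=1) == 1.0

    def test_submodal_ratio(self, stats):
        assert boost(stats, "sp:we|studied", RegionKey(1, "other"), k=1) == 0.75

    def test_k_squares_the_ratio(self, stats):
        assert boost(stats, "sp:we|studied", RegionKey(1, "other"), k=2) == 0.5625

    def test_nonincreasing_in_k_below_the_mode(self, stats):
        r1 = RegionKey(1, "other")
        values = [boost(stats, "sp:we|studied", r1, k) for k in (0.5, 1, 2, 4)]
        assert values == sorted(values, reverse=True)

    def test_unseen_pattern_is_neutral(self, stats):
        assert boost(stats, "sp:never|seen", RegionKey(0, "other"), k=1) == 1.0

    def test_range_where_pattern_occurs(self, stats):
        for region, _count in [(RegionKey(0, "other"), 4), (RegionKey(1, "other"), 3)]:
            b = boost(stats, "sp:we|studied", region, k=1)
            assert 0 < b <= 1

    def test_invalid_k_rejected(self, stats):
        with pytest.raises(ValueError):
            boost(stats, "sp:we|studied", RegionKey(0, "other"), k=0)


class TestScoreSentence:
    def test_worked_example_score(self, worked_example_model, example_sentence, example_region):
        feats = worked_example_model.pipeline.features(example_sentence)
        score = score_sentence(feats, example_region, worked_example_model)
        assert score == pytest.approx(0.516, abs=1e-9)
        assert round(score, 2) == 0.52

    def test_all_zero_weights_score_zero(self, pipeline, example_sentence, example_region):
        model = Model.from_tables(ModelParams(), pipeline, {}, {})
        feats = pipeline.features(example_sentence)
        # every pattern unseen -> weight 0, neutral-ish boost cannot rescue
        assert score_sentence(feats, example_region, model) == 0.0

    def test_weighted_sum_arithmetic(self, pipeline, example_region):
        # CD weights {1.0, 0.5}, no entities, SP weight 2.0, boost 1,
        # printed coefficients (0.4, 0.2, 0.4): 0.4*1.5 + 0.4*2.0 = 1.4
        weights = {
            ("cd:patient", example_region): 1.0,
            ("cd:control", example_region): 0.5,
            ("sp:we|studied", example_region): 2.0,
        }
        from sentmark.features import SubjectPredicatePair

        model = Model.from_tables(ModelParams(), pipeline, weights, {})
        feats = SentenceFeatures(
            cardinals=frozenset(
                {CardinalMention("29", "patient"), CardinalMention("12", "control")}
            ),
            entities=frozenset(),
            sp_pairs=(SubjectPredicatePair("we", ("study",), ("studied",)),),
        )
        assert score_sentence(feats, example_region, model) == pytest.approx(1.4, abs=1e-12)

    def test_unmatched_sp_contributes_nothing_but_neutral_boost(
        self, pipeline, example_region
    ):
        from sentmark.features import SubjectPredicatePair

        weights = {("cd:patient", example_region): 1.0}
        model = Model.from_tables(ModelParams(), pipeline, weights, {})
        feats = SentenceFeatures(
            cardinals=frozenset({CardinalMention("5", "patient")}),
            sp_pairs=(SubjectPredicatePair("bridge", ("collapse",), ("collapsed",)),),
        )
        assert score_sentence(feats, example_region, model) == pytest.approx(0.4 * 1.0)

    def test_adding_positive_pattern_never_lowers_score(self, pipeline, example_region):
        weights = {
            ("cd:patient", example_region): 1.0,
            ("ne:moca", example_region): 0.7,
        }
        model = Model.from_tables(ModelParams(), pipeline, weights, {})
        base = SentenceFeatures(
            cardinals=frozenset({CardinalMention("5", "patient")})
        )
        richer = SentenceFeatures(
            cardinals=base.cardinals,
            entities=frozenset({NamedEntityMention("MoCA", "moca")}),
        )
        assert score_sentence(richer, example_region, model) >= score_sentence(
            base, example_region, model
        )

    def test_coefficient_assignments_differ_as_documented(
        self, pipeline, example_sentence, example_region
    ):
        weights = {
            ("cd:patient", example_region): 1.00,
            ("ne:ftd", example_region): 0.22,
            ("sp:we|studied", example_region): 1.00,
        }
        boosts = {("sp:we|studied", example_region): 0.75}
        feats = pipeline.features(example_sentence)
        printed = Model.from_tables(
            ModelParams(coefficient_assignment="printed"), pipeline, weights, boosts
        )
        assert score_sentence(feats, example_region, printed) == pytest.approx(
            (0.4 * 1.0 + 0.2 * 0.22 + 0.4 * 1.0) * 0.75, abs=1e-12
        )


class TestParams:
    def test_coefficients_must_sum_to_one(self):
        with pytest.raises(ValueError, match="equal 1"):
            ModelParams(alpha=0.5, beta=0.5, gamma=0.5)

    def test_assignment_maps_coefficients(self):
        printed = ModelParams(coefficient_assignment="printed")
        reconciled = ModelParams(coefficient_assignment="reconciled")
        assert printed.coefficients() == (0.4, 0.2, 0.4)
        assert reconciled.coefficients() == (0.2, 0.4, 0.4)

    def test_epsilon_and_k_positive(self):
        with pytest.raises(ValueError):
            ModelParams(epsilon=0)
        with pytest.raises(ValueError):
            ModelParams(k=-1)


class TestTrainPredict:
    @pytest.fixture
    def labelled_corpus(self):
        docs = []
        for d in range(3):
            sentences = []
            for i in range(12):
                if i % 4 == 0:
                    n = 20 + i
                    sentences.append(
                        make_sentence(
                            f"doc-{d}", i,
                            f"We studied {n} patients with FTD.",
                            highlighted=True,
                            tokens=(("We", "PRP"), ("studied", "VBD"),
                                    (str(n), "CD"), ("patients", "NNS"),
                                    ("with", "IN"), ("FTD", "NNP"), (".", ".")),
                            parse=(
                                f"(S (NP (PRP We)) (VP (VBD studied) "
                                f"(NP (CD {n}) (NNS patients)) "
                                f"(PP (IN with) (NP (NNP FTD)))))"
                            ),
                        )
                    )
                else:
                    sentences.append(
                        make_sentence(f"doc-{d}", i,
                                      f"Routine passage number {i} continues.",
                                      highlighted=False)
                    )
            docs.append(Document(f"doc-{d}", tuple(sentences)))
        return Corpus(tuple(docs))

    def test_training_is_deterministic(self, labelled_corpus, fixture_thesaurus, gazetteer):
        kwargs = dict(
            lexicon=bundled_lexicon(),
            params=ModelParams(),
            synonyms=fixture_thesaurus,
            recognizers=[gazetteer],
        )
        m1 = train_model(labelled_corpus, **kwargs)
        m2 = train_model(labelled_corpus, **kwargs)
        assert m1.to_dict() == m2.to_dict()

    def test_separable_corpus_reaches_perfect_f1(self, labelled_corpus, fixture_thesaurus, gazetteer):
        from sentmark.evaluation import evaluate_predictions, macro_average

        model = train_model(
            labelled_corpus, bundled_lexicon(), ModelParams(), fixture_thesaurus, [gazetteer]
        )
        preds = [p for doc in labelled_corpus for p in predict(doc, model)]
        assert macro_average(evaluate_predictions(labelled_corpus, preds)).f1 == 1.0

    def test_all_gold_highlighted_gives_min_score_threshold(
        self, fixture_thesaurus, gazetteer
    ):
        doc = doc_from_texts(
            "d", [("We studied 10 patients.", True), ("FTD was frequent.", True)]
        )
        corpus = Corpus((doc,))
        model = train_model(
            corpus, bundled_lexicon(), ModelParams(), fixture_thesaurus, [gazetteer]
        )
        scores = [p.score for p in predict(doc, model)]
        assert model.threshold <= min(scores)
        assert all(p.highlighted for p in predict(doc, model))

    def test_degenerate_equal_scores_warn(self, pipeline, small_corpus):
        model = Model.from_tables(ModelParams(), pipeline, {}, {})
        with pytest.warns(UserWarning, match="identical"):
            t = tune_threshold(model, small_corpus)
        assert t == 0.0

    def test_predictions_cover_every_sentence(self, labelled_corpus, fixture_thesaurus, gazetteer):
        model = train_model(
            labelled_corpus, bundled_lexicon(), ModelParams(), fixture_thesaurus, [gazetteer]
        )
        doc = labelled_corpus.documents[0]
        preds = predict(doc, model)
        assert [p.sentence_index for p in preds] == list(range(doc.n_sentences))
        for p in preds:
            assert p.highlighted == (p.score >= model.threshold)

    def test_highlighted_sentences_carry_categories(
        self, labelled_corpus, fixture_thesaurus, gazetteer
    ):
        model = train_model(
            labelled_corpus, bundled_lexicon(), ModelParams(), fixture_thesaurus, [gazetteer]
        )
        preds = predict(labelled_corpus.documents[0], model)
        highlighted = [p for p in preds if p.highlighted]
        assert highlighted
        # "we studied" is a goal/method pattern in the bundled lexicon
        assert all(p.categories == {"goal", "method"} for p in highlighted)
        assert all(p.categories == frozenset() for p in preds if not p.highlighted)

    def test_serialization_round_trip(self, labelled_corpus, fixture_thesaurus, gazetteer, tmp_path):
        model = train_model(
            labelled_corpus, bundled_lexicon(), ModelParams(), fixture_thesaurus, [gazetteer]
        )
        path = tmp_path / "model.json"
        model.save(path)
        back = Model.load(path, model.pipeline)
        assert back.to_dict() == model.to_dict()
        region = RegionKey(0, "other")
        assert back.weight("ne:ftd", region) == model.weight("ne:ftd", region)

    def test_lexicon_mismatch_warns_on_load(
        self, labelled_corpus, fixture_thesaurus, gazetteer, tmp_path
    ):
        from sentmark.lexicon import Lexicon, PatternEntry

        model = train_model(
            labelled_corpus, bundled_lexicon(), ModelParams(), fixture_thesaurus, [gazetteer]
        )
        path = tmp_path / "model.json"
        model.save(path)
        other = FeaturePipeline(
            Lexicon([PatternEntry("we", "used", frozenset({"goal"}))]),
            fixture_thesaurus,
            [gazetteer],
        )
        with pytest.warns(UserWarning, match="lexicon"):
            Model.load(path, other)
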