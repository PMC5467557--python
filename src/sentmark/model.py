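"""Smoothed log-ratio pattern weights, spatial boosting and sentence scoring.

Training counts, for every language pattern p (cardinal noun, named entity,
or lexicon-matched subject–predicate pair), how often it appears in
highlighted vs non-highlighted sentences, globally and per spatial region.
The weight of p is the smoothed log-odds

    w_p = log2((RHT_p + eps) / (RNH_p + eps))

where RHT_p is the fraction of highlighted sentences containing p and RNH_p
the fraction of non-highlighted ones; eps (default 0.015) caps the weight of
rare patterns.  Region-conditioned weights use the same formula on
region-restricted fractions.  A sentence's overall score combines the three
family sums with coefficients summing to 1 and is multiplied by a boosting
factor

    b(sp, r) = (count of highlighted sentences with sp in r / modal-region count)^k

that rewards subject–predicate patterns occurring in their typical region.
Sentences scoring at or above a tuned threshold are highlighted and labelled
with the categories (goal/method/finding) of their matched patterns.
"""

from __future__ import annotations

import hashlib
import json
import math
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Optional, Sequence

import numpy as np

from .corpus import Corpus, Document
from .features import (
    Recognizer,
    SentenceFeatures,
    SubjectPredicatePair,
    extract_sentence_features,
)
from .lexicon import Lexicon, MatchResult, SynonymProvider, match_pattern
from .regions import DEFAULT_N_BINS, RegionKey, region_key

__all__ = [
    "ModelParams",
    "PatternStats",
    "Model",
    "HighlightPrediction",
    "estimate_pattern_stats",
    "pattern_weight",
    "regional_weight",
    "boost",
    "score_sentence",
    "train_model",
    "tune_threshold",
    "predict",
]

MODEL_FORMAT_VERSION = 1


@dataclass(frozen=True)
class ModelParams:
    """Scoring parameters.

    ``alpha``, ``beta``, ``gamma`` are the printed component coefficients
    (they must sum to 1); ``coefficient_assignment`` selects how they map
    onto the three feature families:

    * ``"printed"`` — alpha on cardinals, beta on entities, gamma on
      subject–predicates, as the scoring equation is written;
    * ``"reconciled"`` — beta on cardinals, alpha on entities, gamma on
      subject–predicates, the assignment under which the published worked
      example's arithmetic (score 0.52) comes out.
    """

    alpha: float = 0.4
    beta: float = 0.2
    gamma: float = 0.4
    epsilon: float = 0.015
    k: float = 1.0
    threshold: Optional[float] = None
    n_bins: int = DEFAULT_N_BINS
    coefficient_assignment: str = "printed"

    def __post_init__(self) -> None:
        if min(self.alpha, self.beta, self.gamma) < 0:
            raise ValueError("component coefficients must be non-negative")
        if abs(self.alpha + self.beta + self.gamma - 1.0) > 1e-9:
            raise ValueError("alpha + beta + gamma must equal 1")
        if self.epsilon <= 0:
            raise ValueError("epsilon must be positive")
        if self.k <= 0:
            raise ValueError("k must be positive")
        if self.coefficient_assignment not in {"printed", "reconciled"}:
            raise ValueError(
                f"unknown coefficient_assignment {self.coefficient_assignment!r}"
            )

    def coefficients(self) -> tuple[float, float, float]:
        """(cardinal, entity, subject-predicate) coefficients."""
        if self.coefficient_assignment == "printed":
            return self.alpha, self.beta, self.gamma
        return self.beta, self.alpha, self.gamma


@dataclass
class PatternStats:
    """Presence counts of patterns in highlighted/non-highlighted sentences.

    A pattern occurring twice in one sentence counts once.  Keys are family-
    prefixed pattern ids (``cd:patient``, ``ne:ftd``, ``sp:we|studied`` —
    subject–predicate ids use the *lexicon entry* key the raw pair matched).
    """

    n_highlighted: int = 0
    n_nonhighlighted: int = 0
    region_highlighted: dict[RegionKey, int] = field(default_factory=dict)
    region_nonhighlighted: dict[RegionKey, int] = field(default_factory=dict)
    pattern_highlighted: dict[str, int] = field(default_factory=dict)
    pattern_nonhighlighted: dict[str, int] = field(default_factory=dict)
    pattern_region_highlighted: dict[tuple[str, RegionKey], int] = field(default_factory=dict)
    pattern_region_nonhighlighted: dict[tuple[str, RegionKey], int] = field(default_factory=dict)

    @property
    def regions(self) -> frozenset[RegionKey]:
        """All regions observed in the training corpus."""
        return frozenset(self.region_highlighted) | frozenset(self.region_nonhighlighted)

    @property
    def patterns(self) -> frozenset[str]:
        return frozenset(self.pattern_highlighted) | frozenset(self.pattern_nonhighlighted)

    def add_sentence(
        self, highlighted: bool, region: RegionKey, pattern_ids: Sequence[str]
    ) -> None:
        if highlighted:
            self.n_highlighted += 1
            self.region_highlighted[region] = self.region_highlighted.get(region, 0) + 1
            pat, pat_r = self.pattern_highlighted, self.pattern_region_highlighted
        else:
            self.n_nonhighlighted += 1
            self.region_nonhighlighted[region] = (
                self.region_nonhighlighted.get(region, 0) + 1
            )
            pat, pat_r = self.pattern_nonhighlighted, self.pattern_region_nonhighlighted
        for p in set(pattern_ids):
            pat[p] = pat.get(p, 0) + 1
            pat_r[(p, region)] = pat_r.get((p, region), 0) + 1


# ---------------------------------------------------------------------------
# feature -> pattern-id pipeline

class FeaturePipeline:
    """Turns a sentence into family-prefixed pattern ids.

    Subject–predicate pairs are matched against the lexicon through the
    synonym tiers; only matched pairs yield pattern ids (unmatched pairs
    carry no trained statistics and are ignored by the scorer).  Match
    results are cached per raw pair.
    """

    def __init__(
        self,
        lexicon: Lexicon,
        synonyms: SynonymProvider,
        recognizers: Sequence[Recognizer],
        n_bins: int = DEFAULT_N_BINS,
    ):
        self.lexicon = lexicon
        self.synonyms = synonyms
        self.recognizers = list(recognizers)
        self.n_bins = n_bins
        self._match_cache: dict[tuple[str, tuple[str, ...]], MatchResult] = {}

    def match(self, pair: SubjectPredicatePair) -> MatchResult:
        cache_key = (pair.subject, pair.predicate)
        result = self._match_cache.get(cache_key)
        if result is None:
            result = match_pattern(pair, self.lexicon, self.synonyms)
            self._match_cache[cache_key] = result
        return result

    def features(self, sentence) -> SentenceFeatures:
        return extract_sentence_features(sentence, self.recognizers)

    def matched_sp(self, features: SentenceFeatures) -> list[MatchResult]:
        out = []
        for pair in features.sp_pairs:
            if pair.incomplete or not pair.subject or not pair.predicate:
                continue
            result = self.match(pair)
            if result.matched:
                out.append(result)
        return out

    def pattern_ids(self, features: SentenceFeatures) -> list[str]:
        ids = [f"cd:{m.head_noun}" for m in features.cardinals]
        ids += [f"ne:{m.normalized_key}" for m in features.entities]
        ids += [f"sp:{r.entry.key}" for r in self.matched_sp(features)]
        return ids


# ---------------------------------------------------------------------------
# estimation and weight formulas

def estimate_pattern_stats(corpus: Corpus, pipeline: FeaturePipeline) -> PatternStats:
    """Count per-pattern presence in highlighted/non-highlighted sentences.

    Requires every sentence to carry a gold label and the corpus to contain
    at least one highlighted sentence (the enrichment ratios are undefined
    otherwise).
    """
    stats = PatternStats()
    for doc in corpus:
        for sentence in doc.sentences:
            if sentence.gold_highlight is None:
                raise ValueError(
                    f"{sentence.doc_id}[{sentence.index}] has no gold label"
                )
            region = region_key(sentence, doc, pipeline.n_bins)
            ids = pipeline.pattern_ids(pipeline.features(sentence))
            stats.add_sentence(sentence.gold_highlight, region, ids)
    if stats.n_highlighted == 0:
        raise ValueError("corpus contains no highlighted sentences")
    return stats


def pattern_weight(rht: float, rnh: float, epsilon: float) -> float:
    """Smoothed log2 ratio of highlighted vs non-highlighted presence."""
    if not (0 <= rht <= 1 and 0 <= rnh <= 1):
        raise ValueError("RHT and RNH must lie in [0, 1]")
    if epsilon <= 0:
        raise ValueError("epsilon must be positive")
    return math.log2((rht + epsilon) / (rnh + epsilon))


def global_weight(stats: PatternStats, pattern: str, epsilon: float) -> float:
    rht = stats.pattern_highlighted.get(pattern, 0) / stats.n_highlighted
    rnh = (
        stats.pattern_nonhighlighted.get(pattern, 0) / stats.n_nonhighlighted
        if stats.n_nonhighlighted
        else 0.0
    )
    return pattern_weight(rht, rnh, epsilon)


def regional_weight(
    stats: PatternStats, pattern: str, region: RegionKey, epsilon: float
) -> float:
    """Region-conditioned weight; falls back to the global weight for
    regions with no highlighted training sentences."""
    n_h = stats.region_highlighted.get(region, 0)
    if n_h == 0:
        return global_weight(stats, pattern, epsilon)
    n_nh = stats.region_nonhighlighted.get(region, 0)
    rht = stats.pattern_region_highlighted.get((pattern, region), 0) / n_h
    rnh = (
        stats.pattern_region_nonhighlighted.get((pattern, region), 0) / n_nh
        if n_nh
        else 0.0
    )
    return pattern_weight(rht, rnh, epsilon)


def boost(stats: PatternStats, sp_pattern: str, region: RegionKey, k: float) -> float:
    """Region-preference multiplier for a subject–predicate pattern.

    ``(count in region / modal-region count)^k`` over highlighted training
    sentences; neutral 1 for patterns never seen highlighted in training.
    """
    if k <= 0:
        raise ValueError("k must be positive")
    counts = {
        r: c
        for (p, r), c in stats.pattern_region_highlighted.items()
        if p == sp_pattern
    }
    if not counts:
        return 1.0
    peak = max(counts.values())
    return (counts.get(region, 0) / peak) ** k


# ---------------------------------------------------------------------------
# the trained model

@dataclass(frozen=True)
class HighlightPrediction:
    doc_id: str
    sentence_index: int
    score: float
    highlighted: bool
    categories: frozenset[str]
    region: RegionKey


class Model:
    """Trained highlighting model: pattern statistics plus parameters."""

    def __init__(
        self,
        stats: PatternStats,
        params: ModelParams,
        pipeline: FeaturePipeline,
    ):
        self.stats = stats
        self.params = params
        self.pipeline = pipeline
        self._weight_cache: dict[tuple[str, RegionKey], float] = {}
        self._boost_cache: dict[tuple[str, RegionKey], float] = {}

    @classmethod
    def from_tables(
        cls,
        params: ModelParams,
        pipeline: FeaturePipeline,
        regional_weights: dict[tuple[str, RegionKey], float],
        boosts: Optional[dict[tuple[str, RegionKey], float]] = None,
    ) -> "Model":
        """Assemble a model from externally supplied weight/boost tables.

        Useful for scoring with published or hand-set component weights.
        Patterns absent from the tables score 0 with neutral boost.
        """
        model = cls(PatternStats(n_highlighted=1, n_nonhighlighted=1), params, pipeline)
        model._weight_cache.update(regional_weights)
        model._boost_cache.update(boosts or {})
        return model

    # -- weight/boost lookups ------------------------------------------------
    def weight(self, pattern: str, region: RegionKey) -> float:
        key = (pattern, region)
        w = self._weight_cache.get(key)
        if w is None:
            w = regional_weight(self.stats, pattern, region, self.params.epsilon)
            self._weight_cache[key] = w
        return w

    def boost_for(self, sp_pattern: str, region: RegionKey) -> float:
        key = (sp_pattern, region)
        b = self._boost_cache.get(key)
        if b is None:
            b = boost(self.stats, sp_pattern, region, self.params.k)
            self._boost_cache[key] = b
        return b

    @property
    def threshold(self) -> float:
        if self.params.threshold is None:
            raise ValueError("model threshold not set; call tune_threshold")
        return self.params.threshold

    def with_threshold(self, threshold: float) -> "Model":
        m = Model(self.stats, replace(self.params, threshold=threshold), self.pipeline)
        m._weight_cache = self._weight_cache
        m._boost_cache = self._boost_cache
        return m

    # -- scoring -------------------------------------------------------------
    def score_features(
        self, features: SentenceFeatures, region: RegionKey
    ) -> tuple[float, frozenset[str]]:
        """Overall score and the matched categories of a sentence."""
        c_cd, c_ne, c_sp = self.params.coefficients()
        cd_sum = sum(self.weight(f"cd:{m.head_noun}", region) for m in features.cardinals)
        ne_sum = sum(
            self.weight(f"ne:{m.normalized_key}", region) for m in features.entities
        )
        matches = self.pipeline.matched_sp(features)
        if matches:
            # Eq-2 treats sp as singular: take the matched pair with maximal
            # regional weight for the sp term and the boost.
            best = max(matches, key=lambda r: self.weight(f"sp:{r.entry.key}", region))
            sp_id = f"sp:{best.entry.key}"
            sp_w = self.weight(sp_id, region)
            b = self.boost_for(sp_id, region)
            categories = frozenset().union(*(r.entry.categories for r in matches))
        else:
            sp_w, b, categories = 0.0, 1.0, frozenset()
        score = (c_cd * cd_sum + c_ne * ne_sum + c_sp * sp_w) * b
        return score, categories

    # -- serialization -------------------------------------------------------
    def lexicon_hash(self) -> str:
        payload = json.dumps(
            {e.key: sorted(e.categories) for e in self.pipeline.lexicon},
            sort_keys=True,
        )
        return hashlib.sha256(payload.encode()).hexdigest()

    def to_dict(self) -> dict:
        s = self.stats
        return {
            "format_version": MODEL_FORMAT_VERSION,
            "params": {
                "alpha": self.params.alpha,
                "beta": self.params.beta,
                "gamma": self.params.gamma,
                "epsilon": self.params.epsilon,
                "k": self.params.k,
                "threshold": self.params.threshold,
                "n_bins": self.params.n_bins,
                "coefficient_assignment": self.params.coefficient_assignment,
            },
            "lexicon_hash": self.lexicon_hash(),
            "stats": {
                "n_highlighted": s.n_highlighted,
                "n_nonhighlighted": s.n_nonhighlighted,
                "region_highlighted": {str(r): c for r, c in s.region_highlighted.items()},
                "region_nonhighlighted": {
                    str(r): c for r, c in s.region_nonhighlighted.items()
                },
                "pattern_highlighted": dict(s.pattern_highlighted),
                "pattern_nonhighlighted": dict(s.pattern_nonhighlighted),
                "pattern_region_highlighted": [
                    [p, str(r), c] for (p, r), c in s.pattern_region_highlighted.items()
                ],
                "pattern_region_nonhighlighted": [
                    [p, str(r), c]
                    for (p, r), c in s.pattern_region_nonhighlighted.items()
                ],
            },
        }

    def save(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=1), encoding="utf-8")

    @classmethod
    def from_dict(cls, data: dict, pipeline: FeaturePipeline) -> "Model":
        if data.get("format_version") != MODEL_FORMAT_VERSION:
            raise ValueError(f"unsupported model format: {data.get('format_version')}")
        sd = data["stats"]
        stats = PatternStats(
            n_highlighted=sd["n_highlighted"],
            n_nonhighlighted=sd["n_nonhighlighted"],
            region_highlighted={
                RegionKey.parse(r): c for r, c in sd["region_highlighted"].items()
            },
            region_nonhighlighted={
                RegionKey.parse(r): c for r, c in sd["region_nonhighlighted"].items()
            },
            pattern_highlighted=dict(sd["pattern_highlighted"]),
            pattern_nonhighlighted=dict(sd["pattern_nonhighlighted"]),
            pattern_region_highlighted={
                (p, RegionKey.parse(r)): c
                for p, r, c in sd["pattern_region_highlighted"]
            },
            pattern_region_nonhighlighted={
                (p, RegionKey.parse(r)): c
                for p, r, c in sd["pattern_region_nonhighlighted"]
            },
        )
        params = ModelParams(**data["params"])
        model = cls(stats, params, pipeline)
        if data.get("lexicon_hash") and data["lexicon_hash"] != model.lexicon_hash():
            warnings.warn("lexicon differs from the one the model was trained with")
        return model

    @classmethod
    def load(cls, path: str | Path, pipeline: FeaturePipeline) -> "Model":
        return cls.from_dict(
            json.loads(Path(path).read_text(encoding="utf-8")), pipeline
        )


def score_sentence(
    features: SentenceFeatures, region: RegionKey, model: Model
) -> float:
    """Overall relevance score of a sentence's features in its region."""
    return model.score_features(features, region)[0]


# ---------------------------------------------------------------------------
# training / threshold / prediction

def _document_scores(model: Model, document: Document) -> np.ndarray:
    scores = np.empty(document.n_sentences)
    for i, sentence in enumerate(document.sentences):
        region = region_key(sentence, document, model.params.n_bins)
        features = model.pipeline.features(sentence)
        scores[i] = model.score_features(features, region)[0]
    return scores


def tune_threshold(model: Model, corpus: Corpus, max_candidates: int = 201) -> float:
    """Pick the score threshold maximising macro-averaged F1 on ``corpus``.

    Candidates are the observed score quantiles; ties break toward the
    higher threshold (fewer highlights).
    """
    doc_scores, doc_gold = [], []
    for doc in corpus:
        doc_scores.append(_document_scores(model, doc))
        doc_gold.append(
            np.array([s.gold_highlight is True for s in doc.sentences])
        )
    all_scores = np.concatenate(doc_scores)
    uniq = np.unique(all_scores)
    if uniq.size == 1:
        warnings.warn("all sentence scores identical; threshold degenerate")
        return float(uniq[0])
    if uniq.size > max_candidates:
        uniq = np.unique(np.quantile(all_scores, np.linspace(0, 1, max_candidates)))
    best_t, best_f1 = float(uniq[0]), -1.0
    for t in uniq:
        f1s = []
        for scores, gold in zip(doc_scores, doc_gold):
            pred = scores >= t
            tp = int(np.sum(pred & gold))
            fp = int(np.sum(pred & ~gold))
            fn = int(np.sum(~pred & gold))
            p = tp / (tp + fp) if tp + fp else 0.0
            r = tp / (tp + fn) if tp + fn else 0.0
            f1s.append(2 * p * r / (p + r) if p + r else 0.0)
        macro_f1 = float(np.mean(f1s))
        if macro_f1 >= best_f1:  # >= so ties move toward higher thresholds
            best_f1, best_t = macro_f1, float(t)
    return best_t


def train_model(
    corpus: Corpus,
    lexicon: Lexicon,
    params: ModelParams,
    synonyms: SynonymProvider,
    recognizers: Sequence[Recognizer],
    tune: bool = True,
) -> Model:
    """Estimate statistics on a labelled corpus and assemble a model.

    Deterministic: training twice on the same corpus yields identical
    models.  The decision threshold is tuned on the training corpus unless
    ``params.threshold`` is already set or ``tune`` is false.
    """
    pipeline = FeaturePipeline(lexicon, synonyms, recognizers, params.n_bins)
    stats = estimate_pattern_stats(corpus, pipeline)
    model = Model(stats, params, pipeline)
    if params.threshold is None and tune:
        model = model.with_threshold(tune_threshold(model, corpus))
    return model


def predict(document: Document, model: Model) -> list[HighlightPrediction]:
    """Score every sentence and flag those at or above the threshold.

    Highlighted sentences carry the union of the categories of their
    matched subject–predicate patterns.
    """
    threshold = model.threshold
    out = []
    for sentence in document.sentences:
        region = region_key(sentence, document, model.params.n_bins)
        features = model.pipeline.features(sentence)
        score, categories = model.score_features(features, region)
        highlighted = score >= threshold
        out.append(
            HighlightPrediction(
                doc_id=document.doc_id,
                sentence_index=sentence.index,
                score=score,
                highlighted=highlighted,
                categories=categories if highlighted else frozenset(),
                region=region,
            )
        )
    return out
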