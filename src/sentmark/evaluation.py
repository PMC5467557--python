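"""Precision/recall/F1 evaluation and bag-of-words baselines.

Counting is sentence-level: a sentence carrying several (or partial)
curator highlights is one gold positive, counted once.  Macro averages
compute P/R/F1 per paper first and then take the unweighted mean; micro
averages pool TP/FP/FN over all papers before computing the metrics.  Zero
denominators yield 0 (conservative convention).

The baselines abstract each sentence as a stopword-filtered tf-idf
bag-of-words vector (smooth idf ``ln((1+N)/(1+df)) + 1``, L2-normalised
rows) and train one of four standard binary classifiers on it.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier
from sklearn.feature_extraction.text import TfidfVectorizer
from sklearn.linear_model import PassiveAggressiveClassifier, Perceptron
from sklearn.neighbors import KNeighborsClassifier

from .corpus import Corpus

__all__ = [
    "ConfusionCounts",
    "MetricsReport",
    "confusion_counts",
    "prf",
    "macro_average",
    "micro_average",
    "evaluate_predictions",
    "default_stopwords",
    "tfidf_vectorize",
    "BASELINE_ALGORITHMS",
    "train_baseline",
    "evaluate_baseline",
]


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    fp: int
    fn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.fn) < 0:
            raise ValueError("confusion counts must be non-negative")

    def __add__(self, other: "ConfusionCounts") -> "ConfusionCounts":
        return ConfusionCounts(self.tp + other.tp, self.fp + other.fp, self.fn + other.fn)


@dataclass(frozen=True)
class MetricsReport:
    precision: float
    recall: float
    f1: float
    per_paper: Optional[pd.DataFrame] = None  # doc_id, precision, recall, f1


def confusion_counts(
    gold_labels: Sequence[bool], predicted_labels: Sequence[bool]
) -> ConfusionCounts:
    """Sentence-level TP/FP/FN from aligned gold and predicted label lists."""
    if len(gold_labels) != len(predicted_labels):
        raise ValueError(
            f"label length mismatch: {len(gold_labels)} gold vs "
            f"{len(predicted_labels)} predicted"
        )
    tp = fp = fn = 0
    for g, p in zip(gold_labels, predicted_labels):
        if p and g:
            tp += 1
        elif p and not g:
            fp += 1
        elif g and not p:
            fn += 1
    return ConfusionCounts(tp, fp, fn)


def prf(counts: ConfusionCounts) -> tuple[float, float, float]:
    """Precision, recall, F1; zero denominators give 0."""
    p = counts.tp / (counts.tp + counts.fp) if counts.tp + counts.fp else 0.0
    r = counts.tp / (counts.tp + counts.fn) if counts.tp + counts.fn else 0.0
    f1 = 2 * p * r / (p + r) if p + r else 0.0
    return p, r, f1


def _per_paper_table(per_paper: dict[str, ConfusionCounts]) -> pd.DataFrame:
    rows = []
    for doc_id, counts in per_paper.items():
        p, r, f1 = prf(counts)
        rows.append({"doc_id": doc_id, "precision": p, "recall": r, "f1": f1})
    return pd.DataFrame(rows, columns=["doc_id", "precision", "recall", "f1"])


def macro_average(per_paper: dict[str, ConfusionCounts]) -> MetricsReport:
    """Per-paper P/R/F1 first, then the unweighted mean across papers."""
    if not per_paper:
        raise ValueError("macro average needs at least one paper")
    table = _per_paper_table(per_paper)
    return MetricsReport(
        precision=float(table["precision"].mean()),
        recall=float(table["recall"].mean()),
        f1=float(table["f1"].mean()),
        per_paper=table,
    )


def micro_average(per_paper: dict[str, ConfusionCounts]) -> MetricsReport:
    """Pool TP/FP/FN across all papers, then compute P/R/F1 once."""
    if not per_paper:
        raise ValueError("micro average needs at least one paper")
    total = ConfusionCounts(0, 0, 0)
    for counts in per_paper.values():
        total = total + counts
    p, r, f1 = prf(total)
    return MetricsReport(p, r, f1, per_paper=_per_paper_table(per_paper))


def evaluate_predictions(corpus: Corpus, predictions) -> dict[str, ConfusionCounts]:
    """Per-paper confusion counts for HighlightPrediction records."""
    by_doc: dict[str, dict[int, bool]] = {}
    for pred in predictions:
        by_doc.setdefault(pred.doc_id, {})[pred.sentence_index] = pred.highlighted
    out = {}
    for doc in corpus:
        preds = by_doc.get(doc.doc_id, {})
        gold = [s.gold_highlight is True for s in doc.sentences]
        predicted = [preds.get(s.index, False) for s in doc.sentences]
        out[doc.doc_id] = confusion_counts(gold, predicted)
    return out


# ---------------------------------------------------------------------------
# tf-idf bag-of-words baselines

def default_stopwords() -> list[str]:
    text = resources.files("sentmark").joinpath("data/stopwords.txt").read_text("utf-8")
    return [w for w in (line.strip() for line in text.splitlines())
            if w and not w.startswith("#")]


def tfidf_vectorize(
    corpus: Corpus, stopword_list: Optional[Sequence[str]] = None
) -> tuple[TfidfVectorizer, "np.ndarray", np.ndarray, list[str]]:
    """Fit a tf-idf vectorizer on every sentence of ``corpus``.

    Returns (fitted vectorizer, sentence × term matrix, gold label vector,
    doc_id per row).  Sentences consisting only of stopwords become zero
    rows (kept, so row alignment with the corpus is preserved).
    """
    texts = [s.text for s in corpus.sentences()]
    if not texts:
        raise ValueError("empty corpus")
    stop = list(stopword_list) if stopword_list is not None else default_stopwords()
    vectorizer = TfidfVectorizer(stop_words=stop)  # smooth idf + l2 defaults
    matrix = vectorizer.fit_transform(texts)
    labels = np.array([s.gold_highlight is True for s in corpus.sentences()])
    doc_ids = [s.doc_id for s in corpus.sentences()]
    return vectorizer, matrix, labels, doc_ids


BASELINE_ALGORITHMS = ("perceptron", "passive_aggressive", "knn", "random_forest")


def train_baseline(matrix, labels: np.ndarray, algorithm_name: str, seed: int = 0):
    """Train one of the four standard binary sentence classifiers."""
    if algorithm_name == "perceptron":
        clf = Perceptron(random_state=seed)
    elif algorithm_name == "passive_aggressive":
        clf = PassiveAggressiveClassifier(random_state=seed)
    elif algorithm_name == "knn":
        clf = KNeighborsClassifier()
    elif algorithm_name == "random_forest":
        clf = RandomForestClassifier(random_state=seed, n_estimators=100)
    else:
        raise ValueError(
            f"unknown baseline algorithm {algorithm_name!r}; "
            f"valid names: {', '.join(BASELINE_ALGORITHMS)}"
        )
    if len(set(labels.tolist())) == 1:
        # degenerate constant-label training set: predict that label everywhere
        return _ConstantClassifier(bool(labels[0]))
    clf.fit(matrix, labels)
    return clf


class _ConstantClassifier:
    def __init__(self, label: bool):
        self.label = label

    def predict(self, matrix) -> np.ndarray:
        return np.full(matrix.shape[0], self.label, dtype=bool)


def evaluate_baseline(
    classifier, vectorizer: TfidfVectorizer, corpus: Corpus
) -> dict[str, ConfusionCounts]:
    """Per-paper confusion counts for a trained bag-of-words classifier."""
    out = {}
    for doc in corpus:
        matrix = vectorizer.transform([s.text for s in doc.sentences])
        predicted = np.asarray(classifier.predict(matrix), dtype=bool)
        gold = [s.gold_highlight is True for s in doc.sentences]
        out[doc.doc_id] = confusion_counts(gold, list(predicted))
    return out
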