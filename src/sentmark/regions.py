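"""Spatial regions: sequential position bins crossed with section types.

Every sentence lives in a cell of a 2-D grid: one of five ordered
proportional position bins (r0 holds the first 20% of a document's
sentences, r4 the last 20%) crossed with a normalized section type.  Pattern
weights and the boosting function are conditioned on these cells, which is
what lets the model learn that, say, goal sentences cluster early in the
introduction while findings sit late in results/discussion.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import TYPE_CHECKING, Iterable, Optional

import pandas as pd

if TYPE_CHECKING:  # pragma: no cover
    from .corpus import Corpus, Document, Sentence

__all__ = [
    "SECTION_TYPES",
    "RegionKey",
    "assign_sequential_region",
    "normalize_section_type",
    "region_key",
    "region_distribution",
]

SECTION_TYPES = (
    "abstract",
    "introduction",
    "methods",
    "results",
    "discussion",
    "conclusion",
    "other",
)

DEFAULT_N_BINS = 5

# keyword → section type; checked in order, first hit wins, so a title like
# "Results and discussion" maps to results.
_SECTION_KEYWORDS = (
    ("abstract", "abstract"),
    ("summary", "abstract"),
    ("introduction", "introduction"),
    ("background", "introduction"),
    ("method", "methods"),
    ("material", "methods"),
    ("result", "results"),
    ("finding", "results"),
    ("discussion", "discussion"),
    ("conclu", "conclusion"),
)


@dataclass(frozen=True, order=True)
class RegionKey:
    """A cell of the sequential-bin × section-type grid."""

    seq_bin: int
    section_type: str

    def __post_init__(self) -> None:
        if self.seq_bin < 0:
            raise ValueError(f"negative sequential bin {self.seq_bin}")
        if self.section_type not in SECTION_TYPES:
            raise ValueError(f"unknown section type {self.section_type!r}")

    def __str__(self) -> str:
        return f"r{self.seq_bin}|{self.section_type}"

    @classmethod
    def parse(cls, text: str) -> "RegionKey":
        seq, _, stype = text.partition("|")
        return cls(int(seq.lstrip("r")), stype)


def assign_sequential_region(index: int, n_sentences: int, n_bins: int = DEFAULT_N_BINS) -> int:
    """Bin a 0-based sentence index into one of ``n_bins`` ordered regions.

    Uses the exact proportional split ``floor(n_bins * index / n_sentences)``,
    clamped to the last bin; bin b therefore holds indices with
    ``index/n_sentences`` in [b/n_bins, (b+1)/n_bins).
    """
    if n_sentences < 1:
        raise ValueError("document must have at least one sentence")
    if not 0 <= index < n_sentences:
        raise ValueError(f"index {index} out of range for {n_sentences} sentences")
    return min(n_bins * index // n_sentences, n_bins - 1)


def normalize_section_type(raw_title: Optional[str]) -> str:
    """Map a raw section title onto the controlled section vocabulary."""
    if not raw_title:
        return "other"
    title = raw_title.strip().lower()
    if title in SECTION_TYPES:
        return title
    for keyword, stype in _SECTION_KEYWORDS:
        if keyword in title:
            return stype
    return "other"


def region_key(sentence: "Sentence", document: "Document", n_bins: int = DEFAULT_N_BINS) -> RegionKey:
    if not (0 <= sentence.index < document.n_sentences):
        raise ValueError(
            f"sentence index {sentence.index} outside document "
            f"{document.doc_id!r} of {document.n_sentences} sentences"
        )
    return RegionKey(
        assign_sequential_region(sentence.index, document.n_sentences, n_bins),
        sentence.section_type,
    )


def region_distribution(
    corpus: "Corpus",
    category_filter: Optional[str] = None,
    sentence_categories: Optional[dict[tuple[str, int], Iterable[str]]] = None,
    n_bins: int = DEFAULT_N_BINS,
) -> pd.DataFrame:
    """Count gold-highlighted sentences per region cell.

    Returns a seq_bin × section_type DataFrame of counts.  With
    ``category_filter`` set (goal/method/finding), only sentences whose
    ``(doc_id, index)`` entry in ``sentence_categories`` contains that
    category are counted.
    """
    counts = pd.DataFrame(
        0, index=range(n_bins), columns=list(SECTION_TYPES), dtype=int
    )
    for doc in corpus:
        for s in doc.sentences:
            if s.gold_highlight is not True:
                continue
            if category_filter is not None:
                cats = (sentence_categories or {}).get((s.doc_id, s.index), ())
                if category_filter not in cats:
                    continue
            key = region_key(s, doc, n_bins)
            counts.loc[key.seq_bin, key.section_type] += 1
    counts.index = [f"r{b}" for b in range(n_bins)]
    return counts
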