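"""Curated subject–predicate pattern lexicon and synonym-based matching.

The lexicon maps ``subject|predicate`` keys ("we|studied") to one or more of
the three rhetorical categories *goal*, *method*, *finding*.  New pairs met
at prediction time rarely occur verbatim in the curated list, so matching
proceeds through three tiers: exact key, lemma-level key, and synonym-set
intersection on both sides.  The synonym source is injectable; the bundled
default is a static thesaurus of common scientific-prose verbs/nouns, and
every provider is reflexive (a word is always its own synonym).
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Optional, Protocol

from .features import SubjectPredicatePair
from .lemmas import lemma

__all__ = [
    "CATEGORIES",
    "PatternEntry",
    "Lexicon",
    "SynonymProvider",
    "StaticThesaurus",
    "MatchResult",
    "load_pattern_lexicon",
    "bundled_lexicon",
    "bundled_thesaurus",
    "match_pattern",
    "categories_of",
]

CATEGORIES = ("goal", "method", "finding")


@dataclass(frozen=True)
class PatternEntry:
    subject: str
    predicate: str
    categories: frozenset[str]

    def __post_init__(self) -> None:
        if not self.categories:
            raise ValueError(f"pattern {self.key!r} has no categories")
        bad = self.categories - set(CATEGORIES)
        if bad:
            raise ValueError(f"pattern {self.key!r}: unknown categories {sorted(bad)}")

    @property
    def key(self) -> str:
        return f"{self.subject}|{self.predicate}"


class Lexicon:
    """Ordered collection of pattern entries, unique by key."""

    def __init__(self, entries: Optional[list[PatternEntry]] = None):
        self._entries: dict[str, PatternEntry] = {}
        for e in entries or []:
            self.add(e)

    def add(self, entry: PatternEntry) -> None:
        existing = self._entries.get(entry.key)
        if existing is not None:  # duplicate keys merge by category union
            entry = PatternEntry(
                entry.subject, entry.predicate, existing.categories | entry.categories
            )
        self._entries[entry.key] = entry

    def __len__(self) -> int:
        return len(self._entries)

    def __iter__(self):
        return iter(self._entries.values())

    def __contains__(self, key: str) -> bool:
        return key in self._entries

    def get(self, key: str) -> Optional[PatternEntry]:
        return self._entries.get(key)

    def category_counts(self) -> dict[str, int]:
        counts = {c: 0 for c in CATEGORIES}
        for e in self:
            for c in e.categories:
                counts[c] += 1
        return counts


class SynonymProvider(Protocol):
    def __call__(self, word: str, pos: str) -> frozenset[str]:
        """Synonym lemmas of ``word`` (POS hint 'n' or 'v'); reflexive."""
        ...  # pragma: no cover


class StaticThesaurus:
    """Synonym provider backed by a word → synonyms table.

    Reflexive closure over lemmas: the result always contains the word's own
    lemma, and lookups go through the lemmatizer so inflected forms share
    synonym sets.
    """

    def __init__(self, table: dict[str, list[str]]):
        self._table = {k.lower(): frozenset(w.lower() for w in v) for k, v in table.items()}

    def __call__(self, word: str, pos: str = "v") -> frozenset[str]:
        lem = lemma(word, pos)
        return self._table.get(lem, frozenset()) | {lem}


def _phrase_lemmas(phrase: str, pos: str) -> tuple[str, ...]:
    return tuple(lemma(w, pos) for w in phrase.split())


def _phrase_head(phrase: str) -> str:
    words = phrase.split()
    return words[-1] if words else ""


# ---------------------------------------------------------------------------
# loading

def load_pattern_lexicon(path: str | Path) -> Lexicon:
    """Load a ``{"subject|predicate": ["goal", ...]}`` JSON lexicon.

    Duplicate keys merge by category union; an empty category list is a
    validation error.
    """
    data = json.loads(Path(path).read_text(encoding="utf-8"))
    lex = Lexicon()
    for key, cats in data.items():
        subject, _, predicate = key.partition("|")
        if not cats:
            raise ValueError(f"lexicon entry {key!r} has an empty category list")
        lex.add(PatternEntry(subject.strip().lower(), predicate.strip().lower(),
                             frozenset(cats)))
    return lex


def bundled_lexicon() -> Lexicon:
    """The mini-lexicon shipped with the package (demos and defaults)."""
    with resources.as_file(
        resources.files("sentmark").joinpath("data/mini_lexicon.json")
    ) as p:
        return load_pattern_lexicon(p)


def bundled_thesaurus() -> StaticThesaurus:
    text = (
        resources.files("sentmark").joinpath("data/mini_thesaurus.json").read_text("utf-8")
    )
    return StaticThesaurus(json.loads(text))


# ---------------------------------------------------------------------------
# matching

@dataclass(frozen=True)
class MatchResult:
    matched: bool
    entry: Optional[PatternEntry] = None
    tier: Optional[str] = None  # exact | lemma | synonym

    def __post_init__(self) -> None:
        if self.matched != (self.entry is not None):
            raise ValueError("matched flag inconsistent with entry")


_NO_MATCH = MatchResult(False)


def match_pattern(
    pair: SubjectPredicatePair, lexicon: Lexicon, synonyms: SynonymProvider
) -> MatchResult:
    """Match an extracted pair against the lexicon.

    Tiers, tried in order over the lexicon's stable insertion order:

    1. *exact* — surface key equality;
    2. *lemma* — equality after lemmatizing subject (noun) and predicate
       verbs;
    3. *synonym* — the subject-head synonym sets intersect AND, position by
       position, the predicate-verb synonym sets intersect.

    The first entry satisfying a tier wins; an unmatched pair is a valid
    result, not an error.
    """
    if pair.incomplete or not pair.subject or not pair.predicate:
        raise ValueError("only complete subject-predicate pairs can be matched")

    key = pair.pattern_key
    entry = lexicon.get(key)
    if entry is not None:
        return MatchResult(True, entry, "exact")

    pair_subject_lemma = lemma(_phrase_head(pair.subject), "n")
    pair_pred_lemmas = pair.predicate
    for entry in lexicon:
        if (
            lemma(_phrase_head(entry.subject), "n") == pair_subject_lemma
            and _phrase_lemmas(entry.predicate, "v") == pair_pred_lemmas
        ):
            return MatchResult(True, entry, "lemma")

    pair_subject_syns = synonyms(_phrase_head(pair.subject), "n")
    pair_pred_syns = [synonyms(v, "v") for v in pair.predicate]
    for entry in lexicon:
        entry_pred = _phrase_lemmas(entry.predicate, "v")
        if len(entry_pred) != len(pair_pred_syns):
            continue
        if not (synonyms(_phrase_head(entry.subject), "n") & pair_subject_syns):
            continue
        if all(
            synonyms(v, "v") & psyns for v, psyns in zip(entry_pred, pair_pred_syns)
        ):
            return MatchResult(True, entry, "synonym")
    return _NO_MATCH


def categories_of(result: MatchResult) -> frozenset[str]:
    return result.entry.categories if result.matched else frozenset()
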