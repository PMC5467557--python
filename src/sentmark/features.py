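"""Sentence-level language-pattern extraction.

Three pattern families drive highlight scoring:

* **cardinal mentions** — a token POS-tagged ``CD`` that specifies a nearby
  noun ("29 patients"); keyed by the noun's lemma, so all cohort sizes of
  patients share statistics;
* **named entities** — dictionary (gazetteer) or plug-in recognizer hits
  ("FTD", "MoCA"); keyed by normalized surface or a recognizer-supplied
  concept id;
* **subject–predicate pairs** — the first noun phrase or personal pronoun of
  a clause and all verbs of the following verb phrase ("we studied"),
  extracted from a constituency parse.

Taggers/parsers are injected: extractors consume pre-tagged tokens and
bracketed parse strings carried on the sentences, so results do not depend
on any specific NLP toolchain.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Callable, Optional, Sequence

from .lemmas import lemma
from .trees import Tree, TreeParseError, parse_tree

__all__ = [
    "CardinalMention",
    "NamedEntityMention",
    "SubjectPredicatePair",
    "SentenceFeatures",
    "GazetteerRecognizer",
    "load_gazetteer",
    "extract_cardinal_mentions",
    "extract_named_entities",
    "extract_subject_predicates",
    "extract_sentence_features",
]

# recognizer contract: text -> iterable of (start, end, surface, key)
Recognizer = Callable[[str], Sequence[tuple[int, int, str, str]]]


@dataclass(frozen=True)
class CardinalMention:
    number_surface: str
    head_noun: str  # lemma

    @property
    def pattern_key(self) -> str:
        return f"CD+{self.head_noun}"


@dataclass(frozen=True)
class NamedEntityMention:
    surface: str
    normalized_key: str
    source: str = "gazetteer"


@dataclass(frozen=True)
class SubjectPredicatePair:
    subject: str  # lower-cased head word
    predicate: tuple[str, ...]  # verb lemmas
    predicate_surface: tuple[str, ...] = ()
    incomplete: bool = False

    @property
    def pattern_key(self) -> str:
        """Surface-form key, e.g. ``we|studied``."""
        surface = self.predicate_surface or self.predicate
        return f"{self.subject}|{' '.join(surface)}"

    @property
    def lemma_key(self) -> str:
        return f"{lemma(self.subject, 'n')}|{' '.join(self.predicate)}"


@dataclass(frozen=True)
class SentenceFeatures:
    cardinals: frozenset[CardinalMention] = frozenset()
    entities: frozenset[NamedEntityMention] = frozenset()
    sp_pairs: tuple[SubjectPredicatePair, ...] = ()


# ---------------------------------------------------------------------------
# cardinal numbers

_NOUN_TAGS = ("NN", "NNS", "NNP", "NNPS")
_HEAD_WINDOW = 3  # nearest following noun within this many tokens


def extract_cardinal_mentions(tagged_tokens: Sequence[tuple[str, str]]) -> frozenset[CardinalMention]:
    """Cardinal numbers that further specify a noun.

    Every token tagged ``CD`` whose noun head (nearest following ``NN*``
    token within a 3-token window) exists yields one mention; bare numbers
    are dropped.  Numbers spelled out as words are typically tagged ``JJ``
    by Penn-Treebank taggers and are therefore not captured.
    """
    if not all(len(t) == 2 and t[1] for t in tagged_tokens):
        raise ValueError("tokens must carry Penn-Treebank POS tags")
    mentions = set()
    for i, (surface, tag) in enumerate(tagged_tokens):
        if tag != "CD":
            continue
        for j in range(i + 1, min(i + 1 + _HEAD_WINDOW, len(tagged_tokens))):
            nsurface, ntag = tagged_tokens[j]
            if ntag in _NOUN_TAGS:
                mentions.add(CardinalMention(surface, lemma(nsurface, "n")))
                break
    return frozenset(mentions)


# ---------------------------------------------------------------------------
# named entities

def _normalize_key(surface: str) -> str:
    return re.sub(r"\s+", " ", surface).strip().lower()


class GazetteerRecognizer:
    """Case-insensitive longest-match dictionary recognizer.

    ``terms`` maps a surface term to its concept id (empty id → the
    normalized surface is the key).  Matches respect word boundaries; at
    overlapping positions the longest term wins.
    """

    name = "gazetteer"

    def __init__(self, terms: dict[str, str]):
        if not terms:
            raise ValueError("empty gazetteer")
        self.terms = {t: (k or _normalize_key(t)) for t, k in terms.items()}
        escaped = sorted((re.escape(t) for t in self.terms), key=len, reverse=True)
        self._regex = re.compile(
            r"(?<!\w)(" + "|".join(escaped) + r")(?!\w)", re.IGNORECASE
        )
        self._by_lower = {t.lower(): key for t, key in self.terms.items()}

    def __call__(self, text: str) -> list[tuple[int, int, str, str]]:
        out = []
        for m in self._regex.finditer(text):
            surface = m.group(1)
            out.append((m.start(), m.end(), surface, self._by_lower[surface.lower()]))
        return out


def load_gazetteer(path: str | Path) -> GazetteerRecognizer:
    """Read a gazetteer file: one term per line, optional tab-separated
    concept id, ``#`` comments."""
    terms: dict[str, str] = {}
    for line in Path(path).read_text(encoding="utf-8").splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        term, _, concept = line.partition("\t")
        terms[term.strip()] = concept.strip()
    return GazetteerRecognizer(terms)


def extract_named_entities(
    sentence_text: str, recognizers: Sequence[Recognizer]
) -> frozenset[NamedEntityMention]:
    """Union of all recognizers' hits, deduplicated by normalized key.

    A recognizer that raises is skipped with a warning; the others are still
    used.  Output order (when iterated sorted) is deterministic.
    """
    if not recognizers:
        raise ValueError("at least one named-entity recognizer is required")
    seen: dict[str, NamedEntityMention] = {}
    for rec in recognizers:
        name = getattr(rec, "name", type(rec).__name__)
        try:
            spans = list(rec(sentence_text))
        except Exception as exc:  # recognizer-internal failure is non-fatal
            warnings.warn(f"recognizer {name!r} failed: {exc}")
            continue
        for start, _end, surface, key in sorted(spans):
            nkey = _normalize_key(key or surface)
            if nkey and nkey not in seen:
                seen[nkey] = NamedEntityMention(surface, nkey, source=name)
    return frozenset(seen.values())


# ---------------------------------------------------------------------------
# subject–predicate pairs

_CLAUSE_LABELS = {"S", "SINV", "SQ"}
_SUBJECT_POS = ("NN", "NNS", "NNP", "NNPS", "PRP")


def _np_head(node: Tree) -> Optional[str]:
    """Rightmost noun (or pronoun) leaf of a noun phrase."""
    nouns = [s for s, tag in node.leaves() if tag in _SUBJECT_POS]
    return nouns[-1].lower() if nouns else None


def _vp_verbs(node: Tree) -> list[str]:
    """VB* leaf surfaces within a VP, not descending into nested clauses."""
    verbs: list[str] = []
    for child in node.children:
        if isinstance(child, str):
            continue
        if child.label in _CLAUSE_LABELS or child.label == "SBAR":
            continue
        if child.is_preterminal:
            if child.label.startswith("VB"):
                verbs.append(child.children[0])
        else:
            verbs.extend(_vp_verbs(child))
    return verbs


def extract_subject_predicates(parse: str | Tree) -> list[SubjectPredicatePair]:
    """Extract (subject, predicate) pairs from a constituency parse.

    Per clause: the head of the first noun phrase (or the personal pronoun)
    under the clause root is the subject; all verbs of the following verb
    phrase form the predicate.  A sentence with several clauses yields
    several pairs.  Pairs with a missing side are returned flagged
    ``incomplete`` (callers exclude them from scoring); a malformed tree
    yields a single incomplete pair.
    """
    if isinstance(parse, str):
        try:
            tree = parse_tree(parse)
        except TreeParseError:
            return [SubjectPredicatePair("", (), incomplete=True)]
    else:
        tree = parse

    pairs: list[SubjectPredicatePair] = []
    clauses = [t for t in tree.subtrees() if t.label in _CLAUSE_LABELS]
    if not clauses and tree.label not in _CLAUSE_LABELS:
        clauses = [tree]
    for clause in clauses:
        subject: Optional[str] = None
        verbs: list[str] = []
        subject_seen_at = None
        children = [c for c in clause.children if isinstance(c, Tree)]
        for pos, child in enumerate(children):
            if subject is None and (
                child.label == "NP"
                or (child.is_preterminal and child.label == "PRP")
            ):
                subject = _np_head(child) or (
                    child.children[0].lower() if child.is_preterminal else None
                )
                subject_seen_at = pos
            elif child.label == "VP" and subject_seen_at is not None and pos > subject_seen_at:
                verbs = _vp_verbs(child)
                break
        if subject and verbs:
            pairs.append(
                SubjectPredicatePair(
                    subject=subject,
                    predicate=tuple(lemma(v, "v") for v in verbs),
                    predicate_surface=tuple(v.lower() for v in verbs),
                )
            )
        elif subject or verbs:
            pairs.append(
                SubjectPredicatePair(
                    subject=subject or "",
                    predicate=tuple(lemma(v, "v") for v in verbs),
                    predicate_surface=tuple(v.lower() for v in verbs),
                    incomplete=True,
                )
            )
    if not pairs:
        pairs.append(SubjectPredicatePair("", (), incomplete=True))
    return pairs


# ---------------------------------------------------------------------------
# per-sentence bundle

def extract_sentence_features(
    sentence, recognizers: Sequence[Recognizer]
) -> SentenceFeatures:
    """Run every extractor the sentence's annotations permit.

    Cardinals need tokens, subject–predicates need a parse; missing
    annotations yield empty feature sets for those families.
    """
    cardinals: frozenset[CardinalMention] = frozenset()
    if sentence.tokens is not None:
        cardinals = extract_cardinal_mentions(sentence.tokens)
    entities = (
        extract_named_entities(sentence.text, recognizers)
        if recognizers
        else frozenset()
    )
    sp_pairs: tuple[SubjectPredicatePair, ...] = ()
    if sentence.parse is not None:
        sp_pairs = tuple(
            p for p in extract_subject_predicates(sentence.parse) if not p.incomplete
        )
    return SentenceFeatures(cardinals=cardinals, entities=entities, sp_pairs=sp_pairs)
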