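"""Documents, corpora and their on-disk formats.

A *document* is an ordered list of sentences, each carrying a section label
and (optionally) a gold highlight flag, token/POS annotations and a
constituency parse.  Two interchange formats are supported: a structured XML
dialect (one document per file, ``<section>`` elements wrapping ``<sentence>``
elements) and a flat per-sentence TSV table that can hold a whole corpus.

Raw curator highlights arrive as text spans; :func:`align_highlights` maps
them onto sentences by normalized string matching.  A span that covers only
part of a sentence marks the whole sentence (sentences are the basic unit of
the model), and several spans inside one sentence mark it once.
"""

from __future__ import annotations

import csv
import io
import re
import unicodedata
from dataclasses import dataclass, field, replace
from difflib import SequenceMatcher
from pathlib import Path
from typing import Iterable, Optional, Sequence

from lxml import etree

from .regions import SECTION_TYPES, normalize_section_type

__all__ = [
    "Sentence",
    "Document",
    "Corpus",
    "HighlightSpan",
    "AlignmentReport",
    "load_corpus",
    "load_document_xml",
    "write_corpus",
    "align_highlights",
    "write_predictions",
    "read_predictions",
]

Token = tuple[str, str]  # (surface, Penn Treebank POS tag)


@dataclass(frozen=True)
class Sentence:
    """One sentence with its position, section and optional annotations."""

    doc_id: str
    index: int  # 0-based ordinal within the document
    text: str
    section_title: str = ""
    section_type: str = "other"
    tokens: Optional[tuple[Token, ...]] = None
    parse: Optional[str] = None  # bracketed constituency tree
    gold_highlight: Optional[bool] = None

    def __post_init__(self) -> None:
        if not self.text.strip():
            raise ValueError(f"{self.doc_id}[{self.index}]: empty sentence text")
        if self.section_type not in SECTION_TYPES:
            raise ValueError(
                f"{self.doc_id}[{self.index}]: unknown section type "
                f"{self.section_type!r}"
            )
        if self.tokens is not None:
            for tok in self.tokens:
                if len(tok) != 2 or not tok[1]:
                    raise ValueError(
                        f"{self.doc_id}[{self.index}]: token without POS tag: {tok!r}"
                    )


@dataclass(frozen=True)
class Document:
    doc_id: str
    sentences: tuple[Sentence, ...]
    journal: Optional[str] = None

    def __post_init__(self) -> None:
        if not self.sentences:
            raise ValueError(f"document {self.doc_id!r} has zero sentences")
        for i, s in enumerate(self.sentences):
            if s.index != i:
                raise ValueError(
                    f"document {self.doc_id!r}: sentence indices not consecutive "
                    f"from 0 (position {i} has index {s.index})"
                )
            if s.doc_id != self.doc_id:
                raise ValueError(
                    f"document {self.doc_id!r} contains sentence of {s.doc_id!r}"
                )

    @property
    def n_sentences(self) -> int:
        return len(self.sentences)


@dataclass(frozen=True)
class Corpus:
    documents: tuple[Document, ...]
    split_tag: str = ""

    def __post_init__(self) -> None:
        ids = [d.doc_id for d in self.documents]
        if len(set(ids)) != len(ids):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise ValueError(f"duplicate doc_ids in corpus: {dupes}")

    def __len__(self) -> int:
        return len(self.documents)

    def __iter__(self):
        return iter(self.documents)

    def sentences(self) -> Iterable[Sentence]:
        for doc in self.documents:
            yield from doc.sentences


@dataclass(frozen=True)
class HighlightSpan:
    """A raw highlighted text span, as extracted from an annotated PDF."""

    doc_id: str
    raw_text: str

    def __post_init__(self) -> None:
        if not self.raw_text.strip():
            raise ValueError("empty highlight span")


@dataclass
class AlignmentReport:
    matched: dict[str, list[int]] = field(default_factory=dict)  # span -> indices
    unmatched: list[HighlightSpan] = field(default_factory=list)


# ---------------------------------------------------------------------------
# highlight-to-sentence alignment

_DASHES = dict.fromkeys(map(ord, "‐‑‒–—―"), "-")
_QUOTES = {0x2018: "'", 0x2019: "'", 0x201C: '"', 0x201D: '"', 0x00B4: "'"}


def _normalize(text: str) -> str:
    text = unicodedata.normalize("NFKC", text)
    text = text.translate(_DASHES).translate(_QUOTES)
    return re.sub(r"\s+", " ", text).strip().lower()


def _containment_similarity(needle: str, haystack: str) -> float:
    """Fraction of needle characters recoverable in order from haystack."""
    if not needle:
        return 0.0
    blocks = SequenceMatcher(None, needle, haystack, autojunk=False).get_matching_blocks()
    return sum(b.size for b in blocks) / len(needle)


def align_highlights(
    document: Document,
    spans: Sequence[HighlightSpan],
    similarity_threshold: float = 0.90,
) -> tuple[Document, AlignmentReport]:
    """Set ``gold_highlight`` on each sentence a span matches.

    Matching tries, per span/sentence pair: exact normalized substring in
    either direction (a span inside a sentence highlights the whole sentence;
    a span covering several sentences highlights each one), then a
    character-level containment similarity fallback at
    ``similarity_threshold`` to tolerate extraction imprecision.

    Unmatched spans are recorded in the report, never raised.
    """
    for span in spans:
        if span.doc_id != document.doc_id:
            raise ValueError(
                f"span for {span.doc_id!r} applied to document {document.doc_id!r}"
            )
    norm_sents = [_normalize(s.text) for s in document.sentences]
    highlighted = {
        s.index for s in document.sentences if s.gold_highlight is True
    }
    report = AlignmentReport()
    for span in spans:
        nspan = _normalize(span.raw_text)
        hits: list[int] = []
        for idx, nsent in enumerate(norm_sents):
            if nspan in nsent or nsent in nspan:
                hits.append(idx)
        if not hits:
            for idx, nsent in enumerate(norm_sents):
                sim = max(
                    _containment_similarity(nspan, nsent),
                    _containment_similarity(nsent, nspan),
                )
                if sim >= similarity_threshold:
                    hits.append(idx)
        if hits:
            report.matched[span.raw_text] = hits
            highlighted.update(hits)
        else:
            report.unmatched.append(span)
    # sentences not hit by any span become explicit negatives
    new_sentences = tuple(
        replace(s, gold_highlight=s.index in highlighted) for s in document.sentences
    )
    return Document(document.doc_id, new_sentences, document.journal), report


# ---------------------------------------------------------------------------
# tokens / parse serialization helpers

def _encode_tokens(tokens: Sequence[Token]) -> str:
    return " ".join(f"{surface}/{tag}" for surface, tag in tokens)


def _decode_tokens(text: str) -> tuple[Token, ...]:
    out = []
    for item in text.split():
        surface, _, tag = item.rpartition("/")
        if not surface:
            raise ValueError(f"token without POS tag: {item!r}")
        out.append((surface, tag))
    return tuple(out)


# ---------------------------------------------------------------------------
# readers / writers

_TSV_COLUMNS = [
    "doc_id",
    "index",
    "section_title",
    "section_type",
    "text",
    "gold_highlight",
    "tokens",
    "parse",
]


def _sentence_to_row(s: Sentence) -> list[str]:
    return [
        s.doc_id,
        str(s.index),
        s.section_title,
        s.section_type,
        s.text,
        "" if s.gold_highlight is None else ("1" if s.gold_highlight else "0"),
        "" if s.tokens is None else _encode_tokens(s.tokens),
        "" if s.parse is None else s.parse,
    ]


def _row_to_sentence(row: dict[str, str]) -> Sentence:
    gold = row.get("gold_highlight", "")
    return Sentence(
        doc_id=row["doc_id"],
        index=int(row["index"]),
        text=row["text"],
        section_title=row.get("section_title", ""),
        section_type=row.get("section_type") or "other",
        tokens=_decode_tokens(row["tokens"]) if row.get("tokens") else None,
        parse=row.get("parse") or None,
        gold_highlight=None if gold == "" else gold == "1",
    )


def _load_table(path: Path, split_tag: str) -> Corpus:
    docs: dict[str, list[Sentence]] = {}
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        for row in reader:
            docs.setdefault(row["doc_id"], []).append(_row_to_sentence(row))
    documents = tuple(
        Document(doc_id, tuple(sents)) for doc_id, sents in docs.items()
    )
    return Corpus(documents, split_tag=split_tag)


def load_document_xml(path: Path) -> Document:
    """Read one document from the structured XML dialect.

    Layout: a top-level ``<document id=...>`` element containing ``<section
    title=... [type=...]>`` elements, each wrapping ``<sentence>`` elements
    with text content.  Missing section types are inferred from the title.
    """
    tree = etree.parse(str(path))
    root = tree.getroot()
    doc_id = root.get("id") or Path(path).stem
    journal = root.get("journal")
    sentences: list[Sentence] = []
    for section in root.iter("section"):
        title = section.get("title", "")
        stype = section.get("type") or normalize_section_type(title)
        for sent in section.iter("sentence"):
            text = (sent.text or "").strip()
            if not text:
                raise ValueError(f"{doc_id}: empty <sentence> element")
            gold = sent.get("highlight")
            sentences.append(
                Sentence(
                    doc_id=doc_id,
                    index=len(sentences),
                    text=text,
                    section_title=title,
                    section_type=stype,
                    gold_highlight=None if gold is None else gold == "1",
                )
            )
    return Document(doc_id, tuple(sentences), journal=journal)


def load_corpus(path: str | Path, format_name: str, split_tag: str = "") -> Corpus:
    """Load a corpus from ``path`` in the named format.

    ``format_name`` is ``structured-xml`` (a file or a directory of ``*.xml``
    files, one document each) or ``per-sentence-table`` (a TSV file, or a
    directory of ``*.tsv`` files).
    """
    path = Path(path)
    if format_name not in {"structured-xml", "per-sentence-table"}:
        raise ValueError(f"unknown corpus format {format_name!r}")
    if not path.exists():
        raise FileNotFoundError(path)
    if format_name == "structured-xml":
        files = sorted(path.glob("*.xml")) if path.is_dir() else [path]
        return Corpus(tuple(load_document_xml(f) for f in files), split_tag=split_tag)
    if path.is_dir():
        parts = [_load_table(f, split_tag) for f in sorted(path.glob("*.tsv"))]
        docs = tuple(d for c in parts for d in c.documents)
        return Corpus(docs, split_tag=split_tag)
    return _load_table(path, split_tag)


def write_corpus(corpus: Corpus, path: str | Path) -> None:
    """Write a corpus as a per-sentence TSV table (lossless round trip)."""
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(_TSV_COLUMNS)
        for doc in corpus:
            for s in doc.sentences:
                writer.writerow(_sentence_to_row(s))


# ---------------------------------------------------------------------------
# prediction records

_PRED_COLUMNS = ["doc_id", "sentence_index", "score", "highlighted", "categories", "region"]


def write_predictions(corpus: Corpus, predictions, path: str | Path) -> None:
    """Write one tab-separated record per sentence, in document order."""
    n_sent = sum(d.n_sentences for d in corpus)
    preds = list(predictions)
    if len(preds) != n_sent:
        raise ValueError(
            f"{len(preds)} prediction records for {n_sent} corpus sentences"
        )
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(_PRED_COLUMNS)
        for p in preds:
            writer.writerow(
                [
                    p.doc_id,
                    str(p.sentence_index),
                    repr(p.score),
                    "1" if p.highlighted else "0",
                    ",".join(sorted(p.categories)),
                    str(p.region),
                ]
            )


def read_predictions(path: str | Path):
    """Companion reader for :func:`write_predictions` (lossless)."""
    from .model import HighlightPrediction  # local import avoids a cycle
    from .regions import RegionKey

    out = []
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        for row in reader:
            out.append(
                HighlightPrediction(
                    doc_id=row["doc_id"],
                    sentence_index=int(row["sentence_index"]),
                    score=float(row["score"]),
                    highlighted=row["highlighted"] == "1",
                    categories=frozenset(
                        c for c in row["categories"].split(",") if c
                    ),
                    region=RegionKey.parse(row["region"]),
                )
            )
    return out
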