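"""Corpus loading, sentence segmentation and cumulative year slicing.

A corpus is an ordered collection of plain-text documents, each carrying a
document id, a publication year and (optionally) a title and a section label.
Because relationships are only ever extracted within a single sentence, the
segmenter here is the contract the rest of the pipeline builds on: sentences
are half-open character spans into the document text, non-overlapping and
ordered, so that every downstream mention can be traced back to its exact
position in the source document.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Iterator, Optional, Sequence

__all__ = [
    "Document",
    "Sentence",
    "Corpus",
    "CorpusLoadError",
    "DEFAULT_ABBREVIATIONS",
    "VALID_SECTIONS",
    "load_corpus",
    "segment_sentences",
    "subset_by_year",
    "write_sentences_tsv",
]

#: Plausible calendar-year range for publication metadata.
YEAR_RANGE = (1900, 2100)

VALID_SECTIONS = frozenset(
    {"ABSTRACT", "INTRODUCTION", "RESULTS", "DISCUSSION", "OTHER"}
)

#: Tokens after which a sentence-final period is *not* a sentence boundary.
DEFAULT_ABBREVIATIONS = frozenset(
    {
        "Fig.",
        "Figs.",
        "et al.",
        "e.g.",
        "i.e.",
        "cf.",
        "vs.",
        "ca.",
        "approx.",
        "no.",
        "spp.",
        "sp.",
        "subsp.",
        "var.",
        "cv.",
    }
)

_SENTENCE_PUNCT = ".!?"


class CorpusLoadError(ValueError):
    """Raised when corpus files and metadata cannot be reconciled."""


@dataclass(frozen=True)
class Document:
    """One corpus unit: an abstract or a full text with its metadata."""

    doc_id: str
    year: int
    text: str
    title: Optional[str] = None
    section: Optional[str] = None

    def __post_init__(self) -> None:
        if not self.doc_id:
            raise ValueError("doc_id must be non-empty")
        if not YEAR_RANGE[0] <= self.year <= YEAR_RANGE[1]:
            raise ValueError(
                f"year {self.year!r} of document {self.doc_id!r} outside "
                f"plausible range {YEAR_RANGE}"
            )
        if self.section is not None and self.section not in VALID_SECTIONS:
            raise ValueError(
                f"section {self.section!r} of document {self.doc_id!r} not in "
                f"{sorted(VALID_SECTIONS)}"
            )


@dataclass(frozen=True)
class Sentence:
    """A half-open character span ``[start, end)`` into a document's text."""

    doc_id: str
    index: int
    start: int
    end: int
    text: str

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise ValueError("sentence span must be non-empty")
        if len(self.text) != self.end - self.start:
            raise ValueError("sentence text does not match its span length")


class Corpus:
    """Ordered, id-unique collection of documents with a year index."""

    def __init__(self, documents: Iterable[Document]) -> None:
        self._documents: list[Document] = list(documents)
        seen: set[str] = set()
        for doc in self._documents:
            if doc.doc_id in seen:
                raise CorpusLoadError(f"duplicate doc_id {doc.doc_id!r}")
            seen.add(doc.doc_id)
        index: dict[int, list[str]] = {}
        for doc in self._documents:
            index.setdefault(doc.year, []).append(doc.doc_id)
        self._year_index = index

    @property
    def documents(self) -> tuple[Document, ...]:
        return tuple(self._documents)

    @property
    def year_index(self) -> dict[int, list[str]]:
        return {year: list(ids) for year, ids in self._year_index.items()}

    def doc_ids(self) -> list[str]:
        return [doc.doc_id for doc in self._documents]

    def years(self) -> list[int]:
        return sorted(self._year_index)

    def __len__(self) -> int:
        return len(self._documents)

    def __iter__(self) -> Iterator[Document]:
        return iter(self._documents)

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return f"Corpus({len(self)} documents, years {self.years()})"


def load_corpus(text_source: str | Path, metadata: str | Path) -> Corpus:
    """Load a corpus from a directory of ``.txt`` files plus a metadata TSV.

    The metadata file must have a header row with at least ``doc_id`` and
    ``year`` columns (``title`` and ``section`` optional).  Each text file's
    stem is its doc_id.  Documents are returned sorted by doc_id so loading
    is deterministic regardless of filesystem order.
    """
    text_dir = Path(text_source)
    meta_path = Path(metadata)
    rows: dict[str, dict[str, str]] = {}
    with open(meta_path, newline="", encoding="utf-8") as handle:
        reader = csv.DictReader(handle, delimiter="\t")
        if reader.fieldnames is None or "doc_id" not in reader.fieldnames:
            raise CorpusLoadError(
                f"metadata {meta_path} lacks a 'doc_id' header column"
            )
        if "year" not in reader.fieldnames:
            raise CorpusLoadError(
                f"metadata {meta_path} lacks a 'year' header column"
            )
        for row in reader:
            doc_id = (row.get("doc_id") or "").strip()
            if not doc_id:
                continue
            if doc_id in rows:
                raise CorpusLoadError(f"duplicate doc_id {doc_id!r} in metadata")
            rows[doc_id] = row

    documents = []
    for path in sorted(text_dir.glob("*.txt")):
        doc_id = path.stem
        if doc_id not in rows:
            raise CorpusLoadError(
                f"no metadata row for document {doc_id!r} ({path.name})"
            )
        row = rows[doc_id]
        try:
            year = int(row["year"])
        except (KeyError, TypeError, ValueError):
            raise CorpusLoadError(
                f"unparseable year {row.get('year')!r} for document {doc_id!r}"
            ) from None
        title = (row.get("title") or "").strip() or None
        section = (row.get("section") or "").strip() or None
        documents.append(
            Document(
                doc_id=doc_id,
                year=year,
                text=path.read_text(encoding="utf-8"),
                title=title,
                section=section,
            )
        )
    return Corpus(documents)


def _is_abbreviation(text: str, punct_end: int, abbreviations: Iterable[str]) -> bool:
    """True if the text ending at ``punct_end`` ends in a known abbreviation."""
    head = text[:punct_end]
    for abbr in abbreviations:
        if head.endswith(abbr):
            pos = punct_end - len(abbr)
            if pos == 0 or text[pos - 1].isspace():
                return True
    return False


def segment_sentences(
    doc: Document,
    abbreviations: Iterable[str] = DEFAULT_ABBREVIATIONS,
) -> list[Sentence]:
    """Split a document into sentences.

    A boundary is a run of sentence-final punctuation (``.``, ``!``, ``?``)
    followed by whitespace and an uppercase letter or digit, unless the token
    ending at the punctuation is a known abbreviation (e.g. ``Fig.``).
    Offsets are 0-based half-open into ``doc.text``; spans never overlap.
    """
    text = doc.text
    abbreviations = frozenset(abbreviations)
    boundaries: list[int] = []
    i = 0
    n = len(text)
    while i < n:
        if text[i] in _SENTENCE_PUNCT:
            j = i
            while j < n and text[j] in _SENTENCE_PUNCT:
                j += 1
            # boundary iff whitespace then uppercase/digit follows
            k = j
            while k < n and text[k].isspace():
                k += 1
            if k > j and k < n and (text[k].isupper() or text[k].isdigit()):
                if not _is_abbreviation(text, j, abbreviations):
                    boundaries.append(j)
            i = j
        else:
            i += 1

    sentences: list[Sentence] = []
    start = 0
    for cut in boundaries + [n]:
        # trim surrounding whitespace from the span
        s, e = start, cut
        while s < e and text[s].isspace():
            s += 1
        while e > s and text[e - 1].isspace():
            e -= 1
        if e > s:
            sentences.append(
                Sentence(
                    doc_id=doc.doc_id,
                    index=len(sentences),
                    start=s,
                    end=e,
                    text=text[s:e],
                )
            )
        start = cut
    return sentences


def subset_by_year(corpus: Corpus, upto_year: int) -> Corpus:
    """Cumulative slice: all documents published in or before ``upto_year``."""
    return Corpus(doc for doc in corpus if doc.year <= upto_year)


def write_sentences_tsv(sentences: Sequence[Sentence], path: str | Path) -> None:
    """Export sentences as TSV: doc_id, index, start, end, text."""
    with open(path, "w", newline="", encoding="utf-8") as handle:
        writer = csv.writer(handle, delimiter="\t", lineterminator="\n")
        writer.writerow(["doc_id", "index", "start", "end", "text"])
        for s in sentences:
            writer.writerow([s.doc_id, s.index, s.start, s.end, s.text])
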