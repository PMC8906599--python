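"""Reading, validating and screening corpora of statistical-methods sections.

A corpus is an ordered collection of documents, one per study, each holding the
raw text of that study's statistical-methods section plus light metadata
(registry/journal source, section heading, submission date, study type, target
sample size, number of funders). Corpora are read from JSONL or CSV, or from a
minimal XML layout modelled on clinical-trial registry exports.
"""

from __future__ import annotations

import csv
import io
import json
from dataclasses import dataclass, field
from typing import Iterator, Optional, Sequence

import numpy as np
from lxml import etree

__all__ = [
    "Document",
    "Corpus",
    "CorpusValidationError",
    "CorpusParseError",
    "read_corpus",
    "write_corpus",
    "read_anzctr_xml",
    "match_section_heading",
    "screen_missing",
    "word_count_stats",
    "DEFAULT_PLACEHOLDERS",
    "SECTION_HEADING_TERMS",
]

VALID_SOURCES = ("plos", "anzctr", "synthetic")
VALID_STUDY_TYPES = ("interventional", "observational", "unknown")

#: Heading fragments that mark a statistical-methods section.
SECTION_HEADING_TERMS = (
    "statistical analysis",
    "statistical analyses",
    "statistical method",
    "statistical methods",
    "statistics",
    "data analysis",
    "data analyses",
)

#: Section texts treated as "no methods provided". Registries accept free text,
#: so authors signal an empty section in several conventional ways.
DEFAULT_PLACEHOLDERS = ("not applicable", "nil", "none", "n/a", "")


class CorpusParseError(ValueError):
    """A record could not be parsed; the message names the offending line."""


class CorpusValidationError(ValueError):
    """A parsed record violates a corpus invariant (e.g. duplicate id)."""


@dataclass(frozen=True)
class Document:
    """One study's statistical-methods section and its metadata."""

    id: str
    raw_text: str
    source: str = "synthetic"
    heading: str = ""
    date: Optional[str] = None
    study_type: str = "unknown"
    target_sample_size: Optional[int] = None
    n_funders: Optional[int] = None

    def __post_init__(self) -> None:
        if not self.id:
            raise CorpusValidationError("Document id must be non-empty")
        if self.source not in VALID_SOURCES:
            raise CorpusValidationError(
                f"source must be one of {VALID_SOURCES}, got {self.source!r}"
            )
        if self.study_type not in VALID_STUDY_TYPES:
            raise CorpusValidationError(
                f"study_type must be one of {VALID_STUDY_TYPES}, "
                f"got {self.study_type!r}"
            )
        if self.target_sample_size is not None and self.target_sample_size <= 0:
            raise CorpusValidationError("target_sample_size must be positive")
        if self.n_funders is not None and self.n_funders < 0:
            raise CorpusValidationError("n_funders must be non-negative")

    @property
    def word_count(self) -> int:
        """Number of whitespace-delimited tokens in the raw text."""
        return len(self.raw_text.split())


@dataclass
class Corpus:
    """Ordered collection of documents with unique ids."""

    documents: list[Document] = field(default_factory=list)
    provenance: str = ""

    def __post_init__(self) -> None:
        seen: set[str] = set()
        for doc in self.documents:
            if doc.id in seen:
                raise CorpusValidationError(f"duplicate document id: {doc.id!r}")
            seen.add(doc.id)

    def __len__(self) -> int:
        return len(self.documents)

    def __iter__(self) -> Iterator[Document]:
        return iter(self.documents)

    def __getitem__(self, idx: int) -> Document:
        return self.documents[idx]

    def ids(self) -> list[str]:
        return [d.id for d in self.documents]


_OPTIONAL_INT_FIELDS = {"sample_size": "target_sample_size", "n_funders": "n_funders"}


def _document_from_record(record: dict, where: str) -> Document:
    if "id" not in record or "text" not in record:
        raise CorpusParseError(f"{where}: record must have 'id' and 'text' fields")
    kwargs: dict = {
        "id": str(record["id"]),
        "raw_text": str(record["text"]),
        "source": record.get("source") or "synthetic",
        "heading": record.get("heading") or "",
        "study_type": record.get("study_type") or "unknown",
        "date": record.get("date") or None,
    }
    for key, attr in _OPTIONAL_INT_FIELDS.items():
        value = record.get(key)
        if value is None or value == "":
            kwargs[attr] = None
        else:
            try:
                kwargs[attr] = int(value)
            except (TypeError, ValueError) as exc:
                raise CorpusParseError(f"{where}: field {key!r} is not an integer") from exc
    try:
        return Document(**kwargs)
    except CorpusValidationError as exc:
        raise CorpusValidationError(f"{where}: {exc}") from exc


def read_corpus(path, format: str = "jsonl", provenance: str = "") -> Corpus:
    """Read a corpus from a JSONL or CSV file.

    Unknown record fields are ignored; duplicate ids raise
    :class:`CorpusValidationError`; malformed records raise
    :class:`CorpusParseError` naming the line.
    """
    if format not in ("jsonl", "csv"):
        raise ValueError(f"format must be 'jsonl' or 'csv', got {format!r}")
    documents: list[Document] = []
    with open(path, "r", encoding="utf-8", newline="") as handle:
        if format == "jsonl":
            for lineno, line in enumerate(handle, start=1):
                if not line.strip():
                    continue
                try:
                    record = json.loads(line)
                except json.JSONDecodeError as exc:
                    raise CorpusParseError(f"line {lineno}: invalid JSON: {exc}") from exc
                if not isinstance(record, dict):
                    raise CorpusParseError(f"line {lineno}: record is not an object")
                documents.append(_document_from_record(record, f"line {lineno}"))
        else:
            reader = csv.DictReader(handle)
            if reader.fieldnames is None or "id" not in reader.fieldnames:
                raise CorpusParseError("line 1: CSV header with an 'id' column required")
            for record in reader:
                where = f"line {reader.line_num}"
                documents.append(_document_from_record(record, where))
    return Corpus(documents=documents, provenance=provenance or str(path))


def _document_to_record(doc: Document) -> dict:
    record = {"id": doc.id, "source": doc.source, "heading": doc.heading, "text": doc.raw_text}
    if doc.date is not None:
        record["date"] = doc.date
    if doc.study_type != "unknown":
        record["study_type"] = doc.study_type
    if doc.target_sample_size is not None:
        record["sample_size"] = doc.target_sample_size
    if doc.n_funders is not None:
        record["n_funders"] = doc.n_funders
    return record


def write_corpus(corpus: Corpus, path, format: str = "jsonl") -> None:
    """Write a corpus to JSONL or CSV; inverse of :func:`read_corpus`."""
    if format not in ("jsonl", "csv"):
        raise ValueError(f"format must be 'jsonl' or 'csv', got {format!r}")
    with open(path, "w", encoding="utf-8", newline="") as handle:
        if format == "jsonl":
            for doc in corpus:
                handle.write(json.dumps(_document_to_record(doc), sort_keys=True))
                handle.write("\n")
        else:
            columns = ["id", "source", "heading", "text", "date", "study_type",
                       "sample_size", "n_funders"]
            writer = csv.DictWriter(handle, fieldnames=columns)
            writer.writeheader()
            for doc in corpus:
                record = {c: "" for c in columns}
                record.update(_document_to_record(doc))
                writer.writerow(record)


def read_anzctr_xml(path) -> Corpus:
    """Read a minimal registry-style XML export.

    Layout: ``<studies><study><id>…</id><statistical_methods>…</statistical_methods>
    <study_type>…</study_type>…</study></studies>``. A study lacking the
    statistical-methods element yields a document with empty text.
    """
    try:
        tree = etree.parse(str(path))
    except etree.XMLSyntaxError as exc:
        raise CorpusParseError(f"not well-formed XML: {exc}") from exc
    documents = []
    for study in tree.getroot().iter("study"):
        sid = study.findtext("id", default="").strip()
        text = study.findtext("statistical_methods", default="") or ""
        study_type = (study.findtext("study_type", default="") or "").strip().lower()
        if study_type not in VALID_STUDY_TYPES:
            study_type = "unknown"
        date = (study.findtext("date", default="") or "").strip() or None
        sample = (study.findtext("sample_size", default="") or "").strip()
        funders = (study.findtext("n_funders", default="") or "").strip()
        documents.append(Document(
            id=sid,
            raw_text=text,
            source="anzctr",
            study_type=study_type,
            date=date,
            target_sample_size=int(sample) if sample else None,
            n_funders=int(funders) if funders else None,
        ))
    return Corpus(documents=documents, provenance=str(path))


def match_section_heading(heading: str) -> bool:
    """True iff the heading marks a statistical-methods section.

    Partial (substring) matching, case-insensitive, against the frequently
    used heading terms (``statistical analysis``, ``data analysis``, …).
    """
    h = heading.strip().lower()
    return any(term in h for term in SECTION_HEADING_TERMS)


def screen_missing(
    corpus: Corpus,
    placeholders: Sequence[str] = DEFAULT_PLACEHOLDERS,
) -> tuple[Corpus, Corpus]:
    """Partition a corpus into (present, missing) statistical-methods sections.

    A section is missing iff its text, lower-cased and whitespace-trimmed,
    equals one of the placeholder strings (by default "not applicable", "nil",
    "none", "n/a" or empty).
    """
    if not placeholders:
        raise ValueError("placeholders must be non-empty")
    norm = {p.strip().lower() for p in placeholders}
    present, missing = [], []
    for doc in corpus:
        (missing if doc.raw_text.strip().lower() in norm else present).append(doc)
    return (
        Corpus(documents=present, provenance=corpus.provenance),
        Corpus(documents=missing, provenance=corpus.provenance),
    )


def word_count_stats(corpus: Corpus, short_words: int = 50, long_words: int = 500) -> dict:
    """Summarise section lengths: median, quartiles, and short/long fractions.

    Counts whitespace-delimited tokens of the raw text. Quartiles use linear
    interpolation between order statistics. ``frac_short`` is the fraction of
    sections with at most ``short_words`` words; ``frac_long`` at least
    ``long_words``.
    """
    if len(corpus) == 0:
        raise ValueError("corpus is empty")
    counts = np.array([doc.word_count for doc in corpus], dtype=float)
    q1, median, q3 = np.percentile(counts, [25, 50, 75])
    return {
        "n": len(corpus),
        "median": float(median),
        "q1": float(q1),
        "q3": float(q3),
        "frac_short": float(np.mean(counts <= short_words)),
        "frac_long": float(np.mean(counts >= long_words)),
    }
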