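"""Text cleaning pipeline for statistical-methods sections.

The goal of cleaning is to standardize mathematical notation and statistical
terminology while destroying as little content as possible, so that set-based
similarity scores compare like with like. The pipeline, in order:

1. sentence segmentation on the raw text (punctuation is needed for this and
   is destroyed by later stages, so it runs first);
2. symbol-to-text conversion (``<`` → ``less-than``, ``%`` → ``percent``, …);
3. formatting removal: citation markers, equation-like lines, brackets
   (bracketed text is kept, the brackets dropped), punctuation except
   intra-word hyphens and decimal points flanked by digits, non-ASCII;
4. lower-casing and whitespace tokenization;
5. stop-word removal with a retain list (prepositions such as ``between`` and
   ``against`` change the meaning of a methods description and are kept);
6. statistical-term standardization to singular, hyphenated canonical forms
   (``chi square``, ``chisquare``, ``chi-squares`` → ``chi-square``).

The shipped symbol map, stop list and term dictionary live under
``methodsminer/data/`` and are user-replaceable.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from functools import lru_cache
from importlib import resources
from typing import Iterable, Mapping, Optional, Sequence

from .corpus_io import Corpus, Document

__all__ = [
    "SymbolMap",
    "StopList",
    "TermDictionary",
    "NormalizedDocument",
    "Normalizer",
    "convert_symbols",
    "strip_formatting",
    "split_sentences",
    "remove_stopwords",
    "standardize_terms",
    "normalize_document",
    "default_normalizer",
    "load_symbol_map",
    "load_stoplist",
    "load_term_dictionary",
]


# ---------------------------------------------------------------------------
# Resources


@dataclass(frozen=True)
class SymbolMap:
    """Mapping from symbols (``<``, ``%``, ``±`` …) to plain-text tokens.

    Multi-character symbols are replaced before their single-character
    prefixes, and no replacement value may itself contain a mapped symbol, so
    applying the map twice equals applying it once.
    """

    mapping: Mapping[str, str]

    def __post_init__(self) -> None:
        for sym, token in self.mapping.items():
            for other in self.mapping:
                if other in token:
                    raise ValueError(
                        f"symbol map not idempotent: value {token!r} for "
                        f"{sym!r} contains mapped symbol {other!r}"
                    )

    def ordered_items(self) -> list[tuple[str, str]]:
        """Items with longer symbols first (stable for equal lengths)."""
        return sorted(self.mapping.items(), key=lambda kv: -len(kv[0]))


@dataclass(frozen=True)
class StopList:
    """Stop words minus an explicit retain set."""

    stop_words: frozenset[str]
    retained: frozenset[str] = frozenset()

    def __post_init__(self) -> None:
        object.__setattr__(self, "stop_words", frozenset(self.stop_words) - frozenset(self.retained))
        object.__setattr__(self, "retained", frozenset(self.retained))

    def __contains__(self, token: str) -> bool:
        return token in self.stop_words


class TermDictionary:
    """Variant-to-canonical statistical term mapping over 1–3 token n-grams.

    Canonical forms are single (possibly hyphenated) tokens and map to
    themselves; construction verifies that re-applying the mapping to any
    canonical output is a no-op.
    """

    MAX_NGRAM = 3

    def __init__(self, variants: Mapping[str, str]):
        self._map: dict[tuple[str, ...], str] = {}
        for variant, canonical in variants.items():
            key = tuple(variant.lower().split())
            if not 1 <= len(key) <= self.MAX_NGRAM:
                raise ValueError(f"variant {variant!r} must be a 1–{self.MAX_NGRAM} token n-gram")
            if " " in canonical:
                raise ValueError(f"canonical form {canonical!r} must be a single token")
            self._map[key] = canonical.lower()
        # idempotent closure: canonicals map to themselves
        for canonical in list(self._map.values()):
            key = (canonical,)
            if self._map.get(key, canonical) != canonical:
                raise ValueError(f"canonical {canonical!r} maps elsewhere: {self._map[key]!r}")
            self._map[key] = canonical

    def lookup(self, ngram: tuple[str, ...]) -> Optional[str]:
        return self._map.get(ngram)

    def __len__(self) -> int:
        return len(self._map)

    @property
    def keys(self) -> set[tuple[str, ...]]:
        return set(self._map)


@dataclass(frozen=True)
class NormalizedDocument:
    """Cleaned, tokenized document: ordered sentences of ordered tokens."""

    id: str
    sentences: tuple[tuple[str, ...], ...]

    @property
    def tokens(self) -> tuple[str, ...]:
        return tuple(t for sent in self.sentences for t in sent)


def _read_data_lines(name: str) -> list[str]:
    text = resources.files("methodsminer.data").joinpath(name).read_text(encoding="utf-8")
    return [ln for ln in (ln.strip() for ln in text.splitlines())
            if ln and not ln.startswith("#")]


def load_symbol_map(path=None) -> SymbolMap:
    if path is not None:
        lines = [ln.strip() for ln in open(path, encoding="utf-8")
                 if ln.strip() and not ln.startswith("#")]
    else:
        lines = _read_data_lines("symbols.tsv")
    mapping = {}
    for ln in lines:
        sym, token = ln.split("\t")
        mapping[sym] = token
    return SymbolMap(mapping)


def load_stoplist(path=None, retain_path=None) -> StopList:
    if path is not None:
        words = [ln.strip().lower() for ln in open(path, encoding="utf-8")
                 if ln.strip() and not ln.startswith("#")]
    else:
        words = _read_data_lines("stopwords.txt")
    if retain_path is not None:
        retained = [ln.strip().lower() for ln in open(retain_path, encoding="utf-8")
                    if ln.strip() and not ln.startswith("#")]
    else:
        retained = _read_data_lines("retain.txt")
    return StopList(frozenset(words), frozenset(retained))


def load_term_dictionary(path=None) -> TermDictionary:
    if path is not None:
        lines = [ln.rstrip("\n") for ln in open(path, encoding="utf-8")
                 if ln.strip() and not ln.startswith("#")]
    else:
        lines = _read_data_lines("terms.tsv")
    variants = {}
    for ln in lines:
        variant, canonical = ln.split("\t")
        variants[variant] = canonical
    return TermDictionary(variants)


# ---------------------------------------------------------------------------
# Pipeline stages

_ABBREVIATIONS = {
    "e.g", "i.e", "vs", "etc", "al", "et al", "cf", "ca", "approx",
    "fig", "figs", "eq", "eqs", "ref", "refs", "dr", "inc", "vol", "st",
}

_SENTENCE_BOUNDARY = re.compile(r"([.!?]+)(\s+)(?=[A-Z0-9])")


def split_sentences(text: str) -> list[str]:
    """Split raw text into sentences.

    Boundaries are sentence-final punctuation followed by whitespace and an
    upper-case letter or digit; a short abbreviation guard (``e.g.``,
    ``et al.`` …) suppresses false splits, and decimal numbers never split
    because no whitespace follows the period.
    """
    if not text.strip():
        return []
    pieces: list[str] = []
    start = 0
    for m in _SENTENCE_BOUNDARY.finditer(text):
        head = text[start:m.end(1)]
        # last word before the punctuation, punctuation stripped
        tail = head.rstrip(".!?").rsplit(None, 1)
        last = tail[-1].lower().lstrip("([{'\"") if tail else ""
        if last in _ABBREVIATIONS or last.rstrip(".") in _ABBREVIATIONS:
            continue
        pieces.append(head)
        start = m.end()
    pieces.append(text[start:])
    return [p.strip() for p in pieces if p.strip()]


def convert_symbols(text: str, symbol_map: SymbolMap) -> str:
    """Replace mapped symbols by space-padded plain-text tokens."""
    for sym, token in symbol_map.ordered_items():
        if sym in text:
            text = text.replace(sym, f" {token} ")
    return text


_CITATION = re.compile(r"\[\s*\d+(?:\s*[,;–—-]\s*\d+)*\s*\]")
_DECIMAL_POINT = re.compile(r"(?<=[0-9])\.(?=[0-9])")
_NON_WORD = re.compile(r"[^A-Za-z0-9\s\x00-]")
_EDGE_HYPHEN = re.compile(r"(?<![A-Za-z0-9])-|-(?![A-Za-z0-9])")
_WS = re.compile(r"\s+")
_WORD = re.compile(r"[A-Za-z]{2,}")


def _drop_equation_lines(text: str) -> str:
    # a display-equation line carries no word of >=2 letters once split out
    lines = text.splitlines()
    if len(lines) <= 1:
        return text
    kept = [ln for ln in lines if not ln.strip() or _WORD.search(ln)]
    return "\n".join(kept)


def strip_formatting(text: str) -> str:
    """Remove formatting: citations, equation lines, brackets, punctuation.

    Bracketed text is retained with the brackets removed; hyphens survive only
    between alphanumerics; a period flanked by digits (``0.05``, ``5.0``) is
    preserved; all other punctuation and non-ASCII characters are dropped and
    whitespace is collapsed.
    """
    text = _drop_equation_lines(text)
    text = _CITATION.sub(" ", text)
    text = text.replace("\r", " ").replace("\n", " ")
    text = text.encode("ascii", "ignore").decode("ascii")
    text = _DECIMAL_POINT.sub("\x00", text)  # protect decimal points
    text = _NON_WORD.sub(" ", text)
    text = re.sub(r"-{2,}", " ", text)
    text = _EDGE_HYPHEN.sub(" ", text)
    text = text.replace("\x00", ".")
    return _WS.sub(" ", text).strip()


def remove_stopwords(tokens: Sequence[str], stoplist: StopList) -> list[str]:
    """Drop stop words (retained words are exempt); order preserved."""
    return [t for t in tokens if t not in stoplist]


def standardize_terms(tokens: Sequence[str], dictionary: TermDictionary) -> list[str]:
    """Longest-match left-to-right replacement of variant n-grams.

    At each position the longest (up to 3-token) n-gram present in the
    dictionary is replaced by its canonical token; output is stable under
    re-application.
    """
    out: list[str] = []
    i, n = 0, len(tokens)
    while i < n:
        for width in range(min(TermDictionary.MAX_NGRAM, n - i), 0, -1):
            canonical = dictionary.lookup(tuple(tokens[i:i + width]))
            if canonical is not None:
                out.append(canonical)
                i += width
                break
        else:
            out.append(tokens[i])
            i += 1
    return out


# ---------------------------------------------------------------------------
# Assembled pipeline


@dataclass(frozen=True)
class Normalizer:
    """The full cleaning pipeline with fixed resources."""

    symbol_map: SymbolMap
    stoplist: StopList
    dictionary: TermDictionary

    def normalize_sentence(self, sentence: str) -> tuple[str, ...]:
        text = convert_symbols(sentence, self.symbol_map)
        text = strip_formatting(text)
        tokens = text.lower().split()
        tokens = remove_stopwords(tokens, self.stoplist)
        tokens = standardize_terms(tokens, self.dictionary)
        return tuple(tokens)

    def normalize_text(self, text: str) -> tuple[tuple[str, ...], ...]:
        sentences = []
        for raw_sentence in split_sentences(text):
            tokens = self.normalize_sentence(raw_sentence)
            if tokens:
                sentences.append(tokens)
        return tuple(sentences)

    def normalize_tokens(self, text: str) -> tuple[str, ...]:
        """Normalize a short phrase (e.g. a search target) to flat tokens."""
        return tuple(t for sent in self.normalize_text(text) for t in sent)

    def __call__(self, doc: Document) -> NormalizedDocument:
        return NormalizedDocument(id=doc.id, sentences=self.normalize_text(doc.raw_text))

    def normalize_corpus(self, corpus: Corpus) -> list[NormalizedDocument]:
        return [self(doc) for doc in corpus]


def normalize_document(
    doc: Document,
    symbol_map: SymbolMap,
    stoplist: StopList,
    dictionary: TermDictionary,
) -> NormalizedDocument:
    """Run the full pipeline on one document."""
    return Normalizer(symbol_map, stoplist, dictionary)(doc)


@lru_cache(maxsize=1)
def default_normalizer() -> Normalizer:
    """Pipeline with the shipped symbol map, stop list and term dictionary."""
    return Normalizer(load_symbol_map(), load_stoplist(), load_term_dictionary())
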