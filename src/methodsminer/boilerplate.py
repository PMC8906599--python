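"""Boilerplate-text detection via asymmetric Jaccard containment.

Two pieces of tokenized text A and B are compared by the containment score
``J(A, B) = |A ∩ B| / |B|`` — the fraction of the target B's distinct tokens
found in A. Scoring relative to a target finds reused text both as a complete
sentence and embedded inside a larger one; a score of 0.9 or higher is treated
as boilerplate.

All-pairs scans over a corpus are accelerated with MinHash signatures and
banded locality-sensitive hashing (LSH): only pairs that collide in at least
one band (or, for section-level scans, share a rare token) are scored
exactly. A brute-force scanner with identical record semantics serves as the
reference oracle.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import numpy as np

from .normalize import NormalizedDocument

__all__ = [
    "TokenSet",
    "MatchRecord",
    "MinHashSignature",
    "LSHIndex",
    "TargetedSearchReport",
    "containment",
    "minhash",
    "build_token_sets",
    "pairwise_scan",
    "brute_force_scan",
    "targeted_search",
    "score_against_target",
    "DEFAULT_THRESHOLD",
    "DEFAULT_NUM_HASHES",
    "DEFAULT_BANDS",
    "DEFAULT_ROWS",
    "MIN_SENTENCE_TOKENS",
]

DEFAULT_THRESHOLD = 0.9
#: LSH defaults: 512 hashes in 64 bands of 8 rows. The collision threshold is
#: (1/b)^(1/r) ≈ 0.59 symmetric Jaccard, chosen so that pairs whose
#: containment reaches 0.9 (symmetric Jaccard ≈ 0.8 for comparable sizes)
#: collide with probability > 1 − 1e-6 per pair.
DEFAULT_NUM_HASHES = 512
DEFAULT_BANDS = 64
DEFAULT_ROWS = 8
#: Sentences shorter than this many distinct tokens are excluded from scans
#: (near-certain spurious matches).
MIN_SENTENCE_TOKENS = 3
#: Section-level scans also admit candidate pairs sharing any token whose
#: document frequency is at most this, compensating for LSH under-detection
#: of containment between very different-sized texts.
RARE_TOKEN_DF_MAX = 5

_MASK64 = np.uint64(0xFFFFFFFFFFFFFFFF)


@dataclass(frozen=True)
class TokenSet:
    """The distinct word tokens of one comparison unit (section or sentence)."""

    owner_id: str
    unit: str                     # "section" | "sentence"
    index: int                    # sentence ordinal; 0 for a section
    tokens: frozenset[str]
    sequence: tuple[str, ...] = ()  # ordered tokens, for raw-identity checks

    @property
    def cardinality(self) -> int:
        return len(self.tokens)

    @property
    def key(self) -> tuple[str, str, int]:
        return (self.owner_id, self.unit, self.index)


@dataclass(frozen=True)
class MatchRecord:
    """A scored cross-document pair at or above the boilerplate threshold."""

    query: tuple[str, str, int]
    target: tuple[str, str, int]
    score: float
    direction: str               # "query_covers_target" | "target_covers_query"
    is_boilerplate: bool
    is_exact: bool               # identical normalized token sets
    is_exact_raw: bool = False   # identical ordered token sequences (stricter)


@dataclass(frozen=True)
class MinHashSignature:
    k: int
    values: tuple[int, ...]
    seed: int


@dataclass(frozen=True)
class TargetedSearchReport:
    """Result of an n-gram targeted search against a sentence target."""

    target: tuple[str, ...]
    ngram: tuple[str, ...]
    potential_matches: int
    best_scores: dict[str, float]     # per potential-match document
    boilerplate_count: int
    median: float
    q1: float
    q3: float


def containment(A: TokenSet | frozenset[str] | set[str],
                B: TokenSet | frozenset[str] | set[str]) -> float:
    """Containment score ``|A ∩ B| / |B|`` of target B within A."""
    a = A.tokens if isinstance(A, TokenSet) else A
    b = B.tokens if isinstance(B, TokenSet) else B
    if len(b) == 0:
        raise ValueError("containment undefined for an empty target set")
    return len(a & b) / len(b)


# ---------------------------------------------------------------------------
# MinHash / LSH


def _base_hash(token: str, seed: int) -> int:
    """Deterministic, platform-independent 64-bit hash of a token string."""
    digest = hashlib.blake2b(
        token.encode("utf-8"), digest_size=8, key=seed.to_bytes(8, "little")
    ).digest()
    return int.from_bytes(digest, "little")


def _multipliers(k: int, seed: int) -> np.ndarray:
    rng = np.random.default_rng(seed)
    # odd multipliers give a permutation of Z_2^64 under multiply-shift
    a = rng.integers(1, 1 << 63, size=k, dtype=np.uint64) * np.uint64(2) + np.uint64(1)
    return a


def _signature_matrix(
    token_sets: Sequence[TokenSet], k: int, seed: int
) -> np.ndarray:
    """MinHash signatures, one row of k values per token set."""
    base_cache: dict[str, int] = {}
    a = _multipliers(k, seed)
    sig = np.empty((len(token_sets), k), dtype=np.uint64)
    for i, ts in enumerate(token_sets):
        bases = np.fromiter(
            (base_cache.setdefault(t, _base_hash(t, seed)) for t in sorted(ts.tokens)),
            dtype=np.uint64, count=len(ts.tokens),
        )
        # 64-bit multiply-shift, wrapping multiplication
        sig[i] = (bases[:, None] * a[None, :]).min(axis=0)
    return sig


def minhash(A: TokenSet, k: int = DEFAULT_NUM_HASHES, seed: int = 0) -> MinHashSignature:
    """Seeded k-permutation MinHash signature of a token set.

    The expected fraction of equal signature components between two sets is
    their symmetric Jaccard similarity.
    """
    if k < 16:
        raise ValueError("k must be >= 16")
    if len(A.tokens) == 0:
        raise ValueError("cannot MinHash an empty token set")
    sig = _signature_matrix([A], k, seed)[0]
    return MinHashSignature(k=k, values=tuple(int(v) for v in sig), seed=seed)


class LSHIndex:
    """Banded LSH over MinHash signatures: b bands of r rows, b·r = k."""

    def __init__(self, k: int = DEFAULT_NUM_HASHES, b: int = DEFAULT_BANDS,
                 r: int = DEFAULT_ROWS, seed: int = 0):
        if b * r != k:
            raise ValueError(f"bands × rows must equal k: {b}×{r} != {k}")
        self.k, self.b, self.r, self.seed = k, b, r, seed
        self.buckets: dict[tuple[int, bytes], list[int]] = {}

    def add_all(self, signatures: np.ndarray) -> None:
        view = signatures.reshape(signatures.shape[0], self.b, self.r)
        for i in range(signatures.shape[0]):
            for band in range(self.b):
                key = (band, view[i, band].tobytes())
                self.buckets.setdefault(key, []).append(i)

    def candidate_pairs(self) -> set[tuple[int, int]]:
        pairs: set[tuple[int, int]] = set()
        for members in self.buckets.values():
            if len(members) < 2:
                continue
            for x in range(len(members)):
                for y in range(x + 1, len(members)):
                    i, j = members[x], members[y]
                    pairs.add((i, j) if i < j else (j, i))
        return pairs


# ---------------------------------------------------------------------------
# Scans


def build_token_sets(
    docs: Iterable[NormalizedDocument],
    level: str,
    min_sentence_tokens: int = MIN_SENTENCE_TOKENS,
) -> list[TokenSet]:
    """Token sets for a scan: one per section, or one per eligible sentence."""
    if level not in ("section", "sentence"):
        raise ValueError("level must be 'section' or 'sentence'")
    sets: list[TokenSet] = []
    for doc in docs:
        if level == "section":
            tokens = frozenset(doc.tokens)
            if tokens:
                sets.append(TokenSet(doc.id, "section", 0, tokens, doc.tokens))
        else:
            for idx, sentence in enumerate(doc.sentences):
                tokens = frozenset(sentence)
                if len(tokens) >= min_sentence_tokens:
                    sets.append(TokenSet(doc.id, "sentence", idx, tokens, tuple(sentence)))
    return sets


def _score_pair(A: TokenSet, B: TokenSet) -> tuple[float, str]:
    forward = containment(A, B)   # A covers B
    backward = containment(B, A)  # B covers A
    if forward >= backward:
        return forward, "query_covers_target"
    return backward, "target_covers_query"


def _make_record(A: TokenSet, B: TokenSet, threshold: float) -> Optional[MatchRecord]:
    if A.key > B.key:
        A, B = B, A
    score, direction = _score_pair(A, B)
    if score < threshold:
        return None
    is_exact = A.tokens == B.tokens
    return MatchRecord(
        query=A.key, target=B.key, score=score, direction=direction,
        is_boilerplate=True, is_exact=is_exact,
        is_exact_raw=is_exact and A.sequence == B.sequence
        and len(A.sequence) > 0,
    )


def _sorted_records(records: Iterable[MatchRecord]) -> list[MatchRecord]:
    return sorted(records, key=lambda r: (r.query, r.target))


def brute_force_scan(
    token_sets: Sequence[TokenSet],
    threshold: float = DEFAULT_THRESHOLD,
) -> list[MatchRecord]:
    """Exhaustive all-pairs scan; the reference oracle for the LSH path.

    Every unordered cross-document pair is scored in both directions; a record
    is emitted when the larger direction reaches the threshold.
    """
    records = []
    n = len(token_sets)
    for i in range(n):
        for j in range(i + 1, n):
            if token_sets[i].owner_id == token_sets[j].owner_id:
                continue
            rec = _make_record(token_sets[i], token_sets[j], threshold)
            if rec is not None:
                records.append(rec)
    return _sorted_records(records)


def pairwise_scan(
    token_sets: Sequence[TokenSet],
    threshold: float = DEFAULT_THRESHOLD,
    k: int = DEFAULT_NUM_HASHES,
    b: int = DEFAULT_BANDS,
    r: int = DEFAULT_ROWS,
    seed: int = 0,
    rare_token_df_max: int = RARE_TOKEN_DF_MAX,
) -> list[MatchRecord]:
    """LSH-accelerated all-pairs scan with exact verification.

    Candidate pairs are those colliding in at least one LSH band; for
    section-level sets, pairs sharing any token of document frequency at most
    ``rare_token_df_max`` are additionally admitted. Each candidate is scored
    exactly, so the output is always a subset of :func:`brute_force_scan`.
    """
    if not token_sets:
        return []
    if any(ts.cardinality == 0 for ts in token_sets):
        raise ValueError("all token sets must be non-empty")
    signatures = _signature_matrix(token_sets, k, seed)
    index = LSHIndex(k=k, b=b, r=r, seed=seed)
    index.add_all(signatures)
    candidates = index.candidate_pairs()

    is_section = any(ts.unit == "section" for ts in token_sets)
    if is_section and rare_token_df_max > 0:
        df: dict[str, int] = {}
        for ts in token_sets:
            for t in ts.tokens:
                df[t] = df.get(t, 0) + 1
        rare_index: dict[str, list[int]] = {}
        for i, ts in enumerate(token_sets):
            for t in ts.tokens:
                if df[t] <= rare_token_df_max:
                    rare_index.setdefault(t, []).append(i)
        for members in rare_index.values():
            for x in range(len(members)):
                for y in range(x + 1, len(members)):
                    candidates.add((members[x], members[y]))

    records = []
    for i, j in sorted(candidates):
        if token_sets[i].owner_id == token_sets[j].owner_id:
            continue
        rec = _make_record(token_sets[i], token_sets[j], threshold)
        if rec is not None:
            records.append(rec)
    return _sorted_records(records)


# ---------------------------------------------------------------------------
# Targeted search


def _contains_ngram(sentence: Sequence[str], ngram: Sequence[str]) -> bool:
    n = len(ngram)
    return any(tuple(sentence[i:i + n]) == tuple(ngram)
               for i in range(len(sentence) - n + 1))


def score_against_target(
    docs: Iterable[NormalizedDocument],
    target: Sequence[str],
) -> dict[tuple[str, int], float]:
    """Containment of every sentence in the corpus against a target phrase.

    Returns ``{(doc_id, sentence_index): J(sentence, target)}``. Unlike
    :func:`targeted_search`, no n-gram gate is applied.
    """
    B = frozenset(target)
    if not B:
        raise ValueError("target must be non-empty")
    scores = {}
    for doc in docs:
        for idx, sentence in enumerate(doc.sentences):
            scores[(doc.id, idx)] = containment(frozenset(sentence), B)
    return scores


def targeted_search(
    docs: Sequence[NormalizedDocument],
    target: Sequence[str],
    threshold: float = DEFAULT_THRESHOLD,
    ngram: Optional[Sequence[str]] = None,
) -> TargetedSearchReport:
    """Targeted n-gram search scored against a full target sentence.

    ``ngram`` (default: the whole target) gates which documents are
    "potential matches": those containing it as a contiguous token run inside
    a sentence. Each potential match is then scored — the best containment of
    any of its sentences against the target's token set — and counted as
    boilerplate when that best score reaches the threshold. Median and
    quartiles summarise the per-document best scores.
    """
    target = tuple(target)
    if not target:
        raise ValueError("target must be non-empty")
    gate = tuple(ngram) if ngram is not None else target
    B = frozenset(target)
    best_scores: dict[str, float] = {}
    for doc in docs:
        if not any(_contains_ngram(s, gate) for s in doc.sentences):
            continue
        best = 0.0
        for sentence in doc.sentences:
            best = max(best, containment(frozenset(sentence), B))
        best_scores[doc.id] = best
    if best_scores:
        values = np.array(list(best_scores.values()))
        q1, median, q3 = (float(q) for q in np.percentile(values, [25, 50, 75]))
    else:
        q1 = median = q3 = float("nan")
    return TargetedSearchReport(
        target=target,
        ngram=gate,
        potential_matches=len(best_scores),
        best_scores=best_scores,
        boilerplate_count=sum(1 for s in best_scores.values() if s >= threshold),
        median=median,
        q1=q1,
        q3=q3,
    )
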