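"""Topic discovery over methods sections: tf-idf content matrix + NMF.

The corpus is represented by a term × document content matrix ``P`` under the
tf-idf weighting scheme (raw term counts times smoothed inverse document
frequency, documents scaled to unit Euclidean norm). Topics are found by
non-negative matrix factorization, ``P ≈ W Hᵀ`` with ``W`` (terms × topics)
and ``H`` (documents × topics) both non-negative, fitted by minimising the
Frobenius objective ``½‖P − WHᵀ‖²_F`` with Lee–Seung multiplicative updates.
A document's topic is the argmax of its row of ``H``; that maximum coefficient
is its topic coherence score.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import scipy.sparse as sp
from sklearn.feature_extraction.text import TfidfVectorizer

from .normalize import NormalizedDocument

__all__ = [
    "Vocabulary",
    "ContentMatrix",
    "NMFResult",
    "TopicAssignment",
    "build_tfidf",
    "fit_nmf",
    "assign_topics",
    "top_terms",
]


@dataclass(frozen=True)
class Vocabulary:
    terms: tuple[str, ...]
    doc_frequency: tuple[int, ...]

    def __len__(self) -> int:
        return len(self.terms)


@dataclass(frozen=True)
class ContentMatrix:
    """Sparse non-negative term × document matrix with labelled axes."""

    P: sp.csr_matrix
    terms: tuple[str, ...]
    doc_ids: tuple[str, ...]

    def __post_init__(self) -> None:
        if self.P.shape != (len(self.terms), len(self.doc_ids)):
            raise ValueError("matrix shape does not match labels")
        if self.P.nnz and self.P.data.min() < 0:
            raise ValueError("content matrix must be non-negative")


@dataclass(frozen=True)
class NMFResult:
    W: np.ndarray            # terms × topics
    H: np.ndarray            # documents × topics
    g: int
    objective_trace: tuple[float, ...]
    seed: int
    n_iter: int
    converged: bool
    terms: tuple[str, ...] = ()
    doc_ids: tuple[str, ...] = ()


@dataclass(frozen=True)
class TopicAssignment:
    doc_id: str
    topic: int               # 1..g, or 0 for an all-zero coefficient row
    coherence: float


def build_tfidf(
    docs: Sequence[NormalizedDocument],
    min_df: int = 2,
    max_df_fraction: float = 0.95,
) -> tuple[Vocabulary, ContentMatrix]:
    """Build the tf-idf content matrix from normalized documents.

    Entry (t, d) is ``tf(t,d) · (ln((1+N)/(1+df(t))) + 1)`` with raw counts as
    tf; document columns are scaled to unit L2 norm. Terms appearing in fewer
    than ``min_df`` documents or in more than ``max_df_fraction·N`` are
    dropped.
    """
    if not docs:
        raise ValueError("corpus is empty")
    if min_df < 1:
        raise ValueError("min_df must be >= 1")
    if not 0 < max_df_fraction <= 1:
        raise ValueError("max_df_fraction must be in (0, 1]")
    vectorizer = TfidfVectorizer(
        analyzer=lambda nd: list(nd.tokens),
        min_df=min_df,
        max_df=max_df_fraction,
        norm="l2",
        smooth_idf=True,
        sublinear_tf=False,
    )
    try:
        X = vectorizer.fit_transform(docs)  # documents × terms
    except ValueError as exc:
        raise ValueError(f"empty vocabulary after document-frequency filtering: {exc}") from exc
    terms = tuple(vectorizer.get_feature_names_out())
    if not terms:
        raise ValueError("empty vocabulary after document-frequency filtering")
    # document frequency over the retained vocabulary
    df = np.asarray((X > 0).sum(axis=0)).ravel().astype(int)
    vocab = Vocabulary(terms=terms, doc_frequency=tuple(int(x) for x in df))
    P = sp.csr_matrix(X.T)  # terms × documents
    matrix = ContentMatrix(P=P, terms=terms, doc_ids=tuple(d.id for d in docs))
    return vocab, matrix


def _objective(P: sp.csr_matrix, W: np.ndarray, H: np.ndarray, p_sq: float,
               rows: np.ndarray, cols: np.ndarray) -> float:
    # ½‖P−WHᵀ‖² = ½(‖P‖² − 2·Σ_nz P∘(WHᵀ) + tr(WᵀW·HᵀH)); only the stored
    # nonzeros of P are touched.
    cross = float(np.einsum("ij,ij->", W.T @ W, H.T @ H))
    inner = float(np.sum(P.data * np.einsum("ij,ij->i", W[rows], H[cols])))
    return 0.5 * (p_sq - 2.0 * inner + cross)


def _nndsvd_init(P: sp.csr_matrix, g: int) -> tuple[np.ndarray, np.ndarray]:
    # non-negative double SVD: split each singular pair into its positive and
    # negative parts and keep the heavier one (Boutsidis & Gallopoulos)
    U, s, Vt = np.linalg.svd(P.toarray(), full_matrices=False)
    M, N = P.shape
    W = np.zeros((M, g))
    H = np.zeros((N, g))
    W[:, 0] = np.sqrt(s[0]) * np.abs(U[:, 0])
    H[:, 0] = np.sqrt(s[0]) * np.abs(Vt[0, :])
    for j in range(1, g):
        u, v = U[:, j], Vt[j, :]
        up, un = np.maximum(u, 0), np.maximum(-u, 0)
        vp, vn = np.maximum(v, 0), np.maximum(-v, 0)
        n_up, n_vp = np.linalg.norm(up), np.linalg.norm(vp)
        n_un, n_vn = np.linalg.norm(un), np.linalg.norm(vn)
        if n_up * n_vp >= n_un * n_vn:
            sigma = n_up * n_vp
            if sigma > 0:
                W[:, j] = np.sqrt(s[j] * sigma) * up / n_up
                H[:, j] = np.sqrt(s[j] * sigma) * vp / n_vp
        else:
            sigma = n_un * n_vn
            if sigma > 0:
                W[:, j] = np.sqrt(s[j] * sigma) * un / n_un
                H[:, j] = np.sqrt(s[j] * sigma) * vn / n_vn
    # zero entries stall multiplicative updates; lift them slightly
    floor = 1e-6 * (P.data.mean() if P.nnz else 1.0)
    return np.maximum(W, floor), np.maximum(H, floor)


def fit_nmf(
    matrix: ContentMatrix,
    g: int = 10,
    seed: int = 0,
    max_iter: int = 200,
    tol: float = 1e-4,
    init: str = "random",
) -> NMFResult:
    """Fit NMF by multiplicative updates on the Frobenius objective.

    Default initialization is elementwise ``|N(0,1)|`` scaled by
    ``sqrt(mean(P)/g)``, drawn from a generator seeded by ``seed``, so fits
    are bit-reproducible; ``init="nndsvd"`` uses the deterministic SVD-based
    start instead. Iterations stop when the relative objective decrease falls
    below ``tol`` or after ``max_iter`` updates; the objective is recorded
    every iteration and is non-increasing (a property of the Lee–Seung
    updates).
    """
    P = matrix.P.tocsr()
    M, N = P.shape
    if g < 1:
        raise ValueError("g must be >= 1")
    if g > min(M, N):
        raise ValueError(f"g={g} exceeds min(M, N)={min(M, N)}")
    if max_iter < 1:
        raise ValueError("max_iter must be >= 1")
    if P.nnz and not np.all(np.isfinite(P.data)):
        raise ValueError("content matrix has non-finite entries")

    if init == "nndsvd":
        W, H = _nndsvd_init(P, g)
    elif init == "random":
        rng = np.random.default_rng(seed)
        scale = np.sqrt((P.sum() / (M * N)) / g) if P.nnz else 1.0 / g
        W = np.abs(rng.standard_normal((M, g))) * scale
        H = np.abs(rng.standard_normal((N, g))) * scale
    else:
        raise ValueError(f"unknown init {init!r}")

    eps = 1e-12
    p_sq = float(np.sum(P.data ** 2))
    coo = P.tocoo()
    rows, cols = coo.row, coo.col
    Pt = sp.csr_matrix(P.T)

    trace: list[float] = []
    prev = None
    converged = False
    n_iter = 0
    for n_iter in range(1, max_iter + 1):
        # W ← W ∘ (P H) / (W (Hᵀ H))
        W *= (P @ H) / np.maximum(W @ (H.T @ H), eps)
        # H ← H ∘ (Pᵀ W) / (H (Wᵀ W))
        H *= (Pt @ W) / np.maximum(H @ (W.T @ W), eps)
        obj = _objective(P, W, H, p_sq, rows, cols)
        trace.append(obj)
        if prev is not None and prev > 0 and (prev - obj) / prev < tol:
            converged = True
            break
        prev = obj
    return NMFResult(
        W=W, H=H, g=g, objective_trace=tuple(trace), seed=seed,
        n_iter=n_iter, converged=converged,
        terms=matrix.terms, doc_ids=matrix.doc_ids,
    )


def assign_topics(result: NMFResult) -> list[TopicAssignment]:
    """Assign each document to the topic with its maximum H coefficient.

    Topics are numbered 1..g; ties break to the lowest index; an all-zero row
    gets topic 0 ("unassigned") with coherence 0.
    """
    assignments = []
    ids = result.doc_ids or tuple(str(i) for i in range(result.H.shape[0]))
    for doc_id, row in zip(ids, result.H):
        best = int(np.argmax(row))
        coherence = float(row[best])
        if coherence == 0.0:
            assignments.append(TopicAssignment(doc_id=doc_id, topic=0, coherence=0.0))
        else:
            assignments.append(TopicAssignment(doc_id=doc_id, topic=best + 1, coherence=coherence))
    return assignments


def top_terms(result: NMFResult, topic: int, k: int = 10) -> list[tuple[str, float]]:
    """The k highest-loading terms of a topic, descending; ties lexicographic."""
    if not 1 <= topic <= result.g:
        raise ValueError(f"topic must be in 1..{result.g}")
    if k < 1:
        raise ValueError("k must be >= 1")
    terms = result.terms or tuple(str(i) for i in range(result.W.shape[0]))
    column = result.W[:, topic - 1]
    order = sorted(range(len(terms)), key=lambda i: (-column[i], terms[i]))
    return [(terms[i], float(column[i])) for i in order[:k]]
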