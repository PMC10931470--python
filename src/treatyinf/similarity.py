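"""TF-IDF vectorisation, cosine similarity, pairwise scoring and threshold selection.

The term weight is

    w(i, j) = TF(i, j) * log(N / DF_i)

with TF the *relative* frequency of term ``i`` in document ``j``
(occurrences divided by document length) and DF_i the number of documents
containing the term.  There is no smoothing: a term present in every
document has IDF exactly zero and contributes nothing to any vector.  The
logarithm base (natural log by default) only rescales all weights by one
positive constant, so every cosine score is base-invariant.

Because all weights are non-negative, cosine similarity lies in [0, 1].
Zero vectors need a convention: two documents whose restricted vectors both
vanish are treated as identical (score 1 — every shared term is maximally
common), while a zero vector against a non-zero one scores 0.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import scipy.sparse as sp

from .corpus import Corpus
from .textprep import PreprocessConfig, TokenizedDoc, preprocess_corpus

__all__ = [
    "TfidfModel",
    "TfidfVector",
    "SimilarityPairTable",
    "SimilaritySummary",
    "fit_tfidf",
    "vectorize",
    "cosine",
    "pairwise_similarities",
    "pairwise_from_docs",
    "summarize_similarities",
    "select_threshold",
    "similarity_histogram",
]


@dataclass(frozen=True)
class TfidfModel:
    """Corpus vocabulary with document frequencies.

    ``n_docs`` is the number of documents the model was fitted on; ``df``
    maps each vocabulary term (by position) to the number of documents
    containing it, so ``1 <= df[i] <= n_docs``.  ``log_base`` fixes the IDF
    logarithm; cosine scores do not depend on it.
    """

    n_docs: int
    vocabulary: tuple[str, ...]
    df: tuple[int, ...]
    log_base: float = math.e

    def __post_init__(self) -> None:
        if len(self.vocabulary) != len(set(self.vocabulary)):
            raise ValueError("vocabulary contains duplicate terms")
        if len(self.df) != len(self.vocabulary):
            raise ValueError("df and vocabulary lengths differ")
        for term, d in zip(self.vocabulary, self.df):
            if not (1 <= d <= self.n_docs):
                raise ValueError(
                    f"document frequency of {term!r} is {d}, outside [1, N={self.n_docs}]"
                )

    @property
    def index(self) -> dict[str, int]:
        return {term: i for i, term in enumerate(self.vocabulary)}

    def idf(self, term: str) -> float:
        """log(N / DF) in the model's base; 0 for terms in every document."""
        d = self.df[self.index[term]]
        return math.log(self.n_docs / d) / math.log(self.log_base)

    def with_log_base(self, base: float) -> "TfidfModel":
        if base <= 0 or base == 1:
            raise ValueError("log base must be positive and != 1")
        return TfidfModel(self.n_docs, self.vocabulary, self.df, log_base=base)

    def restrict(self, terms: Iterable[str]) -> "TfidfModel":
        """Sub-model over a chosen term subset (same N and per-term DF).

        Mirrors the in-principle exercise of comparing documents "based on
        selected terms only": weights for the kept terms are unchanged, all
        other terms are ignored at vectorisation.
        """
        keep = [t for t in self.vocabulary if t in set(terms)]
        missing = set(terms) - set(self.vocabulary)
        if missing:
            raise KeyError(f"terms not in model vocabulary: {sorted(missing)}")
        idx = self.index
        return TfidfModel(
            n_docs=self.n_docs,
            vocabulary=tuple(keep),
            df=tuple(self.df[idx[t]] for t in keep),
            log_base=self.log_base,
        )


@dataclass(frozen=True)
class TfidfVector:
    """Sparse per-document weight map over a model's vocabulary."""

    treaty_id: str
    weights: dict[str, float]
    model: TfidfModel

    @property
    def norm(self) -> float:
        return math.sqrt(sum(w * w for w in self.weights.values()))


@dataclass(frozen=True)
class SimilarityPairTable:
    """All C(N,2) pairwise cosine scores for one corpus.

    Pairs are emitted in lexicographic index order of the documents'
    positions in the corpus, so output is reproducible byte for byte.
    """

    pairs: tuple[tuple[str, str, float], ...]
    n_docs: int

    def __post_init__(self) -> None:
        object.__setattr__(self, "pairs", tuple(self.pairs))
        expected = self.n_docs * (self.n_docs - 1) // 2
        if len(self.pairs) != expected:
            raise ValueError(
                f"expected C({self.n_docs},2) = {expected} pairs, got {len(self.pairs)}"
            )

    def __len__(self) -> int:
        return len(self.pairs)

    @property
    def scores(self) -> np.ndarray:
        return np.array([score for _, _, score in self.pairs], dtype=float)


@dataclass(frozen=True)
class SimilaritySummary:
    """Descriptive statistics of a similarity-score distribution."""

    count: int
    mean: float
    std: float
    min: float
    q25: float
    median: float
    q75: float
    max: float

    def as_dict(self) -> dict[str, float]:
        return {
            "count": self.count,
            "mean": self.mean,
            "std": self.std,
            "min": self.min,
            "q25": self.q25,
            "median": self.median,
            "q75": self.q75,
            "max": self.max,
        }


def fit_tfidf(docs: Sequence[TokenizedDoc], log_base: float = math.e) -> TfidfModel:
    """Fit vocabulary and document frequencies on tokenised documents.

    DF counts document *membership* (a term repeated within one clause still
    counts once).  Vocabulary order is first-appearance order, which keeps
    vector layouts reproducible.
    """
    if not docs:
        raise ValueError("cannot fit a TF-IDF model on an empty corpus")
    vocab: dict[str, int] = {}
    for doc in docs:
        if len(doc.tokens) == 0:
            raise ValueError(
                f"document {doc.treaty_id!r} has no tokens after preprocessing"
            )
        for tok in doc.tokens:
            vocab.setdefault(tok, 0)
    for doc in docs:
        for tok in set(doc.tokens):
            vocab[tok] += 1
    return TfidfModel(
        n_docs=len(docs),
        vocabulary=tuple(vocab.keys()),
        df=tuple(vocab.values()),
        log_base=log_base,
    )


def vectorize(doc: TokenizedDoc, model: TfidfModel) -> TfidfVector:
    """TF-IDF vector of one document under a fitted model.

    TF is relative frequency over the *full* document length; terms outside
    the model vocabulary are ignored (their count still inflates the
    denominator, matching the selected-terms exercises where TF stays 1/6).
    Terms with DF = N get weight exactly 0 and are kept out of the sparse map.
    """
    if len(doc.tokens) == 0:
        raise ValueError(f"document {doc.treaty_id!r} has no tokens")
    length = len(doc.tokens)
    counts: dict[str, int] = {}
    vocab = set(model.vocabulary)
    for tok in doc.tokens:
        if tok in vocab:
            counts[tok] = counts.get(tok, 0) + 1
    weights = {}
    for term, cnt in counts.items():
        w = (cnt / length) * model.idf(term)
        if w != 0.0:
            weights[term] = w
    return TfidfVector(treaty_id=doc.treaty_id, weights=weights, model=model)


def cosine(u: TfidfVector, v: TfidfVector) -> float:
    """Cosine similarity of two vectors from the same model, in [0, 1].

    Zero-norm convention: both zero -> 1 (all their modelled terms are
    corpus-wide common, hence maximally similar); exactly one zero -> 0.
    """
    if u.model is not v.model and u.model != v.model:
        raise ValueError("cannot compare vectors built under different TF-IDF models")
    nu, nv = u.norm, v.norm
    if nu == 0.0 and nv == 0.0:
        return 1.0
    if nu == 0.0 or nv == 0.0:
        return 0.0
    small, large = (u.weights, v.weights) if len(u.weights) <= len(v.weights) else (v.weights, u.weights)
    dot = sum(w * large.get(term, 0.0) for term, w in small.items())
    return min(dot / (nu * nv), 1.0)


def pairwise_from_docs(docs: Sequence[TokenizedDoc]) -> SimilarityPairTable:
    """Exhaustive pairwise cosine scores over tokenised documents.

    Vectorised with a sparse document-term matrix; the zero-norm convention
    is applied afterwards.  Requires N >= 2.
    """
    n = len(docs)
    if n < 2:
        raise ValueError(f"need at least 2 documents for pairwise similarity, got {n}")
    model = fit_tfidf(docs)
    index = model.index
    idf = np.log(np.asarray(model.n_docs, dtype=float) / np.asarray(model.df, dtype=float))
    idf /= math.log(model.log_base)

    rows, cols, vals = [], [], []
    for i, doc in enumerate(docs):
        length = len(doc.tokens)
        counts: dict[int, int] = {}
        for tok in doc.tokens:
            j = index[tok]
            counts[j] = counts.get(j, 0) + 1
        for j, cnt in counts.items():
            rows.append(i)
            cols.append(j)
            vals.append(cnt / length)
    tf = sp.csr_matrix((vals, (rows, cols)), shape=(n, len(model.vocabulary)))
    x = tf.multiply(idf[np.newaxis, :]).tocsr()

    norms = np.sqrt(np.asarray(x.multiply(x).sum(axis=1)).ravel())
    zero = norms == 0.0
    safe = np.where(zero, 1.0, norms)
    xn = sp.diags(1.0 / safe) @ x
    sim = (xn @ xn.T).toarray()

    # zero-norm convention
    sim[zero, :] = 0.0
    sim[:, zero] = 0.0
    both = np.outer(zero, zero)
    sim[both] = 1.0

    iu, ju = np.triu_indices(n, k=1)
    scores = np.clip(sim[iu, ju], 0.0, 1.0)
    ids = [doc.treaty_id for doc in docs]
    pairs = tuple(
        (ids[i], ids[j], float(s)) for i, j, s in zip(iu.tolist(), ju.tolist(), scores.tolist())
    )
    return SimilarityPairTable(pairs=pairs, n_docs=n)


def pairwise_similarities(
    corpus: Corpus, config: PreprocessConfig | None = None
) -> SimilarityPairTable:
    """Preprocess a corpus and score every document pair (C(N,2) scores)."""
    docs = preprocess_corpus(corpus, config)
    return pairwise_from_docs(docs)


def summarize_similarities(table: SimilarityPairTable) -> SimilaritySummary:
    """Eight-number summary of the pairwise score distribution.

    Quantiles use linear interpolation; the standard deviation is the sample
    (n-1) estimate, reported as 0 for a single pair.
    """
    scores = table.scores
    if scores.size == 0:
        raise ValueError("cannot summarise an empty pair table")
    q25, med, q75 = np.quantile(scores, [0.25, 0.5, 0.75], method="linear")
    std = float(np.std(scores, ddof=1)) if scores.size > 1 else 0.0
    return SimilaritySummary(
        count=int(scores.size),
        mean=float(np.mean(scores)),
        std=std,
        min=float(np.min(scores)),
        q25=float(q25),
        median=float(med),
        q75=float(q75),
        max=float(np.max(scores)),
    )


def select_threshold(
    table: SimilarityPairTable | Sequence[float] | np.ndarray, ceiling: float
) -> float:
    """Empirical-quantile threshold: the smallest observed score ``t`` such
    that at least ``ceiling`` of all scores are <= ``t``.

    With scores 0.01, 0.02, ..., 0.90 and a 60% ceiling this returns 0.54:
    the value exceeded by at most 40% of the distribution.  ``ceiling`` must
    lie strictly inside (0, 1).  Accepts a pair table or any collection of
    scores.
    """
    if not (0.0 < ceiling < 1.0):
        raise ValueError(f"ceiling must be in (0, 1), got {ceiling}")
    raw = table.scores if isinstance(table, SimilarityPairTable) else np.asarray(table, dtype=float)
    scores = np.sort(raw)
    if scores.size == 0:
        raise ValueError("cannot select a threshold from an empty pair table")
    k = math.ceil(ceiling * scores.size)
    return float(scores[k - 1])


def similarity_histogram(
    table: SimilarityPairTable, bins: int = 20
) -> tuple[np.ndarray, np.ndarray]:
    """Histogram (bin edges, counts) of the scores over [0, 1], for export."""
    counts, edges = np.histogram(table.scores, bins=bins, range=(0.0, 1.0))
    return edges, counts
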