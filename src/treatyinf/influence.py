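"""The influence (INF) score: threshold filtering, document weighting, country aggregation.

Given the pairwise similarity table of a treaty corpus, the score is built
in three moves:

1. keep the M pairs whose similarity is at least the threshold t
   (inclusive); the retained pairs reference a multiset of 2M documents;
2. count how often each distinct document appears in that multiset and
   normalise the frequencies by 2M, giving document weights that sum to 1;
3. credit each country with the total weight of the documents it is a party
   to.

Every score lies in [0, 1].  Because each document names exactly two
distinct parties, the country scores always sum to 2 when at least one pair
is retained.  A country party only to below-threshold documents scores 0; a
hub country party to *every* retained document scores 1 — the star-network
extreme, where one state's clause text radiates through all its treaties.
"""

from __future__ import annotations

import csv
import logging
from collections import Counter
from dataclasses import dataclass
from pathlib import Path

from .corpus import Corpus
from .similarity import (
    SimilarityPairTable,
    pairwise_similarities,
    select_threshold,
)
from .textprep import PreprocessConfig

__all__ = [
    "ThresholdedPairSet",
    "DocWeightTable",
    "InfluenceTable",
    "filter_pairs",
    "doc_weights",
    "compute_inf",
    "inf_pipeline",
    "detect_star",
    "export_edgelist",
]

logger = logging.getLogger(__name__)

# Scores are rounded before comparison with t so that ties at the threshold
# do not depend on platform floating-point noise.
_SCORE_DECIMALS = 12


@dataclass(frozen=True)
class ThresholdedPairSet:
    """The M retained pairs (score >= t) and their 2M-slot document multiset."""

    threshold: float
    pairs: tuple[tuple[str, str, float], ...]

    @property
    def m(self) -> int:
        return len(self.pairs)

    @property
    def doc_multiset(self) -> Counter:
        out: Counter = Counter()
        for id_a, id_b, _ in self.pairs:
            out[id_a] += 1
            out[id_b] += 1
        return out


@dataclass(frozen=True)
class DocWeightTable:
    """Distinct retained documents with raw and normalised frequencies.

    ``entries`` holds ``(treaty_id, frequency, weight)`` with the weights
    summing to 1 (frequencies sum to 2M).  Empty when no pair survived the
    threshold.
    """

    entries: tuple[tuple[str, int, float], ...]
    m: int

    @property
    def d(self) -> int:
        return len(self.entries)

    @property
    def weights(self) -> dict[str, float]:
        return {tid: w for tid, _, w in self.entries}


@dataclass(frozen=True)
class InfluenceTable:
    """Per-country INF scores with the provenance of the run.

    ``scores`` covers every country in the corpus — countries absent from
    all retained documents are reported with 0, keeping rankings comparable
    across thresholds.  ``insufficient`` flags an M = 0 run (all-zero
    scores), the situation reported as "-" in period sweeps.
    """

    scores: dict[str, float]
    threshold: float
    m: int
    d: int
    label: str = ""
    insufficient: bool = False

    def top(self, k: int = 10) -> list[tuple[str, float]]:
        """Top-k countries by descending score, ties broken lexically."""
        ranked = sorted(self.scores.items(), key=lambda kv: (-kv[1], kv[0]))
        return ranked[:k]


def filter_pairs(table: SimilarityPairTable, t: float) -> ThresholdedPairSet:
    """Retain exactly the pairs with score >= t (inclusive); M may be 0."""
    if not (0.0 <= t <= 1.0):
        raise ValueError(f"threshold must lie in [0, 1], got {t}")
    t_r = round(t, _SCORE_DECIMALS)
    kept = tuple(
        (a, b, s) for a, b, s in table.pairs if round(s, _SCORE_DECIMALS) >= t_r
    )
    return ThresholdedPairSet(threshold=t, pairs=kept)


def doc_weights(tps: ThresholdedPairSet) -> DocWeightTable:
    """Frequency of each distinct document in the 2M multiset, normalised by 2M.

    Entries are ordered by descending frequency with lexical tie-break, so
    the table prints deterministically.  An empty pair set yields an empty
    table, consumed downstream as the "insufficient data" signal.
    """
    m = tps.m
    if m == 0:
        return DocWeightTable(entries=(), m=0)
    multiset = tps.doc_multiset
    total = 2 * m
    entries = tuple(
        (tid, freq, freq / total)
        for tid, freq in sorted(multiset.items(), key=lambda kv: (-kv[1], kv[0]))
    )
    return DocWeightTable(entries=entries, m=m)


def compute_inf(
    weights: DocWeightTable,
    corpus: Corpus,
    threshold: float | None = None,
) -> InfluenceTable:
    """Aggregate document weights into per-country INF scores.

    A country's score is the sum of the normalised weights of every retained
    document naming it as a party.  All corpus countries appear in the
    output (0 when unmatched).  An empty weight table produces an all-zero
    table flagged ``insufficient``.
    """
    scores = {country: 0.0 for country in sorted(corpus.countries)}
    by_id = {rec.treaty_id: rec for rec in corpus}
    for tid, _, w in weights.entries:
        rec = by_id.get(tid)
        if rec is None:
            raise KeyError(f"weighted document {tid!r} is not in the corpus")
        scores[rec.country_a] += w
        scores[rec.country_b] += w
    insufficient = weights.m == 0
    if insufficient:
        logger.warning(
            "no pair met the threshold (M = 0); all INF scores are 0 for corpus %r",
            corpus.label,
        )
    return InfluenceTable(
        scores=scores,
        threshold=threshold if threshold is not None else float("nan"),
        m=weights.m,
        d=weights.d,
        label=corpus.label,
        insufficient=insufficient,
    )


def inf_pipeline(
    corpus: Corpus,
    config: PreprocessConfig | None = None,
    threshold: float | None = None,
    ceiling: float | None = None,
) -> InfluenceTable:
    """Full pipeline: preprocess, score all pairs, threshold, weight, aggregate.

    Exactly one of ``threshold`` (a similarity cutoff in [0, 1]) or
    ``ceiling`` (an empirical-quantile fraction in (0, 1) from which the
    cutoff is derived retrospectively) must be given.  Requires N >= 2.
    """
    if (threshold is None) == (ceiling is None):
        raise ValueError("exactly one of threshold or ceiling must be given")
    table = pairwise_similarities(corpus, config)
    t = select_threshold(table, ceiling) if threshold is None else threshold
    tps = filter_pairs(table, t)
    wtab = doc_weights(tps)
    result = compute_inf(wtab, corpus, threshold=t)
    logger.info(
        "corpus %r: N=%d, threshold=%.6f, M=%d, D=%d",
        corpus.label, corpus.n, t, result.m, result.d,
    )
    return result


def detect_star(corpus: Corpus) -> str | None:
    """The unique country party to every treaty of the corpus, if one exists.

    Such a hub is guaranteed an INF score of 1 at any threshold that retains
    at least one pair.  Returns ``None`` when no country — or more than one,
    which can only happen for a single-record corpus — is common to all
    records.
    """
    if corpus.n == 0:
        return None
    common = set(corpus[0].parties)
    for rec in corpus:
        common &= rec.parties
    if len(common) == 1:
        return next(iter(common))
    return None


def export_edgelist(corpus: Corpus, path: str | Path) -> Path:
    """Write the treaty network as a CSV edge list.

    One edge per treaty, ``country_a,country_b,date_signed,treaty_id``, in
    corpus order — the representation behind star-network diagrams where
    each edge carries the signature date.
    """
    path = Path(path)
    with path.open("w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(["country_a", "country_b", "date_signed", "treaty_id"])
        for rec in corpus:
            writer.writerow(
                [rec.country_a, rec.country_b, rec.date_signed.isoformat(), rec.treaty_id]
            )
    return path
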