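"""Independent brute-force reference for the influence computation.

Deliberately written with plain dicts and ``math`` only — no numpy, no
sparse matrices, no code shared with the package — so it can serve as an
oracle for the vectorised implementation.  Every intermediate multiset is
materialised explicitly.
"""

import math
from collections import Counter


def oracle_tfidf_vectors(docs):
    """docs: list of (doc_id, token list) -> dict doc_id -> {term: weight}.

    w = (count/len) * ln(N/DF), DF by document membership.
    """
    n = len(docs)
    df = Counter()
    for _, tokens in docs:
        for term in set(tokens):
            df[term] += 1
    vectors = {}
    for doc_id, tokens in docs:
        counts = Counter(tokens)
        vec = {}
        for term, cnt in counts.items():
            w = (cnt / len(tokens)) * math.log(n / df[term])
            if w != 0.0:
                vec[term] = w
        vectors[doc_id] = vec
    return vectors


def oracle_cosine(u, v):
    nu = math.sqrt(sum(x * x for x in u.values()))
    nv = math.sqrt(sum(x * x for x in v.values()))
    if nu == 0.0 and nv == 0.0:
        return 1.0
    if nu == 0.0 or nv == 0.0:
        return 0.0
    dot = sum(w * v.get(t, 0.0) for t, w in u.items())
    return min(dot / (nu * nv), 1.0)


def oracle_pairwise(docs):
    """All C(N,2) scores in index order: list of (id_a, id_b, score)."""
    vectors = oracle_tfidf_vectors(docs)
    ids = [doc_id for doc_id, _ in docs]
    out = []
    for i in range(len(ids)):
        for j in range(i + 1, len(ids)):
            out.append((ids[i], ids[j], oracle_cosine(vectors[ids[i]], vectors[ids[j]])))
    return out


def oracle_inf(records, t):
    """Steps 1-4 by direct enumeration.

    records: list of (treaty_id, country_a, country_b, token list).
    Returns (scores dict over all countries, M, D).
    """
    docs = [(tid, tokens) for tid, _, _, tokens in records]
    pairs = oracle_pairwise(docs)
    retained = [
        (a, b) for a, b, s in pairs if round(s, 12) >= round(t, 12)
    ]
    m = len(retained)
    multiset = []
    for a, b in retained:
        multiset.append(a)
        multiset.append(b)
    assert len(multiset) == 2 * m
    freq = Counter(multiset)
    weights = {tid: f / (2 * m) for tid, f in freq.items()} if m else {}
    parties = {tid: (a, b) for tid, a, b, _ in records}
    scores = {}
    for tid, a, b, _ in records:
        scores.setdefault(a, 0.0)
        scores.setdefault(b, 0.0)
    for tid, w in weights.items():
        a, b = parties[tid]
        scores[a] += w
        scores[b] += w
    return scores, m, len(weights)
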