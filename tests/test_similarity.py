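import math
from collections import Counter

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

from treatyinf.similarity import (
    SimilarityPairTable,
    cosine,
    fit_tfidf,
    pairwise_from_docs,
    pairwise_similarities,
    select_threshold,
    similarity_histogram,
    summarize_similarities,
    vectorize,
)
from treatyinf.textprep import PreprocessConfig, TokenizedDoc, tokenize

from _oracle import oracle_cosine, oracle_pairwise, oracle_tfidf_vectors

D1 = TokenizedDoc("D1", tuple(tokenize("Investment agreements should protect health-related measures.")))
D2 = TokenizedDoc("D2", tuple(tokenize("Investment agreements should protect climate-related measures.")))


def make_doc(i, tokens):
    return TokenizedDoc(f"R{i:03d}", tuple(tokens))


class TestFitTfidf:
    def test_two_doc_worked_corpus(self):
        model = fit_tfidf([D1, D2])
        assert model.n_docs == 2
        assert model.df[model.index["protect"]] == 2
        assert model.df[model.index["health-related"]] == 1

    def test_single_doc_all_df_one(self):
        model = fit_tfidf([D1])
        assert set(model.df) == {1}

    def test_df_matches_membership_oracle(self, random_corpus_factory):
        corpus = random_corpus_factory(20, seed=2)
        docs = [make_doc(i, rec.clause_text.split()) for i, rec in enumerate(corpus)]
        model = fit_tfidf(docs)
        for term in model.vocabulary:
            brute = sum(1 for d in docs if term in d.tokens)
            assert model.df[model.index[term]] == brute

    def test_empty_corpus_and_empty_doc(self):
        with pytest.raises(ValueError):
            fit_tfidf([])
        with pytest.raises(ValueError, match="R007"):
            fit_tfidf([D1, TokenizedDoc("R007", ())])


class TestVectorize:
    def test_tf_protect_is_one_sixth(self):
        model = fit_tfidf([D1, D2])
        # TF alone: count/len = 1/6; with DF = N the weight collapses to 0
        vec = vectorize(D1, model)
        assert vec.weights.get("protect", 0.0) == 0.0

    def test_discriminating_term_weight(self):
        model = fit_tfidf([D1, D2])
        vec = vectorize(D1, model)
        assert vec.weights["health-related"] == pytest.approx((1 / 6) * math.log(2))

    def test_restricted_vocabulary_keeps_full_doc_length(self):
        model = fit_tfidf([D1, D2]).restrict(["health-related", "climate-related"])
        vec = vectorize(D1, model)
        # TF stays 1/6 even though only one modelled term remains
        assert vec.weights["health-related"] == pytest.approx((1 / 6) * math.log(2))

    def test_zero_length_doc_raises(self):
        model = fit_tfidf([D1])
        with pytest.raises(ValueError):
            vectorize(TokenizedDoc("X", ()), model)


class TestCosine:
    def test_disjoint_adjectives_orthogonal(self):
        model = fit_tfidf([D1, D2]).restrict(["health-related", "climate-related"])
        assert cosine(vectorize(D1, model), vectorize(D2, model)) == 0.0

    def test_shared_terms_zero_vectors_score_one(self):
        model = fit_tfidf([D1, D2]).restrict(["protect", "agreements"])
        assert cosine(vectorize(D1, model), vectorize(D2, model)) == 1.0

    def test_one_zero_vector_scores_zero(self):
        docs = [make_doc(0, ["protect", "health"]), make_doc(1, ["protect", "treaty"]),
                make_doc(2, ["protect", "protect"])]
        model = fit_tfidf(docs)
        # doc 2 only contains the corpus-wide term -> zero vector
        v2 = vectorize(docs[2], model)
        v0 = vectorize(docs[0], model)
        assert v2.norm == 0.0 and v0.norm > 0.0
        assert cosine(v2, v0) == 0.0

    def test_self_similarity_and_symmetry(self, random_corpus_factory):
        corpus = random_corpus_factory(8, seed=9)
        docs = [make_doc(i, rec.clause_text.split()) for i, rec in enumerate(corpus)]
        model = fit_tfidf(docs)
        vecs = [vectorize(d, model) for d in docs]
        for v in vecs:
            if v.norm > 0:
                assert cosine(v, v) == pytest.approx(1.0)
        for u in vecs:
            for v in vecs:
                assert cosine(u, v) == pytest.approx(cosine(v, u))

    def test_different_models_rejected(self):
        m1, m2 = fit_tfidf([D1]), fit_tfidf([D2])
        with pytest.raises(ValueError, match="models"):
            cosine(vectorize(D1, m1), vectorize(D2, m2))

    def test_log_base_invariance(self, random_corpus_factory):
        corpus = random_corpus_factory(10, seed=4)
        docs = [make_doc(i, rec.clause_text.split()) for i, rec in enumerate(corpus)]
        me = fit_tfidf(docs, log_base=math.e)
        m2 = me.with_log_base(2.0)
        m10 = me.with_log_base(10.0)
        for i in range(len(docs)):
            for j in range(i + 1, len(docs)):
                base = cosine(vectorize(docs[i], me), vectorize(docs[j], me))
                for m in (m2, m10):
                    alt = cosine(vectorize(docs[i], m), vectorize(docs[j], m))
                    assert abs(alt - base) <= 1e-12

    def test_relative_tf_equals_raw_count_cosine(self, random_corpus_factory):
        # per-document normalisation rescales each vector, leaving cosine fixed
        corpus = random_corpus_factory(10, seed=6)
        docs = [make_doc(i, rec.clause_text.split()) for i, rec in enumerate(corpus)]
        model = fit_tfidf(docs)
        n = model.n_docs

        def raw_vec(doc):
            counts = Counter(doc.tokens)
            return {
                t: c * math.log(n / model.df[model.index[t]])
                for t, c in counts.items()
                if model.df[model.index[t]] < n
            }

        for i in range(len(docs)):
            for j in range(i + 1, len(docs)):
                rel = cosine(vectorize(docs[i], model), vectorize(docs[j], model))
                raw = oracle_cosine(raw_vec(docs[i]), raw_vec(docs[j]))
                assert rel == pytest.approx(raw, abs=1e-12)


class TestPairwise:
    @pytest.mark.parametrize("n,expected", [(2, 1), (5, 10), (22, 231)])
    def test_pair_count(self, random_corpus_factory, n, expected):
        corpus = random_corpus_factory(n, seed=n)
        table = pairwise_similarities(corpus, PreprocessConfig.passthrough())
        assert len(table) == expected

    def test_single_doc_rejected(self, random_corpus_factory):
        with pytest.raises(ValueError):
            pairwise_similarities(random_corpus_factory(1, seed=0))

    def test_matches_pure_python_oracle(self, random_corpus_factory):
        for seed in range(5):
            corpus = random_corpus_factory(9, seed=seed)
            docs = [make_doc(i, rec.clause_text.split()) for i, rec in enumerate(corpus)]
            table = pairwise_from_docs(docs)
            expected = oracle_pairwise([(d.treaty_id, list(d.tokens)) for d in docs])
            assert len(table.pairs) == len(expected)
            for (a, b, s), (ea, eb, es) in zip(table.pairs, expected):
                assert (a, b) == (ea, eb)
                assert s == pytest.approx(es, abs=1e-10)

    def test_duplicate_texts_score_one(self):
        docs = [make_doc(0, ["health", "policy", "space"]),
                make_doc(1, ["health", "policy", "space"]),
                make_doc(2, ["dispute", "arbitration", "panel"])]
        table = pairwise_from_docs(docs)
        scores = {(a, b): s for a, b, s in table.pairs}
        assert scores[("R000", "R001")] == pytest.approx(1.0)

    def test_scores_in_unit_interval(self, random_corpus_factory):
        table = pairwise_similarities(random_corpus_factory(15, seed=8))
        assert np.all(table.scores >= 0.0) and np.all(table.scores <= 1.0)


class TestSummary:
    def _table(self, scores):
        # wrap raw scores in a structurally valid table: need C(n,2) == len
        n = int((1 + math.isqrt(1 + 8 * len(scores))) // 2)
        assert n * (n - 1) // 2 == len(scores), "pick a triangular count"
        pairs = tuple((f"a{k}", f"b{k}", float(s)) for k, s in enumerate(scores))
        return SimilarityPairTable(pairs=pairs, n_docs=n)

    def test_constant_scores(self):
        s = summarize_similarities(self._table([0.5] * 10))
        assert (s.mean, s.std, s.min, s.max) == (0.5, 0.0, 0.5, 0.5)

    def test_symmetric_median(self):
        s = summarize_similarities(self._table([0.0, 0.5, 1.0]))
        assert s.median == 0.5

    def test_matches_pandas_describe(self):
        rng = np.random.default_rng(12)
        scores = rng.beta(1.2, 4.0, size=1035)  # C(46,2), right-skewed
        s = summarize_similarities(self._table(list(scores)))
        ref = pd.Series(scores).describe()
        assert s.count == ref["count"]
        assert s.mean == pytest.approx(ref["mean"], abs=1e-12)
        assert s.std == pytest.approx(ref["std"], abs=1e-12)
        assert s.q25 == pytest.approx(ref["25%"], abs=1e-12)
        assert s.median == pytest.approx(ref["50%"], abs=1e-12)
        assert s.q75 == pytest.approx(ref["75%"], abs=1e-12)
        assert (s.min, s.max) == (ref["min"], ref["max"])

    def test_quantile_ordering_invariant(self):
        rng = np.random.default_rng(3)
        s = summarize_similarities(self._table(list(rng.random(45))))
        assert s.min <= s.q25 <= s.median <= s.q75 <= s.max


class TestSelectThreshold:
    def test_ninety_score_example(self):
        scores = [round(0.01 * i, 10) for i in range(1, 91)]
        assert select_threshold(scores, 0.60) == pytest.approx(0.54)

    def test_all_identical(self):
        for ceiling in (0.1, 0.5, 0.95):
            assert select_threshold([0.37] * 20, ceiling) == 0.37

    def test_matches_sort_and_index_oracle(self):
        rng = np.random.default_rng(17)
        scores = list(rng.random(500))
        for ceiling in (0.5, 0.8, 0.9, 0.95):
            t = select_threshold(scores, ceiling)
            ordered = sorted(scores)
            k = math.ceil(ceiling * len(scores))
            assert t == ordered[k - 1]
            # defining property: at least ceiling of scores are <= t, and t is minimal
            assert sum(1 for s in scores if s <= t) >= ceiling * len(scores)
            below = [s for s in ordered if s < t]
            if below:
                assert sum(1 for s in scores if s <= below[-1]) < ceiling * len(scores)

    def test_invalid_ceiling(self):
        with pytest.raises(ValueError):
            select_threshold([0.5, 0.6], 1.0)
        with pytest.raises(ValueError):
            select_threshold([0.5, 0.6], 0.0)


def test_histogram_export_covers_all_pairs(random_corpus_factory):
    table = pairwise_similarities(random_corpus_factory(12, seed=1))
    edges, counts = similarity_histogram(table, bins=10)
    assert len(edges) == 11 and counts.sum() == len(table)
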