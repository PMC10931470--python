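# Methods

## Model

The influence score treats clause dissemination as text reuse. The working
assumption is that a country matters for dissemination to the extent that
the clauses of its treaties are highly similar to other treaties' clauses:
similarity is measured pairwise, only the high-similarity tail is kept, and
each country is credited with the (normalised) frequency mass of the
retained treaties it signed.

Formally, for a corpus of N clauses: TF-IDF weights
`w(i,j) = TF(i,j) * log(N / DF_i)` with TF the within-document relative
frequency and DF document membership; cosine similarity over all C(N,2)
pairs; retention of the M pairs with score >= t (inclusive); frequencies of
the D distinct documents in the 2M retained slots, normalised by 2M; and
`INF(c)` = the sum of normalised weights of retained documents naming c as
a party.

Two consequences follow directly from the construction and are enforced as
test invariants: `INF` lies in [0, 1] for every country, and the scores sum
to exactly 2 whenever M >= 1 (each retained document carries two distinct
parties, each of which receives the document's full weight). Monotonicity
in t is *not* an invariant — raising the threshold usually concentrates
weight but can lower an individual country's score — and the test suite
exhibits a counterexample rather than asserting the tendency.

### Conventions that needed a decision

- **TF definition.** Raw occurrence counts and relative frequencies differ
  only by a per-document positive factor, which cancels in cosine
  similarity; the implementation uses relative frequency (count / document
  length) so that single-document weights match the two-sentence exercise
  (TF = 1/6), and a test verifies the cosine equivalence of the raw-count
  variant.
- **IDF logarithm base.** Natural log. Changing the base rescales every
  weight by one positive constant, so all cosine scores are base-invariant
  (tested to 1e-12). No smoothing is applied: DF = 0 cannot occur because
  the vocabulary is fitted on the corpus, and DF = N legitimately zeroes a
  term.
- **Zero-vector cosine.** Two documents whose vectors both vanish (all
  their modelled terms are corpus-wide common) score 1; a zero vector
  against a non-zero one scores 0. This is the convention under which
  documents differing only in universally shared terms count as fully
  similar.
- **Restricted vocabularies.** `TfidfModel.restrict` keeps the fitted N and
  per-term DF for a chosen term subset; document length (the TF
  denominator) still refers to the full document, so restricting the
  vocabulary never changes the weights of the kept terms.
- **Threshold comparison.** `score >= t` after rounding both sides to 12
  decimal places, so ties at the cutoff do not depend on platform
  floating-point noise.
- **Quantile threshold ("ceiling").** `select_threshold` returns the
  smallest *observed* score t such that at least `ceiling * count` scores
  are <= t — an order statistic, not an interpolated quantile — because the
  cutoff must be a value the data can actually attain (90 evenly spaced
  scores at a 60% ceiling give 0.54). The descriptive summary, by contrast,
  uses linearly interpolated quantiles and the sample (n-1) standard
  deviation, reported as 0 for a single pair.
- **M = 0.** An empty retained set produces an all-zero influence table
  flagged `insufficient` (and a logged warning) instead of an exception, so
  that category/decade sweeps can report "insufficient data" cells and
  continue. Countries appearing only in unretained treaties are reported
  with 0 rather than omitted, keeping rankings comparable across runs.
- **Tie-breaks and ordering.** Pairs are emitted in lexicographic index
  order of corpus position; report rows sort by descending score with
  lexical tie-break; document-weight entries by descending frequency then
  id. All outputs are byte-reproducible for fixed inputs.

## Preprocessing

Tokenisation keeps hyphenated compounds as single tokens (clause vocabulary
is dense in forms like "health-related"; splitting them would distort term
frequencies) and drops all other punctuation. The default stop list is
scikit-learn's standard English list; it can be replaced by a
one-token-per-line file. Reduction is pluggable: `none`, a hand-written
classic Porter stemmer, or a light rule-based lemmatizer (regular plural
and -ing/-ed inflections with spelling repair, e.g. "caring" -> "care",
plus a small irregular table). No installed NLP toolkit provides these in
this environment, so they are implemented here; different
stemmers/lemmatizers legitimately disagree on individual words, which is
why all exact numeric checks run under the pass-through configuration
(lower-cased tokenisation only). The pass-through configuration is also the
only one under which the two-sentence exercise is reproducible, since
auxiliary words such as "should" are counted among each sentence's six
words but sit on every standard stop list.

## Synthetic corpora

Real treaty databases (EDIT, UNCTAD) are not redistributable, so testing
rests on generated corpora that emulate the structural features the score
is sensitive to, with a known ground truth:

- **Star corpora** (`generate_star_corpus`): one hub country in every
  treaty, one base clause, optional per-token mutation. At mutation 0 all
  pairwise similarities are 1 and the hub's score is provably 1 at any
  threshold — the analytic extreme used as an end-to-end check.
- **Diffusion corpora** (`generate_diffusion_corpus`): treaties generated
  in date order; with probability `copy_prob` a treaty involves the hub and
  copies the clause of a uniformly chosen earlier hub treaty, mutated at a
  per-token substitution rate; otherwise it links two non-hub countries
  with a clause from one of `n_templates` base templates. Templates draw on
  disjoint vocabulary subsets whenever the subsets fit side by side in the
  closed ~60-term vocabulary, so unrelated clauses share little text and
  the pairwise-similarity distribution is right-skewed (median < mean),
  matching the shape real clause corpora exhibit. Defaults — 60 treaties
  over 1960–2019, 30 countries, copy_prob 0.8, mutation rate 0.05, 20%
  multi-label treaties weighted 0.6/0.3/0.1 across
  defensive/neutral/offensive — describe a mid-sized corpus with a clear
  planted originator and were fixed once as the package's study conditions.
  All randomness flows from a single integer seed.

What the generator does *not* emulate: legal language (clauses are token
bags from a closed vocabulary, so word-order effects are absent — irrelevant
to a bag-of-words score), realistic country-pair network structure, secular
drift in clause wording, or the empirical calibration of any real corpus's
similarity distribution beyond its qualitative right skew. Passing tests
therefore demonstrate correctness of the computation and recoverability of
a planted diffusion structure, not findings about any real treaty corpus.

## Verification strategy

Every pipeline stage is checked against an independent pure-Python
brute-force reference (`tests/_oracle.py`, plain dicts and `math` only)
that materialises each intermediate multiset explicitly; the equivalence
suite runs 200 random corpora of 3–10 treaties across four thresholds.
Distribution summaries are cross-checked against `pandas.Series.describe`,
threshold selection against a sort-and-index oracle, and hub recovery is a
statistical check: over 20 seeds at copy_prob 0.9 and mutation 0.1 the
planted hub must top the ranking in at least 90% of runs. Problem sizes
(corpora of 3–60 treaties; one 419-document corpus exercising the C(N,2)
pair-count arithmetic) keep the full suite under a few seconds while
covering every code path.

## Limitations

Bag-of-words TF-IDF ignores word order and semantics, is sensitive to
clause length, and treats near-synonymous legal formulations as distinct;
embedding-based similarity is out of scope. The score attributes influence
symmetrically to both parties of a treaty and cannot distinguish originator
from adopter within a dyad. Threshold choice remains the analyst's: the
ceiling rule makes it reproducible, not canonical — low ceilings blur large
gaps in the retained tail (a 0.54 cutoff groups pairs at 0.54 and 0.90),
high ceilings zero out most countries.
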