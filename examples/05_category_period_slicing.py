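"""Contextual influence: slicing the corpus by safeguard category and decade.

Multiclass treaties count in each of their classes, so per-category record
counts can sum to more than N.  Period bounds are inclusive calendar years.
"""

from treatyinf import SynthParams, filter_corpus, generate_diffusion_corpus, inf_pipeline

corpus, hub = generate_diffusion_corpus(SynthParams(seed=9))
print(f"{corpus.n} treaties; per-category counts:")
for cat in ("defensive", "neutral", "offensive"):
    print(f"  {cat:10s} {filter_corpus(corpus, category=cat).n}")

for start in range(1960, 2020, 10):
    decade = filter_corpus(corpus, category="defensive", period=(start, start + 9))
    if decade.n < 2:
        print(f"{start}s: -  (insufficient data, {decade.n} treaty/ies)")
        continue
    result = inf_pipeline(decade, threshold=0.8)
    if result.insufficient:
        print(f"{start}s: -  (no pair above threshold among {decade.n} treaties)")
        continue
    country, score = result.top(1)[0]
    print(f"{start}s: {country} ({score:.4f}) from {decade.n} defensive treaties")
# The leading country can differ by decade even with one planted hub,
# because the retained high-similarity pairs shift with the time slice.
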