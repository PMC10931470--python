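"""Retrospective threshold selection from the similarity distribution.

The cutoff t is chosen as an empirical quantile ("ceiling") of all pairwise
scores: the smallest observed score that at least the given fraction of
scores do not exceed.
"""

from treatyinf import (
    SynthParams,
    generate_diffusion_corpus,
    pairwise_similarities,
    select_threshold,
    summarize_similarities,
)

# The schematic 90-score exercise: scores 0.01, 0.02, ..., 0.90.
scores = [round(0.01 * i, 10) for i in range(1, 91)]
t = select_threshold(scores, ceiling=0.60)
print(f"90 evenly spaced scores, 60% ceiling -> t = {t}")
# 0.54: 60% of the scores are <= 0.54; note the pair at 0.90 lands in the
# same retained group, which is why low ceilings blur large similarity gaps.

# On a generated corpus the same rule adapts to the observed distribution.
corpus, _ = generate_diffusion_corpus(SynthParams(seed=3))
table = pairwise_similarities(corpus)
s = summarize_similarities(table)
print(f"synthetic corpus: {s.count} pairs, mean={s.mean:.3f}, "
      f"median={s.median:.3f} (right-skewed tail up to {s.max:.3f})")
for ceiling in (0.80, 0.90, 0.95):
    print(f"  ceiling {ceiling:.2f} -> t = {select_threshold(table, ceiling):.4f}")
# Higher ceilings keep only the near-duplicate tail of treaty pairs.
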