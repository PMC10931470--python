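"""Star topology: a hub country party to every treaty scores INF = 1.

Generates six treaties all involving Brazil with identical clause text, runs
the full pipeline at several thresholds, and exports the network edge list.
"""

from pathlib import Path

from treatyinf import detect_star, export_edgelist, generate_star_corpus, inf_pipeline

corpus = generate_star_corpus("Brazil", n_leaves=6, mutation_rate=0.0, seed=1)
print("hub detected:", detect_star(corpus))

for t in (0.1, 0.5, 0.9, 0.99):
    result = inf_pipeline(corpus, threshold=t)
    print(f"t={t:4}: M={result.m:2d} retained pairs, D={result.d}, "
          f"INF(Brazil)={result.scores['Brazil']:.4f}")
# Every clause is identical, so all 15 pairs score 1 and survive any
# threshold; Brazil is a party to every retained treaty and collects the
# whole weight mass of its side: INF = 1 regardless of t.

out = Path("scratch") if Path("scratch").is_dir() else Path(".")
path = export_edgelist(corpus, out / "star_edges.csv")
print("edge list written to", path)
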