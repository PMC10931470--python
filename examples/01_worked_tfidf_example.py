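"""Two-sentence TF-IDF exercise: why corpus-wide terms carry no weight.

Builds a two-document corpus, computes the weight of a term present in both
documents, and compares the documents on restricted vocabularies.
"""

from treatyinf import PreprocessConfig, TokenizedDoc, cosine, fit_tfidf, preprocess, vectorize

D1 = "Investment agreements should protect health-related measures."
D2 = "Investment agreements should protect climate-related measures."

cfg = PreprocessConfig.passthrough()  # keep all six words of each sentence
d1 = TokenizedDoc("D1", tuple(preprocess(D1, cfg)))
d2 = TokenizedDoc("D2", tuple(preprocess(D2, cfg)))
model = fit_tfidf([d1, d2])

tf = d1.tokens.count("protect") / len(d1.tokens)
w = vectorize(d1, model).weights.get("protect", 0.0)
print(f"TF('protect', D1) = {tf:.3f}")   # 1 occurrence among 6 words
print(f"w('protect', D1)  = {w:.3f}")    # DF = N = 2 -> IDF = log(1) = 0

adjectives = model.restrict(["health-related", "climate-related"])
print("cosine on the two adjectives:",
      cosine(vectorize(d1, adjectives), vectorize(d2, adjectives)))
# 0.0 — each adjective appears in only one document, the vectors are orthogonal

shared = model.restrict(["protect", "agreements"])
print("cosine on the two shared terms:",
      cosine(vectorize(d1, shared), vectorize(d2, shared)))
# 1.0 — both restricted vectors vanish (IDF = 0), and documents that differ
# only in corpus-wide common terms are treated as fully similar
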