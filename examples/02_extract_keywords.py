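"""Rank keywords by TF-IDF and narrow the top-100 to a top-20 table.

Each word's per-document term frequency is weighted by ln(D/(1+df)) and
summed over posts; the top table renormalizes scores to shares of the
table mass — the quantity the concern profiles are built from.
"""

from opinionflow import GeneratorConfig, generate_corpus, tfidf_scores, top_keywords

corpus = generate_corpus(
    GeneratorConfig(
        event_name="transit_accident",
        n_docs=716,
        dimension_weights=(0.6, 0.2, 0.1, 0.1),
        seed=1,
    )
)
stats = tfidf_scores(corpus)
top100 = top_keywords(stats, 100)
top20 = top_keywords(stats, 20, previous=top100)

print("rank  token      score   share   docs")
for rank, entry in enumerate(top20.entries[:8], start=1):
    df = stats.loc[entry.token, "df"]
    print(f"{rank:>4}  {entry.token:<9} {entry.score:6.3f}  {entry.share:.3f}  {df:>5}")
print("...")
print(
    f"top-20 shares sum to {sum(e.share for e in top20.entries):.3f}; a token's\n"
    "share is its fraction of the table's total TF-IDF mass. Prefixes (od_,\n"
    "de_, pp_, pe_) reveal each keyword's true dimension in synthetic data."
)
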