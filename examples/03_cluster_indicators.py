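"""Cluster the top-100 keywords and map clusters to concern dimensions.

Keywords are embedded as L2-normalized per-document TF-IDF profiles and
grouped by K-means (k = number of lexicon indicators); each cluster is
labelled by the seed-lexicon indicator it overlaps most.  On well-separated
synthetic data the clusters recover the generator's dimensions.
"""

from opinionflow import (
    GeneratorConfig,
    assign_clusters_to_indicators,
    build_word_vectors,
    generate_corpus,
    kmeans,
    synthetic_lexicon,
    tfidf_scores,
    top_keywords,
)

corpus = generate_corpus(
    GeneratorConfig(
        event_name="transit_accident",
        n_docs=1000,
        dimension_weights=(0.6, 0.2, 0.1, 0.1),
        separation=0.95,
        seed=1,
    )
)
table = top_keywords(tfidf_scores(corpus), 100)
vectors = build_word_vectors(corpus, table)
lexicon = synthetic_lexicon(corpus)
result = kmeans(vectors, k=lexicon.n_indicators, seed=0)
mapping = assign_clusters_to_indicators(result, lexicon)

print(f"K-means: k={result.k}, J={result.loss:.3f}, {result.n_iterations} iterations")
for cluster, members in result.clusters().items():
    dim, indicator = mapping[cluster]
    print(f"  cluster {cluster} -> {dim}/{indicator}: {len(members)} keywords, "
          f"e.g. {', '.join(members[:4])}")

labelled = [t for t in table.tokens if t in corpus.truth]
tmap = {t: mapping[int(c)][0] for t, c in zip(result.tokens, result.assignments)}
acc = sum(tmap[t] == corpus.truth[t] for t in labelled) / len(labelled)
print(f"{acc:.1%} of labelled keywords were clustered into their true dimension.")
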