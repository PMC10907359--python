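"""Generate a synthetic event corpus and inspect its composition.

Builds a 716-post corpus (the size of the study's first transit-accident
crawl) whose posts mix the four concern dimensions 60/20/10/10, then counts
where tokens actually came from.
"""

from collections import Counter

from opinionflow import GeneratorConfig, generate_corpus

config = GeneratorConfig(
    event_name="transit_accident",
    n_docs=716,
    dimension_weights=(0.6, 0.2, 0.1, 0.1),
    separation=0.95,
    seed=1,
)
corpus = generate_corpus(config)

origins = Counter(
    corpus.truth.get(tok, "background")
    for doc in corpus.documents
    for tok in doc.tokens
)
total = sum(origins.values())

print(f"{len(corpus)} documents, {len(corpus.vocabulary)} distinct tokens")
print("first post:", " ".join(corpus.documents[0].tokens[:8]), "...")
for name, count in origins.most_common():
    print(f"  {name:<20} {count / total:.3f} of tokens")
print(
    "Token shares track separation * dimension_weights (0.57/0.19/0.095/0.095)\n"
    "with the remaining 5% drawn from the shared background vocabulary."
)
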