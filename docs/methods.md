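# Methods

This note documents the models implemented in `opinionflow`, the choices
made where the design was genuinely open, and what the synthetic-data
results do and do not establish.

## Synthetic corpus model

Each event corpus is a bag-of-tokens mixture model.  A post's dimension
mixture `θ ~ Dirichlet(c · w)` is centred on the event-level weights `w`
(a probability vector over the four concern dimensions) with concentration
`c`; each token is drawn from the sampled dimension's vocabulary with
probability `s` (the *separation*) and from a shared background vocabulary
otherwise.  Within every vocabulary, token probabilities follow a Zipf law
`p_r ∝ r^{-1.1}`, so a few head words dominate — matching the heavily
skewed top-keyword share profiles seen on real platforms, where a single
word can carry ~0.5 of the top-20 mass.  Post length is
`Poisson(doc_length_mean)` truncated below at 3 tokens.

Defaults and why:

| parameter | default | rationale |
|---|---|---|
| `separation` | 0.95 | on-topic crawls are dominated by event-relevant terms; 5% background noise |
| `concentration` | 0.5 | short posts are topically focussed: a sub-1 concentration makes most posts near-single-dimension while the *event-level* mixture still equals `w`; with a large concentration every post blends all four dimensions and no clustering method could separate them, which would contradict what the separation knob is meant to control |
| `doc_length_mean` | 20 | typical short-post token count after segmentation and stop-word removal |
| `vocab_sizes` | 250/dimension | enough tail for realistic Zipf decay while keeping df spectra informative at 10²–10³ posts |
| `background_vocab_size` | 500 | function words/platform boilerplate outnumber topical terms |
| `n_docs` | per event | the seven default crawl sizes (716, 381, 1844, 1013, 1126, 1841, 622) mirror the case study's collection |

The generator emits a token → dimension ground-truth map used only for
evaluation.  What it does **not** emulate: word order and syntax, token
ambiguity (every synthetic token belongs to exactly one dimension, whereas
real words like "death" straddle dimensions), temporal drift within a
crawl, platform-specific style, and correlated document lengths.  Passing
recovery tests therefore show the *pipeline machinery* is correct and
statistically consistent under the stated generative assumptions — not that
the four dimensions are recoverable from arbitrary real text.

## TF–IDF

Within-document frequency is `IF_i = f_i / Σ f_i` (sums to 1 per post).
The default IDF is the standard smoothed form `ln(D / (1 + df_i))`: it is
the unique reading consistent with the requirement that the more common a
word, the closer its IDF to 0.  A `literal` mode evaluates the
alternative form `ln(df_i / (Σ df + 1))` for audit; it is not anti-monotone
in df and is not used by the pipeline.  Natural log throughout (the base
only rescales rankings).  Negative IDF values (df + 1 > D) are kept, not
clipped.  Corpus-level scores aggregate per-document `IF · IDF` by sum;
keyword tables take the K highest scores with lexicographic tie-breaks and
renormalize scores to shares of the table mass.

## K-means indicator construction

Keywords are embedded as their per-document TF–IDF profiles (one coordinate
per post), L2-normalized by default so cosine-like geometry drives the
clustering.  Lloyd's algorithm runs from k-means++ seeding with 10 restarts
(best loss kept), `tol = 1e-8` on ΔJ, `max_iter = 300`; empty clusters are
re-seeded with the globally farthest point; the loss history is checked to
be non-increasing on every run and final labels are nearest-centroid
consistent.  `k` defaults to the number of indicators in the active
lexicon.  Cluster → indicator assignment maximizes seed-word overlap, with
ties broken by lexicon order and zero-overlap clusters labelled
"unassigned".

## Satisfaction statistics

Satisfaction is defined as the original-event share of the assigned
top-keyword mass.  Three estimators of that share are provided:

- `original_share` — the TF–IDF share mass itself (the function-level
  default, and the direct reading of a concern profile);
- `frequency` — raw occurrence counts of the assigned keywords;
- `balanced_depth` — the pipeline default: counts compared at equal
  keyword depth per dimension (each assigned dimension contributes its
  `n*` most frequent table keywords, `n*` = the smallest per-dimension
  keyword count), in the spirit of rarefaction in ecology.

The rarefied estimator exists because the other two are biased on skewed
vocabularies.  TF–IDF shares penalize dominant dimensions (their head words
appear in most posts, so IDF collapses), and a top-K table covers a larger
fraction of a dominant dimension's Zipf mass than of a minor one's, which
inflates raw frequency shares.  Measured on synthetic corpora at separation
0.95, the score-share estimator misses a configured weight of 0.6 by ≈0.06–
0.09, while the balanced-depth estimator is unbiased to within sampling
noise (≤0.03 across weights 0.29–0.73); its cancellation argument assumes
the dimensions share a common frequency-rank shape, which Zipf universality
makes a mild assumption for real vocabularies too.  Opinion states
discretize satisfaction at thresholds (0.4, 0.6), chosen symmetric around
neutrality; both thresholds and statistic are run configuration.

## The consensus hidden Markov model

`φ = (A, B, π)` with hidden policy-intent states Q = (Continue=1, Change=0)
and opinion observations P = (Support=1, Neutral=0.5, Opposed=0).  The
case-study parameterization is `π = (1, 0)`,
`A = ((0.7, 0.3), (0.3, 0.7))`, `B = ((0.6, 0.3, 0.1), (0.1, 0.3, 0.6))`.
Useful closed forms: `E[o_1] = 0.75`; the symmetric A has stationary
distribution (0.5, 0.5), hence a long-run mean observation of
`0.5·0.75 + 0.5·0.25 = 0.5` — a 50% support rate.

- **Sampling** uses inverse-CDF draws from precomputed row CDFs; ensembles
  (default 10 runs, the case study's convention) derive per-run seeds
  deterministically from a master seed and average numeric observation
  values and state codes per time step.
- **Filtering** is the scaled forward recursion; posteriors are normalized
  each step and the log-likelihood accumulates the scale factors.  Results
  are verified against exhaustive path enumeration for T ≤ 8 (1e-10) and
  against an external HMM library's likelihood.
- **Estimation** is Baum–Welch EM, vectorized across sequences of equal
  length; the total log-likelihood is asserted non-decreasing (1e-9) every
  iteration, and an initial emission matrix that gives an observed symbol
  zero mass in every state is rejected up front.  Label switching is
  resolved by ordering states by Support-emission probability (highest →
  Continue).  The unsupervised entry point runs 10 Dirichlet-random
  restarts and keeps the best likelihood.  `tol = 1e-6` on Δlog-likelihood
  (absolute, on the total over all sequences) with `max_iter = 200` by
  default; EM's terminal crawl means convergence to `1e-6` may use the full
  budget while parameters have long stopped moving at the 1e-3 level.

## Pipeline and reproducibility

The end-to-end run validates the whole configuration before any stage
executes, then writes every intermediate artifact (corpora as JSONL with a
ground-truth sidecar, keyword tables and cluster maps as CSV, the opinion
sequence and model spec as JSON) plus a manifest of SHA-256 file hashes.
A single master seed deterministically spawns per-checkpoint generator
seeds and the clustering/simulation seeds, so identical configurations
reproduce every artifact byte for byte.  Stage failures abort with the
stage name; completed artifacts are retained.

Default problem sizes (four checkpoints of 622–1844 posts, top-100 tables,
2000-post recovery corpora, 100×1000-step simulation ensembles, 200×100
estimation sequences) were chosen as the smallest sizes at which the
statistical claims are comfortably resolvable — e.g. the Monte-Carlo
standard error of the long-run support rate at 100×1000 samples is ≈0.1
percentage points against a ±1-point claim.

## Known limitations

- Tokens are atomic and unambiguous; no real segmentation ships in-core
  (any callable text → tokens can be plugged in as segmenter).
- The satisfaction → support-percentage mapping of real platforms is
  unidentifiable from keyword shares alone; the statistic here is a defined
  convention, validated only against the generator's ground truth.
- Clustering is hard-assignment K-means on TF–IDF geometry; polysemous
  keywords that genuinely belong to two dimensions will be forced into one.
- The consensus model's states and alphabet are fixed at 2×3 in the
  unsupervised fitting entry point; the underlying EM handles arbitrary
  discrete HMMs but the package's labelling conventions assume the
  opinion-policy structure.
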