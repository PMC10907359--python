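# opinionflow

Public-opinion-to-policy analysis for long-running public-safety events.

During a protracted emergency (an epidemic, say), the public discusses the
original event, the derived events it spawns (accidents, fires), what they
predict policy will do and what they expect it to do.  `opinionflow`
implements, as a tested and reusable pipeline, the analysis chain that turns
a stream of short social-media posts into a policy-feedback signal:

1. **Keyword extraction** — per-word salience by TF–IDF:
   `IF_i = f_i / Σ f_i` within a post, `IDF_i = ln(D / (1 + df_i))` over the
   corpus, score `(TF–IDF)_i = Σ_docs IF_i · IDF_i`; top-100 and top-20
   keyword tables with normalized shares.
2. **Indicator construction** — K-means clustering (Lloyd's algorithm
   minimizing `J(c,p) = Σ_i ‖x_i − p_{c_i}‖²`) of keywords embedded as
   per-document TF–IDF profiles, with clusters labelled by a two-level seed
   lexicon (dimension → indicator → seed words) covering four concern
   dimensions: original event, derived event, public prediction, public
   expectation.
3. **Concern & satisfaction** — dimension-level shares of the top-keyword
   mass; the original-event share is read as satisfaction with current
   policy and discretized into support (1) / neutral (0.5) / oppose (0).
4. **Consensus model** — a discrete hidden Markov model `φ = (A, B, π)`
   whose hidden state is the agency's policy intent (Continue=1, Change=0)
   and whose observations are the opinion states: trajectory sampling with
   ensemble averaging, scaled forward filtering of the policy-intent
   posterior, and Baum–Welch parameter estimation.

Because real platform crawls are not redistributable, the package includes a
first-class synthetic corpus generator (Dirichlet-mixed, Zipf-weighted
dimension vocabularies with ground truth) so every stage is testable and
every claimed recovery is measurable.

Intended users: computational social scientists and infodemiology /
risk-communication researchers who want a reproducible reference
implementation of this analysis pattern, or a harness to evaluate variants
of it.

## Worked example

```bash
python examples/05_consensus_simulation.py
```

prints, among other lines:

```
closed form: E[o_1] = 0.75, stationary state distribution = [0.5 0.5]
10-run averages over 4 checkpoints:
  mean opinion: [0.85 0.65 0.5  0.5 ]
long-run support rate: 50.13%
P(policy intent = Continue | opinions so far): [1.    0.28  0.105 0.08 ]
```

Starting from certain policy continuation, the expected first opinion value
is 0.75 (leaning support); because the transition matrix is symmetric the
chain spends half its time in each regime, so the long-run mean opinion —
the support rate — converges to 50%, a neutral synthesis.  Feeding the
filter one support observation followed by three oppositions drives the
posterior probability of "Continue" from 1.0 down to 0.08: sustained
negative opinion is what pushes the agency toward a policy change.

The full loop (`python examples/06_full_pipeline.py`) generates four
chronological event checkpoints with original-event weights 0.73 / 0.37 /
0.35 / 0.29, and the pipeline recovers satisfaction rates 0.740 / 0.358 /
0.360 / 0.311 — opinion states (support, oppose, oppose, oppose).

A thin CLI mirrors the library (`opinionflow generate | keywords | cluster
| concern | simulate | fit | run-all`); see `opinionflow --help`.

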