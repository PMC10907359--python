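"""Independent reference implementations used as test oracles.

These are deliberately naive (double loops, exhaustive enumeration) and
share no code with the package internals they check.
"""

from __future__ import annotations

import itertools
import math

import numpy as np


def naive_tfidf(docs: list[list[str]]) -> dict[str, float]:
    """Corpus TF-IDF scores by direct double loop over documents and tokens."""
    n_docs = len(docs)
    vocab = sorted({t for d in docs for t in d})
    df = {t: sum(1 for d in docs if t in d) for t in vocab}
    scores = {t: 0.0 for t in vocab}
    for doc in docs:
        for t in vocab:
            f = sum(1 for x in doc if x == t)
            if f:
                tf = f / len(doc)
                idf = math.log(n_docs / (1 + df[t]))
                scores[t] += tf * idf
    return scores


def exhaustive_kmeans(points: np.ndarray, k: int) -> float:
    """Optimal K-means loss by enumerating every surjective assignment."""
    points = np.asarray(points, dtype=float)
    if points.ndim == 1:
        points = points[:, None]
    n = len(points)
    best = np.inf
    for assign in itertools.product(range(k), repeat=n):
        if len(set(assign)) < k:
            continue
        loss = 0.0
        a = np.array(assign)
        for c in range(k):
            cluster = points[a == c]
            loss += ((cluster - cluster.mean(axis=0)) ** 2).sum()
        best = min(best, loss)
    return best


def brute_force_filter(pi, A, B, obs: list[int]) -> np.ndarray:
    """Filtering posteriors by enumerating all hidden paths (unscaled)."""
    pi, A, B = np.asarray(pi), np.asarray(A), np.asarray(B)
    n = len(pi)
    posteriors = []
    for t in range(1, len(obs) + 1):
        prefix = obs[:t]
        marg = np.zeros(n)
        for path in itertools.product(range(n), repeat=t):
            p = pi[path[0]] * B[path[0], prefix[0]]
            for s in range(1, t):
                p *= A[path[s - 1], path[s]] * B[path[s], prefix[s]]
            marg[path[-1]] += p
        posteriors.append(marg / marg.sum())
    return np.array(posteriors)
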