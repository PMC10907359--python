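"""K-means clustering of keywords into a dimension/indicator system.

Each top-ranked keyword is represented by its per-document TF-IDF profile
(one coordinate per document, optionally L2-normalized); words that are
salient in the same posts end up close in this space.  Lloyd's algorithm
minimizes the within-cluster sum of squared Euclidean distances

    J(c, p) = sum_i || x_i - p_{c_i} ||^2

and clusters are then labelled by the indicator of a seed lexicon (a
two-level hierarchy dimension -> indicator -> seed words) whose seed words
they overlap most.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .corpus import DIMENSIONS, Corpus
from .tfidf import KeywordTable, inverse_document_frequency, term_frequency

__all__ = [
    "WordVectorSet",
    "ClusteringResult",
    "DimensionLexicon",
    "build_word_vectors",
    "kmeans",
    "assign_clusters_to_indicators",
    "default_lexicon",
    "synthetic_lexicon",
]


@dataclass
class WordVectorSet:
    """TF-IDF word vectors: one row per token, one column per document."""

    tokens: list[str]
    matrix: np.ndarray  # shape (n_tokens, n_docs)
    normalized: bool = False

    def __post_init__(self) -> None:
        if len(self.tokens) != self.matrix.shape[0]:
            raise ValueError("one vector per token required")


@dataclass
class ClusteringResult:
    """Outcome of one K-means run (best of the restarts)."""

    k: int
    assignments: np.ndarray  # cluster index in 0..k-1 per point
    centroids: np.ndarray
    loss: float  # J = sum of squared distances to assigned centroids
    n_iterations: int
    seed: int
    loss_history: list[float] = field(default_factory=list)
    tokens: list[str] | None = None

    def clusters(self) -> dict[int, list[str]]:
        """Token membership per cluster (requires token labels)."""
        if self.tokens is None:
            raise ValueError("clustering was run on unlabelled points")
        out: dict[int, list[str]] = {c: [] for c in range(self.k)}
        for tok, c in zip(self.tokens, self.assignments):
            out[int(c)].append(tok)
        return out


@dataclass
class DimensionLexicon:
    """Seed lexicon: dimension -> indicator -> seed words.

    Indicator order is meaningful (ties in cluster labelling are broken by
    lexicon order) and seed words must be unique across indicators.
    """

    indicators: dict[str, dict[str, list[str]]]

    def __post_init__(self) -> None:
        seen: set[str] = set()
        for dim, inds in self.indicators.items():
            for ind, seeds in inds.items():
                for w in seeds:
                    if w in seen:
                        raise ValueError(f"seed word {w!r} appears in two indicators")
                    seen.add(w)

    @property
    def dimensions(self) -> list[str]:
        return list(self.indicators)

    @property
    def n_indicators(self) -> int:
        return sum(len(v) for v in self.indicators.values())

    def items(self) -> list[tuple[str, str, list[str]]]:
        """(dimension, indicator, seeds) triples in lexicon order."""
        return [
            (dim, ind, seeds)
            for dim, inds in self.indicators.items()
            for ind, seeds in inds.items()
        ]

    def seed_dimension(self, token: str) -> str | None:
        for dim, _, seeds in self.items():
            if token in seeds:
                return dim
        return None

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.indicators, indent=2))

    @classmethod
    def from_json(cls, path: str | Path) -> "DimensionLexicon":
        return cls(indicators=json.loads(Path(path).read_text()))


def default_lexicon() -> DimensionLexicon:
    """The epidemic-case-study indicator system.

    Four dimensions of public concern; the original/derived-event indicators
    follow the man-machine-environment (5M) risk-management decomposition,
    the prediction/expectation indicators come from domain expertise.
    """
    return DimensionLexicon(
        indicators={
            "original_event": {
                "epidemic_name": ["COVID-19", "epidemic", "pneumonia"],
                "infections": ["cases", "positive"],
                "virus": ["asymptomatic"],
                "status": ["death", "virus_parameters"],
                "policies": ["close_loop", "initial_screening"],
            },
            "derived_event": {
                "event_name": ["fire", "transfer"],
                "people": ["experts", "out_of_province"],
                "materials": ["wire_board"],
                "environment": ["Xinjiang", "time"],
                "response": ["detection", "prevention"],
                "consequence": ["injured", "deaths"],
            },
            "public_prediction": {
                "residence": ["mass", "public"],
                "vulnerable_groups": ["the_elderly"],
                "measures": ["government_measures", "current"],
                "projections": ["according_to", "other_provinces"],
                "living_environment": ["community", "neighborhood"],
                "service": ["designated_hospitals", "medical_observation"],
                "livelihood": ["high_risk_area", "local"],
                "management": ["recovery", "homestay"],
            },
            "public_expectation": {
                "object": ["government", "country"],
                "condition": ["public_health", "economy"],
                "requirement": ["optimization", "development"],
                "desires": ["release", "scientific"],
            },
        }
    )


def synthetic_lexicon(corpus: Corpus, n_seeds: int = 10) -> DimensionLexicon:
    """Build a seed lexicon from a synthetic corpus's ground truth.

    One indicator per dimension, seeded with the head (most frequent, i.e.
    lowest-numbered) tokens of that dimension's vocabulary.
    """
    by_dim: dict[str, list[str]] = {d: [] for d in DIMENSIONS}
    for tok, dim in sorted(corpus.truth.items()):
        by_dim[dim].append(tok)
    return DimensionLexicon(
        indicators={dim: {"core": sorted(toks)[:n_seeds]} for dim, toks in by_dim.items()}
    )


def build_word_vectors(
    corpus: Corpus,
    keywords: KeywordTable | Sequence[str],
    l2_normalize: bool = True,
    mode: str = "standard",
) -> WordVectorSet:
    """Per-document TF-IDF vectors for the given keywords.

    Entry (i, d) is token i's TF x IDF weight in document d.  Raises
    ``ValueError`` naming any keyword absent from the corpus.
    """
    tokens = keywords.tokens if isinstance(keywords, KeywordTable) else list(keywords)
    docs = [doc.tokens for doc in corpus.documents]
    idf = inverse_document_frequency(docs, mode=mode)
    missing = [t for t in tokens if t not in idf]
    if missing:
        raise ValueError(f"keywords absent from corpus: {missing}")
    col = {t: i for i, t in enumerate(tokens)}
    mat = np.zeros((len(tokens), len(docs)))
    for d, doc in enumerate(docs):
        if len(doc) == 0:
            continue
        for tok, tf in term_frequency(doc).items():
            i = col.get(tok)
            if i is not None:
                mat[i, d] = tf * idf[tok]
    if l2_normalize:
        norms = np.linalg.norm(mat, axis=1, keepdims=True)
        nonzero = norms[:, 0] > 0
        mat[nonzero] /= norms[nonzero]
    return WordVectorSet(tokens=tokens, matrix=mat, normalized=l2_normalize)


def _loss(x: np.ndarray, centroids: np.ndarray, assign: np.ndarray) -> float:
    return float(((x - centroids[assign]) ** 2).sum())


def _plusplus_init(x: np.ndarray, k: int, rng: np.random.Generator) -> np.ndarray:
    """k-means++ seeding: subsequent centers drawn proportional to D^2."""
    n = x.shape[0]
    centers = [int(rng.integers(n))]
    d2 = ((x - x[centers[0]]) ** 2).sum(axis=1)
    for _ in range(1, k):
        total = d2.sum()
        if total <= 0:  # all remaining points coincide with a center
            centers.append(int(rng.integers(n)))
        else:
            centers.append(int(rng.choice(n, p=d2 / total)))
        d2 = np.minimum(d2, ((x - x[centers[-1]]) ** 2).sum(axis=1))
    return x[centers].copy()


def _lloyd(
    x: np.ndarray, k: int, rng: np.random.Generator, tol: float, max_iter: int
) -> tuple[np.ndarray, np.ndarray, float, int, list[float]]:
    centroids = _plusplus_init(x, k, rng)
    assign: np.ndarray | None = None
    history: list[float] = []
    prev_loss = np.inf
    for it in range(1, max_iter + 1):
        d2 = ((x[:, None, :] - centroids[None, :, :]) ** 2).sum(axis=2)
        new_assign = d2.argmin(axis=1)
        for c in range(k):
            mask = new_assign == c
            if mask.any():
                centroids[c] = x[mask].mean(axis=0)
            else:
                # empty cluster: seize the globally farthest point
                far = d2.min(axis=1).argmax()
                centroids[c] = x[far]
                new_assign[far] = c
        loss = _loss(x, centroids, new_assign)
        history.append(loss)
        converged = (
            assign is not None and np.array_equal(new_assign, assign)
        ) or prev_loss - loss < tol
        assign = new_assign
        prev_loss = loss
        if converged:
            break
    # final reassignment so labels are 1-nearest-centroid consistent
    d2 = ((x[:, None, :] - centroids[None, :, :]) ** 2).sum(axis=2)
    final = d2.argmin(axis=1)
    if not np.array_equal(final, assign):
        assign = final
        prev_loss = _loss(x, centroids, assign)
        history.append(prev_loss)
    return assign, centroids, prev_loss, it, history


def kmeans(
    vectors: WordVectorSet | np.ndarray,
    k: int,
    seed: int = 0,
    tol: float = 1e-8,
    max_iter: int = 300,
    n_restarts: int = 10,
) -> ClusteringResult:
    """Lloyd's K-means with k-means++ seeding, keeping the best of restarts.

    Iterations stop when assignments stabilize or the loss decrease falls
    below ``tol``; the loss J never increases across iterations.  Empty
    clusters are re-seeded with the point farthest from every centroid.
    Deterministic for a fixed seed.
    """
    if isinstance(vectors, WordVectorSet):
        x, tokens = vectors.matrix, vectors.tokens
    else:
        x = np.asarray(vectors, dtype=float)
        if x.ndim == 1:
            x = x[:, None]
        tokens = None
    n = x.shape[0]
    if k < 1:
        raise ValueError(f"k must be >= 1, got {k}")
    if k > n:
        raise ValueError(f"k={k} exceeds the number of points ({n})")

    best: tuple | None = None
    rng = np.random.default_rng(seed)
    for _ in range(n_restarts):
        assign, centroids, loss, n_iter, history = _lloyd(x, k, rng, tol, max_iter)
        if best is None or loss < best[2]:
            best = (assign, centroids, loss, n_iter, history)
    assign, centroids, loss, n_iter, history = best
    if any(later > earlier + 1e-9 for earlier, later in zip(history, history[1:])):
        raise AssertionError("K-means loss increased across iterations")
    return ClusteringResult(
        k=k,
        assignments=assign,
        centroids=centroids,
        loss=loss,
        n_iterations=n_iter,
        seed=seed,
        loss_history=history,
        tokens=tokens,
    )


def assign_clusters_to_indicators(
    result: ClusteringResult, lexicon: DimensionLexicon
) -> dict[int, tuple[str, str]]:
    """Label each cluster by its best-overlapping lexicon indicator.

    A cluster gets the (dimension, indicator) whose seed-word list shares
    the most tokens with it; ties go to the earlier lexicon entry, and
    clusters overlapping no seed words are labelled ("unassigned",
    "unassigned").
    """
    if not lexicon.indicators:
        raise ValueError("lexicon is empty")
    mapping: dict[int, tuple[str, str]] = {}
    for c, members in result.clusters().items():
        member_set = set(members)
        best_overlap = 0
        best_label = ("unassigned", "unassigned")
        for dim, ind, seeds in lexicon.items():
            overlap = len(member_set & set(seeds))
            if overlap > best_overlap:
                best_overlap = overlap
                best_label = (dim, ind)
        mapping[c] = best_label
    return mapping


def clustering_frame(
    result: ClusteringResult, mapping: Mapping[int, tuple[str, str]]
) -> pd.DataFrame:
    """Tabulate token, cluster, dimension, indicator for export."""
    rows = [
        {
            "token": tok,
            "cluster": int(c),
            "dimension": mapping[int(c)][0],
            "indicator": mapping[int(c)][1],
        }
        for tok, c in zip(result.tokens or [], result.assignments)
    ]
    return pd.DataFrame(rows)
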