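"""TF-IDF keyword extraction for short-document corpora.

Within-document term frequency is the count of a word divided by the
document length (so documents of different lengths are comparable); inverse
document frequency down-weights words that appear in many documents.  The
default IDF is the standard smoothed form

    IDF(t) = ln( D / (1 + df(t)) )

with D the number of documents and df(t) the number of documents containing
t.  An alternative ``literal`` mode evaluates the variant
ln(df(t) / (sum_t df(t) + 1)) for audit purposes only; it is not used by the
pipeline because it is not anti-monotone in df.  Negative IDF values
(possible when df + 1 > D) are kept rather than clipped.

A token's corpus-level keyword score is the sum over documents of its
per-document TF x IDF, and keyword tables are the K highest-scoring tokens
with scores renormalized to shares of the table mass.
"""

from __future__ import annotations

import math
from collections import Counter
from dataclasses import dataclass
from typing import Callable, Iterable, Mapping, Sequence

import pandas as pd

from .corpus import Corpus, Document

__all__ = [
    "tokenize",
    "term_frequency",
    "document_frequency",
    "inverse_document_frequency",
    "tfidf_scores",
    "KeywordEntry",
    "KeywordTable",
    "top_keywords",
]

Segmenter = Callable[[str], Sequence[str]]


def tokenize(
    text: str | Document | Sequence[str],
    stopwords: Iterable[str] = (),
    segmenter: Segmenter | None = None,
) -> list[str]:
    """Segment text and drop stop words, preserving token order.

    Accepts raw text (segmented by ``segmenter``, defaulting to whitespace
    splitting), an already-tokenized sequence, or a :class:`Document`.  Any
    callable ``text -> token sequence`` may be plugged in as the segmenter
    (e.g. a Chinese word segmenter); synthetic corpora are pre-tokenized so
    the default suffices.  An empty result is permitted.
    """
    if isinstance(text, Document):
        tokens: Sequence[str] = text.tokens
    elif isinstance(text, str):
        tokens = segmenter(text) if segmenter is not None else text.split()
    else:
        tokens = text
    stop = set(stopwords)
    return [t for t in tokens if t not in stop]


def term_frequency(tokens: Sequence[str]) -> dict[str, float]:
    """Normalized within-document frequencies: count / document length.

    The values sum to 1.  Raises ``ValueError`` on an empty document, whose
    normalization is undefined.
    """
    if len(tokens) == 0:
        raise ValueError("term frequency of an empty document is undefined")
    n = len(tokens)
    return {tok: c / n for tok, c in Counter(tokens).items()}


def document_frequency(corpus: Corpus | Sequence[Sequence[str]]) -> dict[str, int]:
    """Number of documents containing each token."""
    df: Counter[str] = Counter()
    for doc in _token_lists(corpus):
        df.update(set(doc))
    return dict(df)


def _token_lists(corpus: Corpus | Sequence[Sequence[str]]) -> list[Sequence[str]]:
    if isinstance(corpus, Corpus):
        return [doc.tokens for doc in corpus.documents]
    return list(corpus)


def inverse_document_frequency(
    corpus: Corpus | Sequence[Sequence[str]], mode: str = "standard"
) -> dict[str, float]:
    """Per-token IDF over the corpus.

    ``standard`` (default): ln(D / (1 + df)), anti-monotone in df.
    ``literal``: ln(df / (sum of all dfs + 1)), retained for audit.
    """
    docs = _token_lists(corpus)
    if len(docs) == 0:
        raise ValueError("IDF of an empty corpus is undefined")
    df = document_frequency(docs)
    if mode == "standard":
        n_docs = len(docs)
        return {t: math.log(n_docs / (1 + d)) for t, d in df.items()}
    if mode == "literal":
        total = sum(df.values())
        return {t: math.log(d / (total + 1)) for t, d in df.items()}
    raise ValueError(f"unknown IDF mode {mode!r}")


def tfidf_scores(
    corpus: Corpus | Sequence[Sequence[str]],
    mode: str = "standard",
    agg: str = "sum",
) -> pd.DataFrame:
    """Corpus-level TF-IDF statistics per token.

    Per document, a token's weight is TF x IDF; the corpus score aggregates
    these over documents (sum by default, mean optionally).  Returns a
    DataFrame indexed by token with columns ``count`` (total occurrences),
    ``df`` (document frequency), ``idf``, and ``score``, sorted by
    descending score with lexicographic tie-break.
    """
    docs = _token_lists(corpus)
    idf = inverse_document_frequency(docs, mode=mode)
    score: dict[str, float] = {t: 0.0 for t in idf}
    count: Counter[str] = Counter()
    for doc in docs:
        if len(doc) == 0:
            continue
        count.update(doc)
        for tok, tf in term_frequency(doc).items():
            score[tok] += tf * idf[tok]
    if agg == "mean":
        n_docs = len(docs)
        score = {t: s / n_docs for t, s in score.items()}
    elif agg != "sum":
        raise ValueError(f"unknown aggregation {agg!r}")
    df_counts = document_frequency(docs)
    frame = pd.DataFrame(
        {
            "count": pd.Series(dict(count), dtype=int),
            "df": pd.Series(df_counts, dtype=int),
            "idf": pd.Series(idf, dtype=float),
            "score": pd.Series(score, dtype=float),
        }
    )
    frame.index.name = "token"
    frame = frame.reset_index().sort_values(
        ["score", "token"], ascending=[False, True]
    )
    return frame.set_index("token")


@dataclass(frozen=True)
class KeywordEntry:
    token: str
    score: float
    share: float
    count: int | None = None  # total corpus occurrences, when known


@dataclass
class KeywordTable:
    """Ranked top-K keywords with scores renormalized to table shares."""

    entries: list[KeywordEntry]
    k: int
    short: bool = False  # fewer than K distinct tokens were available

    @property
    def tokens(self) -> list[str]:
        return [e.token for e in self.entries]

    @property
    def shares(self) -> dict[str, float]:
        return {e.token: e.share for e in self.entries}

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "rank": range(1, len(self.entries) + 1),
                "token": [e.token for e in self.entries],
                "score": [e.score for e in self.entries],
                "normalized_share": [e.share for e in self.entries],
            }
        )

    def __len__(self) -> int:
        return len(self.entries)


def top_keywords(
    stats: pd.DataFrame | Mapping[str, float],
    k: int,
    previous: KeywordTable | None = None,
) -> KeywordTable:
    """Select the K highest-scoring tokens as a keyword table.

    Ties are broken lexicographically.  If ``previous`` is given (e.g. the
    top-20 table is drawn from the top-100 table) the selection is
    restricted to its tokens.  If fewer than K distinct tokens exist, all
    are returned and the table is flagged short.
    """
    if k < 1:
        raise ValueError(f"table size must be >= 1, got {k}")
    counts: dict[str, int] = {}
    if isinstance(stats, pd.DataFrame):
        scores = dict(zip(stats.index, stats["score"]))
        if "count" in stats.columns:
            counts = dict(zip(stats.index, stats["count"]))
    else:
        scores = dict(stats)
    if previous is not None:
        allowed = set(previous.tokens)
        scores = {t: s for t, s in scores.items() if t in allowed}
    ranked = sorted(scores.items(), key=lambda ts: (-ts[1], ts[0]))[:k]
    total = sum(s for _, s in ranked)
    if total <= 0:
        raise ValueError("keyword table mass must be positive to normalize shares")
    entries = [
        KeywordEntry(t, s, s / total, count=counts.get(t)) for t, s in ranked
    ]
    return KeywordTable(entries=entries, k=k, short=len(entries) < k)
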