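"""Concern profiles, the satisfaction statistic, and discrete opinion states.

A concern profile distributes the normalized mass of a ranked keyword table
over the four concern dimensions (plus "unassigned" for keywords whose
cluster matched no lexicon indicator).  Concern for the original event is
read as approval of the current policy: the default satisfaction statistic
is the original-event share of the assigned keyword mass.  Satisfaction is
then discretized into the three opinion states consumed by the consensus
model — support (1), neutral (0.5), oppose (0) — by symmetric thresholds.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Mapping, Sequence

import pandas as pd

from .cluster import ClusteringResult, DimensionLexicon
from .corpus import DIMENSIONS
from .tfidf import KeywordTable

__all__ = [
    "ConcernProfile",
    "OpinionObservation",
    "token_dimensions",
    "concern_profile",
    "satisfaction",
    "opinion_state",
    "opinion_sequence",
    "SATISFACTION_STATISTICS",
]

UNASSIGNED = "unassigned"

#: Default satisfaction -> opinion-state thresholds (symmetric around 0.5).
DEFAULT_THRESHOLDS = (0.4, 0.6)

#: Numeric codes of the opinion states.
SUPPORT, NEUTRAL, OPPOSE = 1.0, 0.5, 0.0


@dataclass
class ConcernProfile:
    """Dimension-level shares of a keyword table's normalized mass.

    ``shares`` distributes the table's TF-IDF share mass over dimensions
    (plus "unassigned") and sums to 1; ``token_to_dimension`` retains the
    per-token labels so satisfaction statistics can reweight the raw counts.
    """

    event: str
    shares: dict[str, float]
    table: KeywordTable
    token_to_dimension: dict[str, str] = None  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.token_to_dimension is None:
            self.token_to_dimension = {}
        total = sum(self.shares.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"concern shares must sum to 1, got {total}")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"dimension": list(self.shares), "share": list(self.shares.values())}
        )


@dataclass(frozen=True)
class OpinionObservation:
    """One checkpoint's opinion: satisfaction in [0,1] and its discrete state."""

    event: str
    satisfaction: float
    state: float  # SUPPORT (1), NEUTRAL (0.5) or OPPOSE (0)


def token_dimensions(
    result: ClusteringResult, mapping: Mapping[int, tuple[str, str]]
) -> dict[str, str]:
    """Resolve each clustered token to its cluster's dimension label."""
    return {
        tok: mapping[int(c)][0]
        for tok, c in zip(result.tokens or [], result.assignments)
    }


def concern_profile(
    table: KeywordTable,
    token_to_dimension: Mapping[str, str],
    event: str = "",
) -> ConcernProfile:
    """Aggregate a keyword table's normalized shares by dimension.

    Tokens missing from ``token_to_dimension`` (or mapped to a cluster with
    no seed-word overlap) count toward "unassigned".  The shares over
    dimensions plus "unassigned" sum to 1 by construction.
    """
    if len(table) == 0:
        raise ValueError("cannot profile an empty keyword table")
    shares = {dim: 0.0 for dim in DIMENSIONS}
    shares[UNASSIGNED] = 0.0
    for entry in table.entries:
        dim = token_to_dimension.get(entry.token, UNASSIGNED)
        if dim not in shares:
            raise ValueError(f"unknown dimension label {dim!r} for {entry.token!r}")
        shares[dim] += entry.share
    return ConcernProfile(
        event=event,
        shares=shares,
        table=table,
        token_to_dimension=dict(token_to_dimension),
    )


def _original_share(profile: ConcernProfile) -> float:
    assigned = 1.0 - profile.shares.get(UNASSIGNED, 0.0)
    if assigned <= 0:
        raise ValueError("no keyword mass was assigned to any dimension")
    return profile.shares["original_event"] / assigned


def _dimension_count_groups(profile: ConcernProfile) -> dict[str, list[int]]:
    groups: dict[str, list[int]] = {}
    for entry in profile.table.entries:
        dim = profile.token_to_dimension.get(entry.token, UNASSIGNED)
        if dim == UNASSIGNED:
            continue
        if entry.count is None:
            raise ValueError(
                "count-based satisfaction statistics require keyword tables "
                "built from corpus statistics (token counts are missing)"
            )
        groups.setdefault(dim, []).append(int(entry.count))
    if not groups:
        raise ValueError("no keyword mass was assigned to any dimension")
    return groups


def _frequency_share(profile: ConcernProfile) -> float:
    """Original-event share of the raw occurrence counts of assigned keywords."""
    groups = _dimension_count_groups(profile)
    total = sum(sum(c) for c in groups.values())
    return sum(groups.get("original_event", [])) / total


def _balanced_depth_share(profile: ConcernProfile) -> float:
    """Original-event frequency share at equal keyword depth per dimension.

    A top-K table covers a larger fraction of a dominant dimension's
    (Zipf-skewed) token mass than of a minor one's, which biases raw
    frequency shares toward large dimensions.  Comparing every assigned
    dimension at the same depth — its n* most frequent table keywords, with
    n* the smallest per-dimension keyword count — cancels that coverage
    term, in the spirit of rarefaction in ecology.
    """
    groups = _dimension_count_groups(profile)
    n_star = min(len(c) for c in groups.values())
    mass = {
        dim: sum(sorted(c, reverse=True)[:n_star]) for dim, c in groups.items()
    }
    return mass.get("original_event", 0) / sum(mass.values())


SATISFACTION_STATISTICS: dict[str, Callable[[ConcernProfile], float]] = {
    "original_share": _original_share,
    "frequency": _frequency_share,
    "balanced_depth": _balanced_depth_share,
}


def satisfaction(profile: ConcernProfile, statistic: str = "original_share") -> float:
    """Map a concern profile to a policy-satisfaction rate in [0, 1].

    The default reads the original-event share of the assigned top-keyword
    mass as satisfaction with the current policy; alternative statistics can
    be registered in :data:`SATISFACTION_STATISTICS`.
    """
    try:
        fn = SATISFACTION_STATISTICS[statistic]
    except KeyError:
        raise ValueError(f"unknown satisfaction statistic {statistic!r}") from None
    return fn(profile)


def opinion_state(
    sat: float, thresholds: tuple[float, float] = DEFAULT_THRESHOLDS
) -> float:
    """Discretize satisfaction into support (1), neutral (0.5) or oppose (0)."""
    low, high = thresholds
    if not 0.0 <= low < high <= 1.0:
        raise ValueError(f"thresholds must satisfy 0 <= low < high <= 1, got {thresholds}")
    if sat >= high:
        return SUPPORT
    if sat <= low:
        return OPPOSE
    return NEUTRAL


def opinion_sequence(
    profiles: Sequence[ConcernProfile],
    thresholds: tuple[float, float] = DEFAULT_THRESHOLDS,
    statistic: str = "original_share",
) -> list[OpinionObservation]:
    """Chronological opinion observations, one per event checkpoint.

    This is the observation sequence O consumed by the consensus model's
    forward filter.
    """
    if len(profiles) == 0:
        raise ValueError("opinion sequence requires at least one profile")
    out = []
    for p in profiles:
        s = satisfaction(p, statistic=statistic)
        out.append(
            OpinionObservation(event=p.event, satisfaction=s,
                               state=opinion_state(s, thresholds))
        )
    return out
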