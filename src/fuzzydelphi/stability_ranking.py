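"""Round-to-round stability testing and permutation ranking of indicators.

*Stability* in the Delphi sense means the panel's opinion distribution did
not shift between consecutive rounds: a Mann-Whitney U test on the two
rounds' values that fails to reject (p above the significance level) is
read as stable. Because the named test treats the rounds as two
independent samples while a "before and after" reading suggests pairing, a
paired Wilcoxon signed-rank variant is also provided.

The Mann-Whitney implementation reports the U statistic, a z value from
the tie-corrected, continuity-corrected normal approximation with an
Edgeworth (kurtosis) refinement, and a two-sided p that switches to exact
enumeration for small tie-free samples.

*Ranking* orders the retained indicators by the agreement percentage from
the round each was accepted in (descending), breaking ties by the
defuzzified group score and then catalog order — a deterministic
permutation of the retained set.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

import numpy as np
from scipy import stats

from .survey_io import IndicatorCatalog

__all__ = [
    "StabilityResult",
    "RankingResult",
    "mann_whitney_u",
    "wilcoxon_paired",
    "rank_indicators",
    "compare_conditions",
    "ConditionComparison",
]

#: largest combined sample size for which exact enumeration is used
EXACT_LIMIT = 12


@dataclass(frozen=True)
class StabilityResult:
    """Outcome of a two-sample stability test between Delphi rounds."""

    u: float
    z: float
    p: float
    n1: int
    n2: int
    alpha: float
    stable: bool  # p > alpha: no detectable opinion shift
    method: str  # "exact" or "asymptotic"


def _u_statistic(x: np.ndarray, y: np.ndarray) -> float:
    """Mann-Whitney U of the first sample, with midrank ties."""
    n1 = x.size
    ranks = stats.rankdata(np.concatenate([x, y]))
    r1 = ranks[:n1].sum()
    return float(r1 - n1 * (n1 + 1) / 2.0)


def _tie_term(combined: np.ndarray) -> float:
    _, counts = np.unique(combined, return_counts=True)
    return float(((counts**3 - counts).sum()))


def _u_fourth_moment(n1: int, n2: int) -> float:
    # exact fourth central moment of the tie-free U distribution
    n = n1 + n2
    return (
        n1
        * n2
        * (n + 1)
        / 240.0
        * (5.0 * n1 * n2 * n - 2.0 * (n1**2 + n2**2) + 3.0 * n1 * n2 - 2.0 * n)
    )


def _asymptotic_p(u: float, n1: int, n2: int, tie_term: float) -> tuple[float, float]:
    """(z, two-sided p) from the corrected normal approximation.

    The variance carries the usual tie correction; for tie-free data an
    Edgeworth term built from the exact fourth moment of U sharpens the
    tail probabilities at moderate sample sizes.
    """
    n = n1 + n2
    mu = n1 * n2 / 2.0
    var = n1 * n2 / 12.0 * ((n + 1) - tie_term / (n * (n - 1))) if n > 1 else 0.0
    if var <= 0:
        return 0.0, 1.0
    sigma = math.sqrt(var)
    # continuity-corrected z of the observed U
    if u > mu:
        z = (u - mu - 0.5) / sigma
    elif u < mu:
        z = (u - mu + 0.5) / sigma
    else:
        z = 0.0
    # lower-tail cdf at the smaller tail, Edgeworth-refined (tie-free only)
    u_lo = min(u, n1 * n2 - u)
    z_lo = (u_lo + 0.5 - mu) / sigma
    cdf = stats.norm.cdf(z_lo)
    if tie_term == 0.0:
        g2 = _u_fourth_moment(n1, n2) / var**2 - 3.0
        cdf -= stats.norm.pdf(z_lo) * g2 * (z_lo**3 - 3.0 * z_lo) / 24.0
    p = min(1.0, max(0.0, 2.0 * cdf))
    return z, p


def mann_whitney_u(
    x: Sequence[float], y: Sequence[float], alpha: float = 0.05
) -> StabilityResult:
    """Two-sided Mann-Whitney U test between two Delphi rounds.

    Uses exact enumeration (via :func:`scipy.stats.mannwhitneyu`) when the
    combined sample is small (<= 12) and tie-free, otherwise the corrected
    normal approximation. ``stable`` is True when p > alpha.
    """
    xa = np.asarray(list(x), dtype=float)
    ya = np.asarray(list(y), dtype=float)
    if xa.size == 0 or ya.size == 0:
        raise ValueError("both samples must be nonempty")
    if not (0.0 < alpha < 1.0):
        raise ValueError("alpha must be in (0, 1)")
    u = _u_statistic(xa, ya)
    combined = np.concatenate([xa, ya])
    ties = _tie_term(combined)
    n1, n2 = xa.size, ya.size
    z, p_asym = _asymptotic_p(u, n1, n2, ties)
    if n1 + n2 <= EXACT_LIMIT and ties == 0.0:
        p = float(
            stats.mannwhitneyu(xa, ya, alternative="two-sided", method="exact").pvalue
        )
        method = "exact"
    else:
        p = p_asym
        method = "asymptotic"
    return StabilityResult(
        u=u, z=z, p=p, n1=n1, n2=n2, alpha=alpha, stable=p > alpha, method=method
    )


def asymptotic_p(x: Sequence[float], y: Sequence[float]) -> float:
    """The corrected normal-approximation p, regardless of sample size."""
    xa = np.asarray(list(x), dtype=float)
    ya = np.asarray(list(y), dtype=float)
    u = _u_statistic(xa, ya)
    _, p = _asymptotic_p(u, xa.size, ya.size, _tie_term(np.concatenate([xa, ya])))
    return p


def wilcoxon_paired(
    before: Sequence[float], after: Sequence[float], alpha: float = 0.05
) -> StabilityResult:
    """Paired Wilcoxon signed-rank alternative for the same-panel reading."""
    b = np.asarray(list(before), dtype=float)
    a = np.asarray(list(after), dtype=float)
    if b.size != a.size or b.size == 0:
        raise ValueError("paired samples must be nonempty and equal length")
    if np.allclose(b, a):
        # degenerate: no differences at all, trivially stable
        return StabilityResult(0.0, 0.0, 1.0, b.size, a.size, alpha, True, "exact")
    res = stats.wilcoxon(b, a, zero_method="wilcox", method="auto")
    p = float(res.pvalue)
    return StabilityResult(
        u=float(res.statistic),
        z=float(stats.norm.isf(p / 2.0)),
        p=p,
        n1=b.size,
        n2=a.size,
        alpha=alpha,
        stable=p > alpha,
        method="wilcoxon",
    )


@dataclass
class RankingResult:
    """Retained indicators in rank order (rank 1 = strongest agreement)."""

    indicators: list[str]
    ranks: dict[str, int]
    keys: dict[str, tuple[float, float]]  # id -> (agreement, defuzzified/score)

    def top(self, k: int) -> list[str]:
        if k < 1 or k > len(self.indicators):
            raise ValueError(f"k must be in 1..{len(self.indicators)}")
        return self.indicators[:k]


def rank_indicators(
    entries: Mapping[str, tuple[float, float]],
    catalog: Optional[IndicatorCatalog] = None,
) -> RankingResult:
    """Rank retained indicators by accepted-round agreement, descending.

    ``entries`` maps indicator id -> (agreement percent, secondary score);
    the secondary score (defuzzified group opinion, or any tie-break
    statistic) orders exact agreement ties, with catalog order as the
    final deterministic tie-break.
    """
    if len(entries) == 0:
        raise ValueError("nothing to rank")

    def final_key(item: str) -> int:
        return catalog.sort_key(item) if catalog is not None else 0

    ordered = sorted(
        entries,
        key=lambda i: (-entries[i][0], -entries[i][1], final_key(i), i),
    )
    return RankingResult(
        indicators=ordered,
        ranks={ind: r for r, ind in enumerate(ordered, start=1)},
        keys=dict(entries),
    )


@dataclass
class ConditionComparison:
    """Side-by-side top-k rankings under two operating conditions."""

    k: int
    top_a: list[str]
    top_b: list[str]
    overlap: int


def compare_conditions(
    ranking_a: RankingResult, ranking_b: RankingResult, k: int
) -> ConditionComparison:
    """Compare the top-k indicator lists of two rankings."""
    if k < 1:
        raise ValueError("k must be >= 1")
    top_a, top_b = ranking_a.top(k), ranking_b.top(k)
    return ConditionComparison(
        k=k, top_a=top_a, top_b=top_b, overlap=len(set(top_a) & set(top_b))
    )
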