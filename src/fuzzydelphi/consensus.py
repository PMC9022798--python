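"""Classical, fuzzy, and modified fuzzy Delphi consensus engines.

All three engines reduce one indicator's panel ratings to an *agreement
percentage* in [0, 100] and accept the indicator when that percentage
strictly exceeds the round's threshold:

* **DM** (classical Delphi): the experience-weighted share of ratings of 4
  or 5 ("agree"/"strongly agree"); the median and interquartile range are
  reported alongside for transparency.
* **FDM** (fuzzy Delphi): each rating is fuzzified, the panel's weighted
  group opinion is formed, and agreement is the weighted share of experts
  whose normalized Euclidean distance to the group opinion is at most the
  cutoff ``delta``.
* **MOFD** (modified fuzzy Delphi): each expert gets a *consistency index*

  ``C_k = beta * sim(a_k, g) + (1 - beta) * (1 - [gamma * d_H(a_k, g)
  + (1 - gamma) * d_inf(a_k, g)])``

  blending a similarity coefficient with a weighted Hamming plus
  support-gap (infimum) distance to the group opinion ``g``; agreement is
  the weighted mean of ``C_k`` times 100. The infimum term penalizes
  disjoint opinions that component-wise measures dilute, and the
  continuous index removes the ties a share-above-cutoff rule produces.

Indicators rejected in a round are carried forward into the next round's
questionnaire; an indicator accepted in any round is retained. Helpers for
thresholding, carry-forward, retention unions, and cross-method comparison
operate directly on published agreement tables as well, so the filtering
pipeline can be regression-tested against printed results.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np

from ._util import round_half_up
from .fuzzy_core import (
    DEFAULT_HAMMING_WEIGHTS,
    DEFAULT_SCALE,
    FuzzyScale,
    TriangularFuzzyNumber,
    aggregate_group,
    defuzzify,
    dist_euclidean,
    dist_infimum,
    dist_weighted_hamming,
    fuzzify,
    similarity,
)
from .survey_io import IndicatorCatalog, RoundDataset

logger = logging.getLogger(__name__)

__all__ = [
    "MethodConfig",
    "ConsensusResult",
    "RoundOutcome",
    "dm_consensus",
    "fdm_agreement",
    "mofd_agreement",
    "evaluate_round",
    "suggest_threshold",
    "apply_threshold",
    "next_round_items",
    "retained_set",
    "compare_methods",
    "MethodComparison",
]


@dataclass
class MethodConfig:
    """Configuration of one consensus engine.

    Parameters
    ----------
    method:
        ``"dm"``, ``"fdm"``, or ``"mofd"``.
    delta:
        FDM distance cutoff: an expert agrees with the group when their
        Euclidean distance to the group opinion is <= ``delta``.
    beta:
        MOFD mix between similarity (``beta``) and distance (``1 - beta``).
    gamma:
        MOFD mix between the weighted Hamming (``gamma``) and the
        support-gap/infimum (``1 - gamma``) distance.
    hamming_weights:
        Component weights of the Hamming distance (l, m, u).
    thresholds:
        Per-round acceptance thresholds in percent (strict >). When a
        round has no entry (or thresholds is None) the rounded median of
        that round's agreement values is used — a heuristic only, since
        threshold choice is a study-design decision.
    dm_threshold:
        Acceptance threshold for the classical Delphi rule.
    weighting:
        ``"experience"`` (years-proportional) or ``"uniform"``.
    """

    method: str = "mofd"
    delta: float = 0.2
    beta: float = 0.5
    gamma: float = 0.5
    hamming_weights: Sequence[float] = DEFAULT_HAMMING_WEIGHTS
    thresholds: Optional[dict[int, float]] = None
    dm_threshold: float = 75.0
    weighting: str = "experience"
    scale: FuzzyScale = field(default_factory=FuzzyScale.default)
    defuzzifier: str = "centroid"

    def __post_init__(self) -> None:
        if self.method not in ("dm", "fdm", "mofd"):
            raise ValueError(f"unknown method {self.method!r}")
        if not (0.0 < self.delta < 1.0):
            raise ValueError("delta must be in (0, 1)")
        if not (0.0 <= self.beta <= 1.0 and 0.0 <= self.gamma <= 1.0):
            raise ValueError("beta and gamma must be in [0, 1]")
        if self.thresholds is not None:
            for rnd, t in self.thresholds.items():
                if not (0.0 < t < 100.0):
                    raise ValueError(f"threshold for round {rnd} must be in (0, 100)")
        if self.weighting not in ("experience", "uniform"):
            raise ValueError(f"unknown weighting mode {self.weighting!r}")

    @classmethod
    def from_dict(cls, raw: Mapping) -> "MethodConfig":
        kwargs = dict(raw)
        if "thresholds" in kwargs and kwargs["thresholds"] is not None:
            kwargs["thresholds"] = {int(k): float(v) for k, v in kwargs["thresholds"].items()}
        if "scale" in kwargs and not isinstance(kwargs["scale"], FuzzyScale):
            kwargs["scale"] = FuzzyScale.from_dict(kwargs["scale"])
        if "hamming_weights" in kwargs:
            kwargs["hamming_weights"] = tuple(kwargs["hamming_weights"])
        return cls(**kwargs)

    def threshold_for(self, round: int, agreements: Sequence[float]) -> float:
        if self.thresholds is not None and round in self.thresholds:
            return self.thresholds[round]
        t = suggest_threshold(agreements)
        logger.info(
            "round %d: no configured threshold, using suggested median %s", round, t
        )
        return t


@dataclass
class ConsensusResult:
    """Per-indicator outcome of one consensus computation."""

    indicator_id: str
    group_tfn: Optional[TriangularFuzzyNumber]
    defuzzified: Optional[float]
    mean_distance: Optional[float]
    agreement: float  # percent in [0, 100]
    threshold: Optional[float] = None
    accepted: Optional[bool] = None
    median: Optional[float] = None  # DM only
    iqr: Optional[float] = None  # DM only

    def with_threshold(self, threshold: float) -> "ConsensusResult":
        return ConsensusResult(
            indicator_id=self.indicator_id,
            group_tfn=self.group_tfn,
            defuzzified=self.defuzzified,
            mean_distance=self.mean_distance,
            agreement=self.agreement,
            threshold=threshold,
            accepted=self.agreement > threshold,
            median=self.median,
            iqr=self.iqr,
        )


@dataclass
class RoundOutcome:
    """All indicators of one round: accepted and carried-forward sets."""

    round: int
    method: str
    threshold: float
    results: dict[str, ConsensusResult]
    accepted: list[str]
    carried_forward: list[str]


def _check_panel(ratings: Sequence[int], weights: Sequence[float]) -> np.ndarray:
    r = np.asarray(list(ratings), dtype=int)
    w = np.asarray(list(weights), dtype=float)
    if r.size < 2:
        raise ValueError("need ratings from at least 2 experts")
    if r.size != w.size:
        raise ValueError("ratings and weights differ in length")
    if abs(w.sum() - 1.0) > 1e-6:
        raise ValueError("weights must sum to 1")
    return w


def dm_consensus(
    indicator_id: str,
    ratings: Sequence[int],
    weights: Sequence[float],
    threshold: float = 75.0,
) -> ConsensusResult:
    """Classical Delphi: weighted percent of ratings >= 4, plus median/IQR."""
    w = _check_panel(ratings, weights)
    r = np.asarray(list(ratings), dtype=float)
    agreement = 100.0 * float(w[r >= 4].sum())
    q1, med, q3 = np.percentile(r, [25, 50, 75])
    return ConsensusResult(
        indicator_id=indicator_id,
        group_tfn=None,
        defuzzified=None,
        mean_distance=None,
        agreement=agreement,
        threshold=threshold,
        accepted=agreement > threshold,
        median=float(med),
        iqr=float(q3 - q1),
    )


def _fuzzy_group(
    ratings: Sequence[int], weights: np.ndarray, scale: FuzzyScale
) -> tuple[list[TriangularFuzzyNumber], TriangularFuzzyNumber]:
    tfns = [fuzzify(int(r), scale) for r in ratings]
    return tfns, aggregate_group(tfns, weights)


def fdm_agreement(
    indicator_id: str,
    ratings: Sequence[int],
    weights: Sequence[float],
    config: MethodConfig,
) -> ConsensusResult:
    """Fuzzy Delphi: weighted share of experts within ``delta`` of the group."""
    w = _check_panel(ratings, weights)
    tfns, group = _fuzzy_group(ratings, w, config.scale)
    d = np.array([dist_euclidean(t, group) for t in tfns])
    agreement = 100.0 * float(w[d <= config.delta].sum())
    return ConsensusResult(
        indicator_id=indicator_id,
        group_tfn=group,
        defuzzified=defuzzify(group, config.defuzzifier),
        mean_distance=float(w @ d),
        agreement=agreement,
    )


def mofd_agreement(
    indicator_id: str,
    ratings: Sequence[int],
    weights: Sequence[float],
    config: MethodConfig,
) -> ConsensusResult:
    """Modified fuzzy Delphi: weighted mean per-expert consistency index."""
    w = _check_panel(ratings, weights)
    tfns, group = _fuzzy_group(ratings, w, config.scale)
    beta, gamma = config.beta, config.gamma
    c = np.empty(len(tfns))
    dists = np.empty(len(tfns))
    for i, t in enumerate(tfns):
        sim = similarity(t, group)
        ham = dist_weighted_hamming(t, group, config.hamming_weights)
        inf = dist_infimum(t, group)
        mixed = gamma * ham + (1.0 - gamma) * inf
        c[i] = beta * sim + (1.0 - beta) * (1.0 - mixed)
        dists[i] = mixed
    agreement = 100.0 * float(w @ c)
    return ConsensusResult(
        indicator_id=indicator_id,
        group_tfn=group,
        defuzzified=defuzzify(group, config.defuzzifier),
        mean_distance=float(w @ dists),
        agreement=agreement,
    )


_ENGINES = {
    "fdm": fdm_agreement,
    "mofd": mofd_agreement,
}


def evaluate_round(
    dataset: RoundDataset,
    weights: Mapping[str, float],
    config: MethodConfig,
) -> RoundOutcome:
    """Run one consensus round over a fully imputed rating matrix."""
    w = [weights[e] for e in dataset.ratings.index]
    results: dict[str, ConsensusResult] = {}
    for item in dataset.items:
        ratings = dataset.ratings[item].tolist()
        if config.method == "dm":
            res = dm_consensus(item, ratings, w, config.dm_threshold)
        else:
            res = _ENGINES[config.method](item, ratings, w, config)
        results[item] = res
    agreements = [r.agreement for r in results.values()]
    if config.method == "dm":
        threshold = config.dm_threshold
    else:
        threshold = config.threshold_for(dataset.round, agreements)
    results = {k: r.with_threshold(threshold) for k, r in results.items()}
    accepted = [k for k, r in results.items() if r.accepted]
    carried = [k for k in dataset.items if k not in accepted]
    return RoundOutcome(
        round=dataset.round,
        method=config.method,
        threshold=threshold,
        results=results,
        accepted=accepted,
        carried_forward=carried,
    )


def suggest_threshold(agreements: Sequence[float]) -> float:
    """Rounded median of a round's agreement percentages (heuristic only)."""
    if len(agreements) == 0:
        raise ValueError("no agreement values")
    return round_half_up(float(np.median(list(agreements))), 0)


def apply_threshold(
    values: Mapping[str, float],
    threshold: float,
    catalog: Optional[IndicatorCatalog] = None,
) -> list[str]:
    """Indicators whose agreement strictly exceeds the threshold.

    Output preserves catalog order when a catalog is given, otherwise the
    mapping's insertion order. NaN values (unpublished cells) never pass.
    """
    if not (0.0 < threshold < 100.0):
        raise ValueError("threshold must be in (0, 100)")
    keys = list(values)
    if catalog is not None:
        keys = sorted(keys, key=catalog.sort_key)
    return [k for k in keys if not np.isnan(values[k]) and values[k] > threshold]


def next_round_items(outcome: RoundOutcome) -> list[str]:
    """The revised questionnaire: all evaluated items minus the accepted."""
    return list(outcome.carried_forward)


def retained_set(outcomes: Sequence[RoundOutcome | Sequence[str]]) -> list[str]:
    """Union of accepted sets across rounds.

    An indicator accepted in an earlier round must not be re-evaluated, so
    overlapping accepted sets raise.
    """
    if len(outcomes) == 0:
        raise ValueError("need at least one round")
    retained: list[str] = []
    seen: set[str] = set()
    for outcome in outcomes:
        accepted = outcome.accepted if isinstance(outcome, RoundOutcome) else list(outcome)
        overlap = seen.intersection(accepted)
        if overlap:
            raise ValueError(
                f"indicators accepted in more than one round: {sorted(overlap)}"
            )
        retained.extend(accepted)
        seen.update(accepted)
    return retained


@dataclass
class MethodComparison:
    common: list[str]
    only_a: list[str]
    only_b: list[str]


def compare_methods(
    a: Iterable[str],
    b: Iterable[str],
    catalog: Optional[IndicatorCatalog] = None,
) -> MethodComparison:
    """Intersection and differences of two retained-indicator sets."""
    sa, sb = set(a), set(b)

    def order(ids: set[str]) -> list[str]:
        if catalog is not None:
            return sorted(ids, key=catalog.sort_key)
        return sorted(ids)

    return MethodComparison(
        common=order(sa & sb), only_a=order(sa - sb), only_b=order(sb - sa)
    )
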