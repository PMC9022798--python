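"""Triangular fuzzy numbers on the unit interval and the measures built on them.

A panel member's ordinal Likert rating is mapped to a triangular fuzzy
number (TFN) ``(l, m, u)`` with ``0 <= l <= m <= u <= 1`` — the lower
support, mode, and upper support of a triangular membership function.
Working with TFNs instead of raw ordinal levels lets the aggregation step
carry the linguistic vagueness of "agree" vs "strongly agree" through to
the consensus computation.

This module provides:

* :class:`TriangularFuzzyNumber` and :class:`FuzzyScale` (the Likert
  level -> TFN mapping, with a standard five-level default),
* experience-proportional expert weights,
* component-wise weighted aggregation of per-expert TFNs into a group
  opinion,
* defuzzification (centroid or weighted-mean conventions), and
* the distance / similarity measures the consensus engines consume:
  normalized Euclidean distance (fuzzy Delphi), weighted Hamming distance,
  support-gap ("infimum") distance, and a linear similarity coefficient
  (modified fuzzy Delphi).

All measures map pairs of unit-interval TFNs into ``[0, 1]``, vanish on
identical arguments, and are symmetric.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np

#: absolute tolerance for all floating-point validity checks
ABS_TOL = 1e-9

__all__ = [
    "ABS_TOL",
    "TriangularFuzzyNumber",
    "FuzzyScale",
    "DEFAULT_SCALE",
    "fuzzify",
    "defuzzify",
    "expert_weights",
    "aggregate_group",
    "dist_euclidean",
    "dist_weighted_hamming",
    "dist_infimum",
    "similarity",
    "DEFAULT_HAMMING_WEIGHTS",
]


@dataclass(frozen=True)
class TriangularFuzzyNumber:
    """A triangular fuzzy number ``(l, m, u)`` with support inside [0, 1]."""

    l: float
    m: float
    u: float

    def __post_init__(self) -> None:
        if not (
            -ABS_TOL <= self.l <= self.m + ABS_TOL
            and self.m <= self.u + ABS_TOL
            and self.u <= 1.0 + ABS_TOL
        ):
            raise ValueError(
                f"invalid TFN ({self.l}, {self.m}, {self.u}): "
                "need 0 <= l <= m <= u <= 1"
            )

    def as_array(self) -> np.ndarray:
        return np.array([self.l, self.m, self.u], dtype=float)

    def __iter__(self):
        return iter((self.l, self.m, self.u))


#: alias used throughout
TFN = TriangularFuzzyNumber

#: Standard five-level scale: adjacent levels overlap by half a step so the
#: fuzzified ratings reflect the blurred boundaries between Likert anchors.
_DEFAULT_LEVELS: Mapping[int, tuple[float, float, float]] = {
    1: (0.00, 0.00, 0.25),
    2: (0.00, 0.25, 0.50),
    3: (0.25, 0.50, 0.75),
    4: (0.50, 0.75, 1.00),
    5: (0.75, 1.00, 1.00),
}


@dataclass(frozen=True)
class FuzzyScale:
    """Mapping from the five Likert levels to triangular fuzzy numbers.

    The defuzzified value must increase strictly with the Likert level so
    that fuzzification preserves the ordinal ordering of the scale.
    """

    levels: Mapping[int, TriangularFuzzyNumber]

    def __post_init__(self) -> None:
        if set(self.levels) != {1, 2, 3, 4, 5}:
            raise ValueError("a FuzzyScale must define exactly levels 1..5")
        scores = [defuzzify(self.levels[k]) for k in range(1, 6)]
        if any(b - a <= ABS_TOL for a, b in zip(scores, scores[1:])):
            raise ValueError(
                "defuzzified scale values must strictly increase with the level"
            )

    @classmethod
    def from_dict(cls, mapping: Mapping[int, Sequence[float]]) -> "FuzzyScale":
        return cls({int(k): TFN(*map(float, v)) for k, v in mapping.items()})

    @classmethod
    def default(cls) -> "FuzzyScale":
        return cls.from_dict(_DEFAULT_LEVELS)

    def __getitem__(self, level: int) -> TriangularFuzzyNumber:
        return self.levels[level]


def defuzzify(a: TriangularFuzzyNumber, method: str = "centroid") -> float:
    """Collapse a TFN to a crisp score in [0, 1].

    ``centroid`` is the arithmetic mean ``(l + m + u)/3`` (the centroid of a
    triangular membership function); ``weighted_mean`` uses ``(l + 2m + u)/4``,
    which doubles the mode's influence.
    """
    if method == "centroid":
        return (a.l + a.m + a.u) / 3.0
    if method == "weighted_mean":
        return (a.l + 2.0 * a.m + a.u) / 4.0
    raise ValueError(f"unknown defuzzifier {method!r}")


DEFAULT_SCALE = FuzzyScale.default()


def fuzzify(rating: int, scale: FuzzyScale = DEFAULT_SCALE) -> TriangularFuzzyNumber:
    """Convert a Likert rating (1-5) to its triangular fuzzy number."""
    if rating not in (1, 2, 3, 4, 5):
        raise ValueError(f"Likert rating must be in 1..5, got {rating!r}")
    return scale[int(rating)]


def expert_weights(years: Sequence[float]) -> np.ndarray:
    """Experience-proportional weights ``w_k = years_k / sum(years)``.

    The panel's pooled years of relevant experience act as the total
    "degree of importance"; each expert's share of it weights their opinion
    in every aggregation step.
    """
    y = np.asarray(list(years), dtype=float)
    if y.size == 0:
        raise ValueError("empty panel")
    if np.any(y < 0):
        raise ValueError("years of experience must be non-negative")
    total = y.sum()
    if total <= ABS_TOL:
        raise ValueError("zero total experience: cannot derive weights")
    return y / total


def aggregate_group(
    tfns: Iterable[TriangularFuzzyNumber], weights: Sequence[float]
) -> TriangularFuzzyNumber:
    """Component-wise weighted mean of per-expert TFNs (the group opinion)."""
    arr = np.array([t.as_array() for t in tfns], dtype=float)
    w = np.asarray(list(weights), dtype=float)
    if arr.shape[0] != w.shape[0]:
        raise ValueError(
            f"got {arr.shape[0]} fuzzy numbers but {w.shape[0]} weights"
        )
    if np.any(w < -ABS_TOL):
        raise ValueError("weights must be non-negative")
    if abs(w.sum() - 1.0) > 1e-6:
        raise ValueError("weights must sum to 1")
    l, m, u = w @ arr
    # clip float dust so the result is a valid TFN
    return TFN(min(l, m), m, max(u, m))


def dist_euclidean(a: TriangularFuzzyNumber, b: TriangularFuzzyNumber) -> float:
    """Normalized Euclidean distance, the classical fuzzy-Delphi measure."""
    return math.sqrt(((a.l - b.l) ** 2 + (a.m - b.m) ** 2 + (a.u - b.u) ** 2) / 3.0)


#: default component weights: the mode carries half the emphasis
DEFAULT_HAMMING_WEIGHTS = (0.25, 0.5, 0.25)


def dist_weighted_hamming(
    a: TriangularFuzzyNumber,
    b: TriangularFuzzyNumber,
    alpha: Sequence[float] = DEFAULT_HAMMING_WEIGHTS,
) -> float:
    """Weighted Hamming distance ``sum(alpha_i * |a_i - b_i|)``.

    ``alpha`` must be three non-negative component weights summing to one.
    """
    al = np.asarray(list(alpha), dtype=float)
    if al.shape != (3,) or np.any(al < 0) or abs(al.sum() - 1.0) > 1e-6:
        raise ValueError("alpha must be 3 non-negative weights summing to 1")
    return float(al @ np.abs(a.as_array() - b.as_array()))


def dist_infimum(a: TriangularFuzzyNumber, b: TriangularFuzzyNumber) -> float:
    """Support-gap distance: how far apart the two supports are.

    Zero whenever the supports ``[l, u]`` intersect; otherwise the length of
    the gap between them. Captures the "disjoint opinions" case that purely
    component-wise measures dilute.
    """
    return max(0.0, max(a.l, b.l) - min(a.u, b.u))


def similarity(a: TriangularFuzzyNumber, b: TriangularFuzzyNumber) -> float:
    """Linear similarity coefficient ``1 - mean(|a_i - b_i|)`` in [0, 1]."""
    return 1.0 - (abs(a.l - b.l) + abs(a.m - b.m) + abs(a.u - b.u)) / 3.0
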