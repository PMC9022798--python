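"""Seeded simulator of expert panels and multi-round Likert responses.

No raw panel responses exist for the published surge study, so the
generator emulates its conditions: a panel of 45 experts with 3-11 years
of experience, per-indicator latent importance ``theta`` in [0, 1] and
rating dispersion ``sigma``, occasional missing ratings, and a ~49%
round-2 dropout matching the study's 51.11% second-round response rate.

Each rating is drawn by discretizing a noisy latent value::

    rating = clamp(round(1 + 4 * (theta_p + eps)), 1, 5),  eps ~ N(0, sigma_p^2)

so ``theta`` pins the consensus location and ``sigma`` how far the panel
scatters around it. One shared random stream is consumed in a fixed,
documented order (panel -> per-round ratings by expert-then-indicator ->
missingness -> dropout -> comments), making every study bit-reproducible
from (config, seed).

Ground-truth acceptance labels come straight from (theta, sigma): clearly
important, tightly agreed indicators are expected-accept; unimportant or
highly dispersed ones expected-reject; the band between is indeterminate
and excluded from recovery scoring.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np

from .sentiment import Lexicon
from .survey_io import Expert, Panel, ResponseRecord

__all__ = [
    "SimulationConfig",
    "SimulatedStudy",
    "simulate_panel",
    "ground_truth_labels",
    "recovery_benchmark_config",
]

# label bands: consistent with "high theta + low sigma => accept",
# "low theta or high sigma => reject", indeterminate between
ACCEPT_THETA, ACCEPT_SIGMA = 0.85, 0.15
REJECT_THETA, REJECT_SIGMA = 0.40, 0.45


@dataclass
class SimulationConfig:
    """Study-generating parameters; defaults mirror the emulated panel."""

    indicators: Sequence[str]
    theta: Sequence[float]
    sigma: Sequence[float]
    n_experts: int = 45
    experience_range: tuple[int, int] = (3, 11)
    missingness: float = 0.02
    dropout: float = 0.4889  # round-2 non-response probability
    n_rounds: int = 2
    seed: int = 0
    comment_rate: float = 0.0
    # factor -> (positive token rate, negative token rate) for comments
    comment_polarity: Mapping[str, tuple[float, float]] = field(default_factory=dict)
    factor_of: Mapping[str, str] = field(default_factory=dict)
    tokens_per_comment: int = 8

    def __post_init__(self) -> None:
        k = len(self.indicators)
        if not (len(self.theta) == len(self.sigma) == k):
            raise ValueError("indicators, theta, sigma must align")
        if any(not (0.0 <= t <= 1.0) for t in self.theta):
            raise ValueError("theta must lie in [0, 1]")
        if any(s <= 0.0 for s in self.sigma):
            raise ValueError("sigma must be positive")
        for p in (self.missingness, self.dropout, self.comment_rate):
            if not (0.0 <= p <= 1.0):
                raise ValueError("probabilities must lie in [0, 1]")
        lo, hi = self.experience_range
        if lo < 3 or hi < lo:
            raise ValueError("experience range must satisfy 3 <= lo <= hi")
        if self.n_experts < 2 or self.n_rounds < 1:
            raise ValueError("need >= 2 experts and >= 1 round")


@dataclass
class SimulatedStudy:
    """A reproducible synthetic study with known ground truth."""

    config: SimulationConfig
    panel: Panel
    records: list[ResponseRecord]  # all rounds, pre-imputation
    labels: dict[str, str]  # indicator -> accept | reject | indeterminate

    def round_records(self, round: int) -> list[ResponseRecord]:
        return [r for r in self.records if r.round == round]


def ground_truth_labels(config: SimulationConfig) -> dict[str, str]:
    """Expected acceptance per indicator, from (theta, sigma) alone."""
    labels = {}
    for ind, t, s in zip(config.indicators, config.theta, config.sigma):
        if t >= ACCEPT_THETA and s <= ACCEPT_SIGMA:
            labels[ind] = "accept"
        elif t <= REJECT_THETA or s >= REJECT_SIGMA:
            labels[ind] = "reject"
        else:
            labels[ind] = "indeterminate"
    return labels


def _draw_rating(rng: np.random.Generator, theta: float, sigma: float) -> int:
    latent = 1.0 + 4.0 * (theta + rng.normal(0.0, sigma))
    return int(np.clip(np.rint(latent), 1, 5))


def _maybe_comment(
    rng: np.random.Generator,
    config: SimulationConfig,
    indicator: str,
    lexicon: Lexicon,
) -> Optional[str]:
    if config.comment_rate <= 0.0 or rng.random() >= config.comment_rate:
        return None
    factor = config.factor_of.get(indicator, "")
    pos_rate, neg_rate = config.comment_polarity.get(factor, (0.05, 0.05))
    pos_pool = sorted(lexicon.positive)
    neg_pool = sorted(lexicon.negative)
    filler = ["the", "ed", "patients", "during", "surge", "staff", "we", "see"]
    words = []
    for _ in range(config.tokens_per_comment):
        u = rng.random()
        if u < pos_rate:
            words.append(pos_pool[rng.integers(len(pos_pool))])
        elif u < pos_rate + neg_rate:
            words.append(neg_pool[rng.integers(len(neg_pool))])
        else:
            words.append(filler[rng.integers(len(filler))])
    return " ".join(words)


def simulate_panel(
    config: SimulationConfig, seed: Optional[int] = None
) -> SimulatedStudy:
    """Generate a full multi-round study from a config and seed.

    The seed argument overrides ``config.seed``; identical (config, seed)
    pairs produce identical studies.
    """
    rng = np.random.default_rng(config.seed if seed is None else seed)
    lo, hi = config.experience_range
    experts = tuple(
        Expert(
            expert_id=f"E{k + 1:03d}",
            specialty="simulated",
            years_experience=int(rng.integers(lo, hi + 1)),
        )
        for k in range(config.n_experts)
    )
    panel = Panel(experts)
    lexicon = Lexicon.default() if config.comment_rate > 0 else None

    records: list[ResponseRecord] = []
    for rnd in range(1, config.n_rounds + 1):
        # ratings, expert-major then indicator order
        ratings = {
            (e.expert_id, ind): _draw_rating(rng, t, s)
            for e in experts
            for ind, t, s in zip(config.indicators, config.theta, config.sigma)
        }
        # independent missingness flips, same traversal order
        missing = {
            key: rng.random() < config.missingness for key in ratings
        }
        # dropout applies from round 2 on: a non-responding expert has all
        # ratings missing that round (later imputed Neutral)
        dropped: set[str] = set()
        if rnd >= 2:
            dropped = {
                e.expert_id for e in experts if rng.random() < config.dropout
            }
        for e in experts:
            for ind in config.indicators:
                key = (e.expert_id, ind)
                is_missing = missing[key] or e.expert_id in dropped
                comment = None
                if lexicon is not None and not is_missing:
                    comment = _maybe_comment(rng, config, ind, lexicon)
                records.append(
                    ResponseRecord(
                        round=rnd,
                        expert_id=e.expert_id,
                        indicator_id=ind,
                        rating=None if is_missing else ratings[key],
                        comment=comment,
                    )
                )
    return SimulatedStudy(
        config=config,
        panel=panel,
        records=records,
        labels=ground_truth_labels(config),
    )


def recovery_benchmark_config(seed: int = 0, **overrides) -> SimulationConfig:
    """The standard parameter-recovery benchmark: a 45-expert panel rating
    10 clearly-important, tightly-agreed indicators (theta 0.9, sigma 0.1)
    and 10 unimportant, dispersed ones (theta 0.3, sigma 0.5)."""
    indicators = [f"acc_{i:02d}" for i in range(10)] + [f"rej_{i:02d}" for i in range(10)]
    theta = [0.9] * 10 + [0.3] * 10
    sigma = [0.1] * 10 + [0.5] * 10
    kwargs = dict(
        indicators=indicators, theta=theta, sigma=sigma, seed=seed, n_rounds=1
    )
    kwargs.update(overrides)
    return SimulationConfig(**kwargs)
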