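"""Lexicon-based weighted sentiment scoring of expert comments.

Free-text comments attached to the questionnaire are scored per healthcare
performance factor: each commenting expert's negative (positive) intensity
is the fraction of their tokens found in the negative (positive) lexicon,
and the factor score is the experience-weighted mean intensity over the
experts who commented (weights renormalized over commenters, so sparsely
commented factors are not deflated). The factor label is by dominance:
Negative if the negative score exceeds the positive, Positive if the
reverse, Neutral on an exact tie.

Scoring is unigram and lexicon-driven by design — no negation handling, no
trained model — which keeps the procedure transparent and the lexicon
swappable for any published opinion word list.
"""

from __future__ import annotations

import re
import unicodedata
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Optional

__all__ = ["Lexicon", "SentimentScore", "tokenize", "score_comments", "label_sentiment"]

_PUNCT = re.compile(r"[^\w\s]|_", flags=re.UNICODE)


def tokenize(text: str) -> list[str]:
    """Unicode-lowercase, strip punctuation, split on whitespace."""
    text = unicodedata.normalize("NFKC", text).lower()
    return _PUNCT.sub(" ", text).split()


@dataclass(frozen=True)
class Lexicon:
    """Disjoint sets of lowercase positive and negative opinion tokens."""

    positive: frozenset[str]
    negative: frozenset[str]

    def __post_init__(self) -> None:
        if not self.positive or not self.negative:
            raise ValueError("lexicon term sets must be nonempty")
        overlap = self.positive & self.negative
        if overlap:
            raise ValueError(f"lexicon sets must be disjoint; shared: {sorted(overlap)}")

    @classmethod
    def from_files(cls, positive_path: str | Path, negative_path: str | Path) -> "Lexicon":
        def load(path: str | Path) -> frozenset[str]:
            with open(path, encoding="utf-8") as fh:
                return frozenset(
                    line.strip().lower() for line in fh if line.strip()
                )

        return cls(load(positive_path), load(negative_path))

    @classmethod
    def default(cls) -> "Lexicon":
        from . import datasets

        pos, neg = datasets.default_lexicon_paths()
        return cls.from_files(pos, neg)


@dataclass(frozen=True)
class SentimentScore:
    """Weighted negative/positive intensity for one factor, with a label."""

    factor: str
    negative: float
    positive: float
    label: str

    def __post_init__(self) -> None:
        if self.negative < 0 or self.positive < 0:
            raise ValueError("sentiment scores must be non-negative")
        if self.label != label_sentiment(self.negative, self.positive):
            raise ValueError("label inconsistent with the dominance rule")


def label_sentiment(negative: float, positive: float) -> str:
    """Dominance rule: the larger intensity names the polarity."""
    if negative < 0 or positive < 0:
        raise ValueError("sentiment scores must be non-negative")
    if negative > positive:
        return "Negative"
    if positive > negative:
        return "Positive"
    return "Neutral"


def score_comments(
    factor: str,
    comments: Mapping[str, str],
    weights: Mapping[str, float],
    lexicon: Optional[Lexicon] = None,
) -> SentimentScore:
    """Score one factor's comments (expert id -> comment text).

    Experts without a comment contribute nothing; weights are renormalized
    over the commenting experts. A comment with no tokens has intensity 0.
    """
    if lexicon is None:
        lexicon = Lexicon.default()
    commenters = [e for e, text in comments.items() if text and text.strip()]
    if not commenters:
        return SentimentScore(factor, 0.0, 0.0, "Neutral")
    total_w = sum(weights[e] for e in commenters)
    if total_w <= 0:
        raise ValueError("commenting experts carry zero total weight")
    neg = pos = 0.0
    for e in commenters:
        tokens = tokenize(comments[e])
        if not tokens:
            continue
        n = len(tokens)
        neg_i = sum(1 for t in tokens if t in lexicon.negative) / n
        pos_i = sum(1 for t in tokens if t in lexicon.positive) / n
        w = weights[e] / total_w
        neg += w * neg_i
        pos += w * pos_i
    return SentimentScore(factor, neg, pos, label_sentiment(neg, pos))
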