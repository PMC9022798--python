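"""Data model and I/O for multi-round expert-panel surveys.

The canonical on-disk format is a long-format, UTF-8, comma-separated file
with the header::

    round,expert_id,specialty,years_experience,indicator_id,rating,comment

One row per (round, expert, indicator). ``rating`` is a Likert level 1-5 or
empty (missing); missing ratings stay missing at parse time and are only
replaced (by the neutral level 3) when :func:`impute_missing` is called, so
the raw responses remain inspectable.
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd
import yaml

from ._util import round_half_up

logger = logging.getLogger(__name__)

NEUTRAL_RATING = 3

__all__ = [
    "SurveyValidationError",
    "IndicatorCatalog",
    "Expert",
    "Panel",
    "ResponseRecord",
    "RoundDataset",
    "DemographicsReport",
    "read_responses",
    "write_responses",
    "impute_missing",
    "expand_to_panel",
    "build_round_dataset",
    "demographics_report",
]


class SurveyValidationError(ValueError):
    """Raised when a response file violates the survey contract."""


@dataclass(frozen=True)
class IndicatorCatalog:
    """Ordered factors, each holding an ordered list of (id, display name).

    Every indicator belongs to exactly one factor and identifiers are
    globally unique.
    """

    factors: tuple[str, ...]
    indicators: Mapping[str, tuple[tuple[str, str], ...]]  # factor -> ((id, name), ...)

    def __post_init__(self) -> None:
        if tuple(self.indicators) != self.factors:
            raise ValueError("indicators must list the same factors, in order")
        ids = [i for f in self.factors for i, _ in self.indicators[f]]
        if len(ids) != len(set(ids)):
            raise ValueError("indicator identifiers must be unique")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "IndicatorCatalog":
        with open(path, encoding="utf-8") as fh:
            raw = yaml.safe_load(fh)
        factors = tuple(raw["factors"])
        indicators = {
            f: tuple((e["id"], e["name"]) for e in raw["factors"][f]) for f in factors
        }
        return cls(factors=factors, indicators=indicators)

    @classmethod
    def default(cls) -> "IndicatorCatalog":
        from . import datasets

        return datasets.load_catalog()

    def indicator_ids(self) -> list[str]:
        """All indicator ids, in catalog (factor, then position) order."""
        return [i for f in self.factors for i, _ in self.indicators[f]]

    def factor_of(self, indicator_id: str) -> str:
        for f in self.factors:
            if any(i == indicator_id for i, _ in self.indicators[f]):
                return f
        raise KeyError(indicator_id)

    def display_name(self, indicator_id: str) -> str:
        for f in self.factors:
            for i, name in self.indicators[f]:
                if i == indicator_id:
                    return name
        raise KeyError(indicator_id)

    def sort_key(self, indicator_id: str) -> int:
        return self.indicator_ids().index(indicator_id)

    def factor_sizes(self) -> tuple[int, ...]:
        return tuple(len(self.indicators[f]) for f in self.factors)


@dataclass(frozen=True)
class Expert:
    """A panel member; the inclusion criterion is >= 3 years of experience."""

    expert_id: str
    specialty: str
    years_experience: int

    def __post_init__(self) -> None:
        if self.years_experience < 3:
            raise ValueError(
                f"expert {self.expert_id!r}: minimum of three years of "
                f"experience required, got {self.years_experience}"
            )


@dataclass(frozen=True)
class Panel:
    """Deduplicated expert roster with experience-derived weights."""

    experts: tuple[Expert, ...]

    def __post_init__(self) -> None:
        ids = [e.expert_id for e in self.experts]
        if len(ids) != len(set(ids)):
            raise ValueError("expert ids must be unique within a panel")

    def __len__(self) -> int:
        return len(self.experts)

    def __iter__(self):
        return iter(self.experts)

    def expert_ids(self) -> list[str]:
        return [e.expert_id for e in self.experts]

    def total_years(self) -> int:
        return sum(e.years_experience for e in self.experts)

    def weights(self, mode: str = "experience") -> dict[str, float]:
        """Per-expert weight (degree of importance), summing to 1."""
        from .fuzzy_core import expert_weights

        if mode == "uniform":
            w = np.full(len(self.experts), 1.0 / len(self.experts))
        elif mode == "experience":
            w = expert_weights([e.years_experience for e in self.experts])
        else:
            raise ValueError(f"unknown weighting mode {mode!r}")
        return dict(zip(self.expert_ids(), w))


@dataclass(frozen=True)
class ResponseRecord:
    """One expert's rating of one indicator in one round.

    ``rating`` is 1-5 or ``None`` for missing.
    """

    round: int
    expert_id: str
    indicator_id: str
    rating: Optional[int]
    comment: Optional[str] = None

    def __post_init__(self) -> None:
        if self.round < 1:
            raise ValueError("round must be a positive integer")
        if self.rating is not None and self.rating not in (1, 2, 3, 4, 5):
            raise ValueError(f"rating must be 1..5 or missing, got {self.rating!r}")


@dataclass
class RoundDataset:
    """One round's fully imputed rating matrix plus comments.

    ``ratings`` is an experts x items DataFrame of Likert integers with no
    missing values; ``comments`` maps (expert_id, indicator_id) to text.
    """

    round: int
    items: list[str]
    ratings: pd.DataFrame
    comments: dict[tuple[str, str], str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.ratings.isna().any().any():
            raise ValueError("RoundDataset must be fully imputed")


_COLUMNS = [
    "round",
    "expert_id",
    "specialty",
    "years_experience",
    "indicator_id",
    "rating",
    "comment",
]


def read_responses(
    path: str | Path, catalog: IndicatorCatalog
) -> tuple[list[ResponseRecord], Panel]:
    """Parse and validate a canonical responses CSV.

    Returns the record list (file order) and the deduplicated expert
    roster. Raises :class:`SurveyValidationError` naming offending rows for
    unknown indicators, out-of-range ratings, duplicate keys, or experts
    with inconsistent metadata.
    """
    known = set(catalog.indicator_ids())
    records: list[ResponseRecord] = []
    experts: dict[str, Expert] = {}
    errors: list[str] = []
    seen: set[tuple[int, str, str]] = set()

    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        missing_cols = [c for c in _COLUMNS[:-1] if c not in (reader.fieldnames or [])]
        if missing_cols:
            raise SurveyValidationError(f"missing required columns: {missing_cols}")
        for lineno, row in enumerate(reader, start=2):
            ind = row["indicator_id"].strip()
            if ind not in known:
                errors.append(f"row {lineno}: unknown indicator id {ind!r}")
                continue
            raw_rating = (row.get("rating") or "").strip()
            rating: Optional[int]
            if raw_rating == "":
                rating = None
            else:
                try:
                    rating = int(raw_rating)
                except ValueError:
                    errors.append(f"row {lineno}: unparseable rating {raw_rating!r}")
                    continue
                if rating not in (1, 2, 3, 4, 5):
                    errors.append(f"row {lineno}: rating {rating} outside 1..5")
                    continue
            try:
                rnd = int(row["round"])
                years = int(row["years_experience"])
            except ValueError:
                errors.append(f"row {lineno}: round/years_experience not integers")
                continue
            eid = row["expert_id"].strip()
            key = (rnd, eid, ind)
            if key in seen:
                errors.append(f"row {lineno}: duplicate (round, expert, indicator) {key}")
                continue
            seen.add(key)
            try:
                expert = Expert(eid, row["specialty"].strip(), years)
            except ValueError as exc:
                errors.append(f"row {lineno}: {exc}")
                continue
            prev = experts.get(eid)
            if prev is not None and prev != expert:
                errors.append(
                    f"row {lineno}: expert {eid!r} metadata conflicts with earlier rows"
                )
                continue
            experts[eid] = expert
            comment = (row.get("comment") or "").strip() or None
            records.append(ResponseRecord(rnd, eid, ind, rating, comment))

    if errors:
        raise SurveyValidationError("; ".join(errors))
    return records, Panel(tuple(experts.values()))


def write_responses(
    records: Iterable[ResponseRecord], panel: Panel, path: str | Path
) -> None:
    """Write records back to the canonical CSV dialect (round-trip safe)."""
    roster = {e.expert_id: e for e in panel}
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(_COLUMNS)
        for r in records:
            e = roster[r.expert_id]
            writer.writerow(
                [
                    r.round,
                    r.expert_id,
                    e.specialty,
                    e.years_experience,
                    r.indicator_id,
                    "" if r.rating is None else r.rating,
                    r.comment or "",
                ]
            )


def impute_missing(records: Sequence[ResponseRecord]) -> list[ResponseRecord]:
    """Replace every missing rating with the neutral level 3.

    Idempotent; the number of imputations performed is logged.
    """
    out = [
        replace(r, rating=NEUTRAL_RATING) if r.rating is None else r for r in records
    ]
    n = sum(1 for r in records if r.rating is None)
    logger.info("imputed %d missing rating(s) with Neutral (3)", n)
    return out


def expand_to_panel(
    records: Sequence[ResponseRecord],
    panel: Panel,
    round: int,
    items: Sequence[str],
) -> list[ResponseRecord]:
    """Add missing-rating records so every (expert, item) pair is present.

    Experts who did not respond in ``round`` (for example round-2 dropouts)
    are retained with all ratings missing; downstream imputation then maps
    them to Neutral, mirroring how partial response rates are handled in
    multi-round panel studies.
    """
    have = {(r.expert_id, r.indicator_id) for r in records if r.round == round}
    extra = [
        ResponseRecord(round, e.expert_id, item, None)
        for e in panel
        for item in items
        if (e.expert_id, item) not in have
    ]
    if extra:
        logger.info(
            "round %d: padded %d absent (expert, item) pairs with missing ratings",
            round,
            len(extra),
        )
    return list(records) + extra


def build_round_dataset(
    records: Sequence[ResponseRecord],
    panel: Panel,
    round: int,
    items: Optional[Sequence[str]] = None,
) -> RoundDataset:
    """Assemble one round's imputed expert x item rating matrix."""
    rnd = [r for r in records if r.round == round]
    if items is None:
        items = sorted({r.indicator_id for r in rnd})
    rnd = [r for r in rnd if r.indicator_id in set(items)]
    rnd = expand_to_panel(rnd, panel, round, items)
    rnd = impute_missing(rnd)
    mat = pd.DataFrame(
        index=panel.expert_ids(), columns=list(items), dtype=float
    )
    comments: dict[tuple[str, str], str] = {}
    for r in rnd:
        mat.loc[r.expert_id, r.indicator_id] = r.rating
        if r.comment:
            comments[(r.expert_id, r.indicator_id)] = r.comment
    return RoundDataset(round=round, items=list(items), ratings=mat.astype(int), comments=comments)


@dataclass
class DemographicsReport:
    """Panel composition summary in the style of a study's demographics table."""

    panel_size: int
    specialty_counts: dict[str, int]
    specialty_shares: dict[str, float]  # percent, rounded half-up to 2 dp
    response_rates: dict[int, float]  # round -> percent of panel responding
    experience_min: int
    experience_median: float
    experience_max: int
    experience_total: int


def demographics_report(
    panel: Panel, records: Sequence[ResponseRecord]
) -> DemographicsReport:
    """Specialty shares, per-round response rates, and experience summary.

    An expert counts as a respondent in a round if they contributed at
    least one non-missing rating in it (pre-imputation records expected).
    """
    if len(panel) == 0:
        raise ValueError("empty panel")
    counts: dict[str, int] = {}
    for e in panel:
        counts[e.specialty] = counts.get(e.specialty, 0) + 1
    shares = {
        s: round_half_up(100.0 * c / len(panel), 2) for s, c in counts.items()
    }
    rounds = sorted({r.round for r in records})
    rates = {}
    for rnd in rounds:
        responders = {r.expert_id for r in records if r.round == rnd and r.rating is not None}
        rates[rnd] = round_half_up(100.0 * len(responders) / len(panel), 2)
    years = [e.years_experience for e in panel]
    return DemographicsReport(
        panel_size=len(panel),
        specialty_counts=counts,
        specialty_shares=shares,
        response_rates=rates,
        experience_min=min(years),
        experience_median=float(np.median(years)),
        experience_max=max(years),
        experience_total=sum(years),
    )
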