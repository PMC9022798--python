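"""Loaders for the bundled reference fixtures.

The package ships the published per-indicator consensus tables of the
emergency-department surge study (two survey rounds, fuzzy Delphi and
modified fuzzy Delphi columns), the factor-level weighted sentiment scores,
the normal-vs-surge top-5 rankings, the 29-indicator catalog, and a small
default opinion lexicon. The raw panel responses behind these tables were
never published, so the tables serve as regression inputs for the
filtering, retention, and ranking logic rather than as recomputable
outputs.
"""

from __future__ import annotations

from importlib import resources
from pathlib import Path

import pandas as pd

from .survey_io import IndicatorCatalog

__all__ = [
    "load_catalog",
    "load_round1_results",
    "load_round2_results",
    "load_sentiment_scores",
    "load_condition_rankings",
    "default_lexicon_paths",
    "fixture_names",
    "fixture_path",
]

_DATA = resources.files("fuzzydelphi") / "data"

#: published per-round acceptance thresholds (strict >), per method
PUBLISHED_THRESHOLDS = {
    "fdm": {1: 64.0, 2: 70.0},
    "mofd": {1: 53.0, 2: 56.0},
}


def fixture_names() -> list[str]:
    return sorted(p.name for p in _DATA.iterdir())


def fixture_path(name: str) -> Path:
    p = _DATA / name
    if not p.is_file():
        raise FileNotFoundError(name)
    return Path(str(p))


def load_catalog() -> IndicatorCatalog:
    """The default 5-factor, 29-indicator catalog."""
    return IndicatorCatalog.from_yaml(fixture_path("table1_catalog.yaml"))


def _load_round(name: str) -> pd.DataFrame:
    df = pd.read_csv(fixture_path(name))
    return df.set_index("indicator_id")


def load_round1_results() -> pd.DataFrame:
    """First-round published consensus values (all 29 indicators).

    Columns: ``factor``, ``fdm_avg_fuzzy``, ``fdm_consensus``,
    ``mofd_avg_fuzzy``, ``mofd_consensus``; indexed by indicator id.
    """
    return _load_round("table2_round1.csv")


def load_round2_results() -> pd.DataFrame:
    """Second-round published consensus values (the 17 carried-forward items).

    FDM cells are NaN for the items the published table leaves blank.
    """
    return _load_round("table4_round2.csv")


def load_sentiment_scores() -> pd.DataFrame:
    """Published factor-level weighted sentiment scores with labels."""
    return pd.read_csv(fixture_path("table3_sentiment.csv")).set_index("factor")


def load_condition_rankings() -> pd.DataFrame:
    """Published top-5 indicator rankings under normal vs surge conditions."""
    return pd.read_csv(fixture_path("table5_rankings.csv")).set_index("rank")


def default_lexicon_paths() -> tuple[Path, Path]:
    """(positive, negative) paths of the bundled opinion lexicon."""
    return fixture_path("lexicon_positive.txt"), fixture_path("lexicon_negative.txt")
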