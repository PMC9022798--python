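"""Study orchestration: run consensus rounds end to end and emit reports.

``run_round`` executes one round's impute -> fuzzify -> aggregate ->
agreement -> threshold pipeline and optionally writes the per-indicator
CSV, a JSON summary, and the carried-forward item list for the next
round's questionnaire. ``run_study`` chains the configured rounds per
method and appends retention, stability, ranking, sentiment, and
cross-method comparison — the full analysis a multi-round consensus study
reports.

Outputs are deterministic for identical inputs: JSON keys are sorted and
no timestamps enter the payload.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import pandas as pd

from .consensus import (
    MethodComparison,
    MethodConfig,
    RoundOutcome,
    compare_methods,
    evaluate_round,
    retained_set,
)
from .sentiment import Lexicon, SentimentScore, score_comments
from .stability_ranking import (
    RankingResult,
    StabilityResult,
    mann_whitney_u,
    rank_indicators,
)
from .survey_io import (
    IndicatorCatalog,
    Panel,
    ResponseRecord,
    build_round_dataset,
    demographics_report,
)

logger = logging.getLogger(__name__)

__all__ = ["StudyConfig", "StudyReport", "run_round", "run_study"]


@dataclass
class StudyConfig:
    """Everything one study run needs; one config = one reproducible study."""

    catalog: IndicatorCatalog
    methods: Sequence[MethodConfig]
    n_rounds: int = 2
    alpha: float = 0.05
    lexicon: Optional[Lexicon] = None
    out_dir: Optional[Path] = None


def _outcome_frame(
    outcome: RoundOutcome, catalog: IndicatorCatalog
) -> pd.DataFrame:
    rows = []
    for item in sorted(outcome.results, key=catalog.sort_key):
        r = outcome.results[item]
        tfn = r.group_tfn
        rows.append(
            {
                "indicator_id": item,
                "factor": catalog.factor_of(item),
                "l": None if tfn is None else tfn.l,
                "m": None if tfn is None else tfn.m,
                "u": None if tfn is None else tfn.u,
                "defuzzified": r.defuzzified,
                "mean_distance": r.mean_distance,
                "agreement": r.agreement,
                "threshold": r.threshold,
                "accepted": r.accepted,
            }
        )
    return pd.DataFrame(rows)


def run_round(
    records: Sequence[ResponseRecord],
    panel: Panel,
    catalog: IndicatorCatalog,
    config: MethodConfig,
    round: int,
    items: Optional[Sequence[str]] = None,
    out_dir: Optional[Path] = None,
) -> RoundOutcome:
    """Execute one consensus round; optionally write its artifacts."""
    if items is None:
        items = [
            i
            for i in catalog.indicator_ids()
            if any(r.indicator_id == i and r.round == round for r in records)
        ]
    if not items:
        raise ValueError(
            f"no responses found for round {round}; "
            "check the responses file and --round flag"
        )
    dataset = build_round_dataset(records, panel, round, items)
    weights = panel.weights(config.weighting)
    outcome = evaluate_round(dataset, weights, config)
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        stem = f"{config.method}_round{round}"
        _outcome_frame(outcome, catalog).to_csv(out_dir / f"{stem}.csv", index=False)
        summary = {
            "round": outcome.round,
            "method": outcome.method,
            "threshold": outcome.threshold,
            "accepted": outcome.accepted,
            "carried_forward": outcome.carried_forward,
        }
        (out_dir / f"{stem}.json").write_text(
            json.dumps(summary, indent=2, sort_keys=True) + "\n", encoding="utf-8"
        )
        (out_dir / f"{stem}_next_items.txt").write_text(
            "\n".join(outcome.carried_forward) + "\n", encoding="utf-8"
        )
    return outcome


@dataclass
class StudyReport:
    """All computed sections of a full study run."""

    outcomes: dict[str, list[RoundOutcome]]  # method -> per-round
    retained: dict[str, list[str]]
    rankings: dict[str, RankingResult]
    stability: dict[str, StabilityResult]
    sentiment: list[SentimentScore]
    comparison: Optional[MethodComparison]
    demographics: dict = field(default_factory=dict)
    recovery: Optional[dict] = None

    def to_dict(self) -> dict:
        def enc(obj):
            if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
                return {k: enc(v) for k, v in dataclasses.asdict(obj).items()}
            if isinstance(obj, dict):
                return {str(k): enc(v) for k, v in obj.items()}
            if isinstance(obj, (list, tuple)):
                return [enc(v) for v in obj]
            return obj

        return {
            "retained": enc(self.retained),
            "rankings": {
                m: {"order": r.indicators, "ranks": enc(r.ranks)}
                for m, r in self.rankings.items()
            },
            "stability": enc(self.stability),
            "sentiment": enc(self.sentiment),
            "comparison": enc(self.comparison) if self.comparison else None,
            "demographics": enc(self.demographics),
            "recovery": enc(self.recovery),
            "rounds": {
                m: [
                    {
                        "round": o.round,
                        "threshold": o.threshold,
                        "accepted": o.accepted,
                        "carried_forward": o.carried_forward,
                    }
                    for o in outs
                ]
                for m, outs in self.outcomes.items()
            },
        }

    def to_markdown(self) -> str:
        lines = ["# Consensus study report", ""]
        for m, outs in self.outcomes.items():
            lines.append(f"## Method: {m.upper()}")
            for o in outs:
                lines.append(
                    f"- Round {o.round}: threshold >{o.threshold:g}, "
                    f"{len(o.accepted)} accepted, "
                    f"{len(o.carried_forward)} carried forward"
                )
            lines.append(f"- Retained overall: {len(self.retained[m])}")
            if m in self.stability:
                s = self.stability[m]
                lines.append(
                    f"- Stability (Mann-Whitney): U={s.u:g}, z={s.z:.3f}, "
                    f"p={s.p:.4f} -> {'stable' if s.stable else 'shifted'}"
                )
            if m in self.rankings:
                top = self.rankings[m].indicators[:5]
                lines.append(f"- Top 5: {', '.join(top)}")
            lines.append("")
        if self.comparison is not None:
            c = self.comparison
            lines.append(
                f"## Method comparison\n- common: {len(c.common)} "
                f"({', '.join(c.common)})\n- only first: {', '.join(c.only_a) or '-'}"
                f"\n- only second: {', '.join(c.only_b) or '-'}\n"
            )
        if self.sentiment:
            lines.append("## Sentiment by factor")
            for s in self.sentiment:
                lines.append(
                    f"- {s.factor}: neg={s.negative:.3f} pos={s.positive:.3f} "
                    f"-> {s.label}"
                )
            lines.append("")
        if self.recovery:
            r = self.recovery
            lines.append(
                "## Ground-truth recovery\n"
                f"- determinate indicators: {r['n_determinate']}, "
                f"correct: {r['n_correct']} "
                f"({r['accuracy_percent']:.1f}%)\n"
            )
        return "\n".join(lines)


def run_study(
    records: Sequence[ResponseRecord],
    panel: Panel,
    config: StudyConfig,
    ground_truth: Optional[dict[str, str]] = None,
) -> StudyReport:
    """Run every configured method over all rounds and assemble the report.

    Round 1 evaluates the full catalog (restricted to items with
    responses); each later round evaluates the method's carried-forward
    items. When ``ground_truth`` labels are given (synthetic studies), a
    recovery confusion summary is added.
    """
    outcomes: dict[str, list[RoundOutcome]] = {}
    retained: dict[str, list[str]] = {}
    rankings: dict[str, RankingResult] = {}
    stability: dict[str, StabilityResult] = {}
    recovery = None

    for mcfg in config.methods:
        per_round: list[RoundOutcome] = []
        items: Optional[list[str]] = None
        for rnd in range(1, config.n_rounds + 1):
            if not any(r.round == rnd for r in records):
                break
            if items is not None and len(items) == 0:
                logger.info("%s: converged after round %d", mcfg.method, rnd - 1)
                break
            outcome = run_round(
                records, panel, config.catalog, mcfg, rnd, items, config.out_dir
            )
            per_round.append(outcome)
            items = outcome.carried_forward
        outcomes[mcfg.method] = per_round
        retained[mcfg.method] = retained_set(per_round)
        entries = {}
        for o in per_round:
            for ind in o.accepted:
                r = o.results[ind]
                entries[ind] = (r.agreement, r.defuzzified or 0.0)
        if entries:
            rankings[mcfg.method] = rank_indicators(entries, config.catalog)
        if len(per_round) >= 2:
            shared = per_round[1].results.keys()
            x = [per_round[0].results[i].agreement for i in shared]
            y = [per_round[1].results[i].agreement for i in shared]
            stability[mcfg.method] = mann_whitney_u(x, y, config.alpha)
        if ground_truth is not None and mcfg.method == "mofd":
            recovery = _score_recovery(retained[mcfg.method], per_round, ground_truth)

    sentiment_scores: list[SentimentScore] = []
    weights = panel.weights(config.methods[0].weighting if config.methods else "experience")
    r1 = [r for r in records if r.round == 1 and r.comment]
    if r1:
        lex = config.lexicon or Lexicon.default()
        for factor in config.catalog.factors:
            ids = {i for i, _ in config.catalog.indicators[factor]}
            comments: dict[str, str] = {}
            for rec in r1:
                if rec.indicator_id in ids:
                    prev = comments.get(rec.expert_id, "")
                    comments[rec.expert_id] = (prev + " " + rec.comment).strip()
            sentiment_scores.append(score_comments(factor, comments, weights, lex))

    comparison = None
    if len(config.methods) >= 2:
        a, b = config.methods[0].method, config.methods[1].method
        comparison = compare_methods(retained[a], retained[b], config.catalog)

    demo = demographics_report(panel, records)
    report = StudyReport(
        outcomes=outcomes,
        retained=retained,
        rankings=rankings,
        stability=stability,
        sentiment=sentiment_scores,
        comparison=comparison,
        demographics=dataclasses.asdict(demo),
        recovery=recovery,
    )
    if config.out_dir is not None:
        out = Path(config.out_dir)
        out.mkdir(parents=True, exist_ok=True)
        (out / "study_report.json").write_text(
            json.dumps(report.to_dict(), indent=2, sort_keys=True) + "\n",
            encoding="utf-8",
        )
        (out / "study_report.md").write_text(report.to_markdown(), encoding="utf-8")
    return report


def _score_recovery(
    retained: Sequence[str],
    outcomes: Sequence[RoundOutcome],
    labels: dict[str, str],
) -> dict:
    evaluated = set()
    for o in outcomes:
        evaluated.update(o.results)
    kept = set(retained)
    n_det = n_ok = 0
    confusion = {"accept": {"accepted": 0, "rejected": 0}, "reject": {"accepted": 0, "rejected": 0}}
    for ind in sorted(evaluated):
        truth = labels.get(ind, "indeterminate")
        if truth == "indeterminate":
            continue
        n_det += 1
        got = "accepted" if ind in kept else "rejected"
        confusion[truth][got] += 1
        if (truth == "accept") == (ind in kept):
            n_ok += 1
    return {
        "n_determinate": n_det,
        "n_correct": n_ok,
        "accuracy_percent": 100.0 * n_ok / n_det if n_det else float("nan"),
        "confusion": confusion,
    }
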