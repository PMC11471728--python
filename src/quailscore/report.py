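"""Per-farm scorecards and cohort benchmarking.

Benchmarking mirrors how audited cohorts are usually presented: per
criterion and principle the sample mean, sample SD (n-1 denominator),
range and welfare-category counts, plus a per-farm overall listing.
The dot-plot export writes both the figure and its underlying CSV so
the plotted numbers stay testable as data.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Iterable, Literal, Optional

import pandas as pd
from pydantic import BaseModel, ConfigDict, Field

from .aggregate import WelfareAssessment
from .protocol import ProtocolConfig

__all__ = [
    "LevelStats",
    "BenchmarkSummary",
    "benchmark_cohort",
    "benchmark_frame",
    "render_scorecard",
    "export_criterion_dotplot",
]


class LevelStats(BaseModel):
    """Descriptive statistics of one criterion/principle/overall score
    across a cohort."""

    model_config = ConfigDict(frozen=True)

    level: Literal["criterion", "principle", "overall"]
    id: str
    n: int
    mean: float
    sd: float
    min: float
    max: float
    category_counts: dict[str, int] = Field(default_factory=dict)


class BenchmarkSummary(BaseModel):
    model_config = ConfigDict(frozen=True)

    n: int
    criteria: tuple[LevelStats, ...]
    principles: tuple[LevelStats, ...]
    overall: LevelStats
    farms: tuple[tuple[str, float, str], ...]  # (farm_id, overall score, category)


def _stats(level: str, stat_id: str, scores: list[float],
           categories: list[str]) -> LevelStats:
    s = pd.Series(scores, dtype=float)
    counts: dict[str, int] = {}
    for cat in categories:
        counts[cat] = counts.get(cat, 0) + 1
    return LevelStats(
        level=level, id=stat_id, n=len(s),
        mean=float(s.mean()),
        sd=float(s.std(ddof=1)) if len(s) > 1 else 0.0,
        min=float(s.min()), max=float(s.max()),
        category_counts=counts,
    )


def benchmark_cohort(assessments: Iterable[WelfareAssessment]) -> BenchmarkSummary:
    """Cohort statistics at criterion, principle and overall level."""
    assessments = list(assessments)
    if not assessments:
        raise ValueError("cannot benchmark an empty cohort")
    criteria = []
    for cid in [c.criterion_id for c in assessments[0].criterion_results]:
        results = [a.criterion(cid) for a in assessments]
        criteria.append(_stats("criterion", cid,
                               [r.final_score for r in results],
                               [r.category for r in results]))
    principles = []
    for pid in [p.principle_id for p in assessments[0].principle_results]:
        results = [a.principle(pid) for a in assessments]
        principles.append(_stats("principle", pid,
                                 [r.score for r in results],
                                 [r.category for r in results]))
    overall = _stats("overall", "overall",
                     [a.overall_score for a in assessments],
                     [a.overall_category for a in assessments])
    return BenchmarkSummary(
        n=len(assessments),
        criteria=tuple(criteria),
        principles=tuple(principles),
        overall=overall,
        farms=tuple((a.farm_id, a.overall_score, a.overall_category)
                    for a in assessments),
    )


def benchmark_frame(assessments: Iterable[WelfareAssessment]) -> pd.DataFrame:
    """Long per-farm score table (one row per farm x criterion/principle),
    the data behind the criterion dot plots."""
    rows = []
    for a in assessments:
        for r in a.criterion_results:
            rows.append({"farm_id": a.farm_id, "level": "criterion",
                         "id": r.criterion_id, "score": r.final_score,
                         "category": r.category})
        for r in a.principle_results:
            rows.append({"farm_id": a.farm_id, "level": "principle",
                         "id": r.principle_id, "score": r.score,
                         "category": r.category})
        rows.append({"farm_id": a.farm_id, "level": "overall", "id": "overall",
                     "score": a.overall_score, "category": a.overall_category})
    return pd.DataFrame(rows)


def export_criterion_dotplot(assessments: Iterable[WelfareAssessment],
                             out_dir: str | Path,
                             config: Optional[ProtocolConfig] = None,
                             stem: str = "criterion_scores") -> tuple[Path, Path]:
    """Write the per-criterion dot plot (PNG) and its CSV to ``out_dir``;
    returns (csv_path, png_path)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    frame = benchmark_frame(assessments)
    csv_path = out_dir / f"{stem}.csv"
    frame.to_csv(csv_path, index=False)

    crit = frame[frame["level"] == "criterion"]
    ids = list(dict.fromkeys(crit["id"]))
    fig, ax = plt.subplots(figsize=(max(6, 0.8 * len(ids)), 4))
    for x, cid in enumerate(ids):
        ys = crit.loc[crit["id"] == cid, "score"]
        ax.plot([x] * len(ys), ys, "o", alpha=0.6, color="tab:blue")
    for bound in (20, 55, 80):
        ax.axhline(bound, linestyle="--", linewidth=0.8, color="grey")
    ax.set_xticks(range(len(ids)))
    ax.set_xticklabels(ids, rotation=60, ha="right", fontsize=7)
    ax.set_ylabel("criterion score")
    ax.set_ylim(-2, 102)
    fig.tight_layout()
    png_path = out_dir / f"{stem}.png"
    fig.savefig(png_path, dpi=150)
    plt.close(fig)
    return csv_path, png_path


def render_scorecard(assessment: WelfareAssessment,
                     format: Literal["markdown", "json"] = "markdown",
                     config: Optional[ProtocolConfig] = None,
                     certification_threshold: Optional[float] = None) -> str:
    """Human-readable per-farm breakdown.

    Lists every indicator's raw values, matched band and score, the
    itemised criterion deductions, and the certification verdict at the
    (configurable) 55-point threshold with the gap stated.  Rendering
    is presentation-only: scores are rounded to one decimal for display
    but never altered.
    """
    threshold = certification_threshold
    if threshold is None:
        threshold = config.certification_threshold if config else 55.0
    gap = assessment.overall_score - threshold
    certified = gap >= 0
    verdict = (f"certified; {gap:.1f} points above threshold" if certified
               else f"not certified; {-gap:.1f} points below threshold")

    if format == "json":
        payload = assessment.model_dump(mode="json")
        payload["certification"] = {
            "threshold": threshold,
            "certified": certified,
            "verdict": verdict,
        }
        return json.dumps(payload, indent=1)

    lines = [
        f"# Welfare scorecard — farm {assessment.farm_id}",
        "",
        f"Overall score: **{assessment.overall_score:.1f} / 100** "
        f"({assessment.overall_category})",
        f"Certification (threshold {threshold:g}): {verdict}",
        "",
    ]
    if assessment.sampling_issues:
        lines.append("Sampling caveats:")
        lines.extend(f"- {issue}" for issue in assessment.sampling_issues)
        lines.append("")

    lines.append("## Principles")
    for p in assessment.principle_results:
        lines.append(f"- {p.principle_id}: {p.score:.1f} ({p.category})")
    lines.append("")
    lines.append("## Criteria")
    for c in assessment.criterion_results:
        entry = (f"- {c.criterion_id}: {c.final_score:.1f} ({c.category}); "
                 f"base {c.base_score:.1f}")
        if c.modifier_deduction != 0:
            entry += f", modifier deduction {c.modifier_deduction:g}"
        if c.modifier_deduction <= -100:
            entry += " — criterion zeroed by modifier"
        lines.append(entry)
    lines.append("")
    lines.append("## Indicators")
    lines.append("| indicator | score | band | raw values |")
    lines.append("|---|---|---|---|")
    for r in assessment.indicator_results:
        raw = ", ".join(f"{k}={_fmt(v)}" for k, v in r.raw.items())
        band = r.band_label or f"row {r.band_index + 1}"
        lines.append(f"| {r.indicator_id} | {r.score:g} | {band} | {raw} |")
    return "\n".join(lines) + "\n"


def _fmt(value) -> str:
    if value is None:
        return "n/a"
    return f"{value:.4g}"
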