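"""Hierarchical aggregation: indicators -> criteria -> principles -> farm.

The protocol is a fixed-weight linear roll-up.  Within a criterion the
weighted indicators combine as a weighted sum; modifier deductions
(climate registers, surroundings hazards, emergency killing) are then
added and the result clamped to [0, 100] — a -100 modifier therefore
zeroes its criterion regardless of the animal-based score.  Criteria
combine into principles and principles into the overall score with the
published fixed weights (feeding 15%, housing 30%, health 30%,
behaviour 25%).  Scores are kept at full precision; the four-level
welfare category is assigned on the unrounded value with half-open
intervals [0,20), [20,55), [55,80), [80,100].
"""

from __future__ import annotations

from typing import Iterable, Optional

from pydantic import BaseModel, ConfigDict, Field

from .observations import FarmObservation, SamplingReport, validate_sampling
from .protocol import (
    CategoryScale,
    CriterionDefinition,
    PrincipleDefinition,
    ProtocolConfig,
)
from .scoring import IndicatorResult, score_all_indicators

__all__ = [
    "CriterionResult",
    "PrincipleResult",
    "WelfareAssessment",
    "score_criterion",
    "score_principle",
    "score_overall",
    "categorize",
    "assess_farm",
    "SamplingError",
]


class SamplingError(Exception):
    """Strict-mode assessment aborted on an under-sampled audit."""

    def __init__(self, report: SamplingReport):
        self.report = report
        super().__init__(
            "audit does not meet the protocol sampling design:\n"
            + "\n".join(f"  - {i.requirement}: {i.message}" for i in report.issues))


class CriterionResult(BaseModel):
    model_config = ConfigDict(frozen=True)

    criterion_id: str
    base_score: float
    modifier_deduction: float = Field(le=0)
    final_score: float = Field(ge=0, le=100)
    category: str


class PrincipleResult(BaseModel):
    model_config = ConfigDict(frozen=True)

    principle_id: str
    score: float = Field(ge=0, le=100)
    category: str


class WelfareAssessment(BaseModel):
    """Full per-farm scoring breakdown plus the overall verdict."""

    model_config = ConfigDict(frozen=True)

    farm_id: str
    indicator_results: tuple[IndicatorResult, ...]
    criterion_results: tuple[CriterionResult, ...]
    principle_results: tuple[PrincipleResult, ...]
    overall_score: float = Field(ge=0, le=100)
    overall_category: str
    sampling_issues: tuple[str, ...] = ()

    def indicator(self, indicator_id: str) -> IndicatorResult:
        for res in self.indicator_results:
            if res.indicator_id == indicator_id:
                return res
        raise KeyError(indicator_id)

    def criterion(self, criterion_id: str) -> CriterionResult:
        for res in self.criterion_results:
            if res.criterion_id == criterion_id:
                return res
        raise KeyError(criterion_id)

    def principle(self, principle_id: str) -> PrincipleResult:
        for res in self.principle_results:
            if res.principle_id == principle_id:
                return res
        raise KeyError(principle_id)


def categorize(score: float, scale: CategoryScale) -> str:
    """Welfare category of an unrounded score on the half-open scale."""
    if not 0 <= score <= scale.upper:
        raise ValueError(f"score {score} outside [0, {scale.upper}]")
    return scale.label_for(score)


def score_criterion(indicator_results: Iterable[IndicatorResult],
                    criterion: CriterionDefinition,
                    config: ProtocolConfig) -> CriterionResult:
    """Weighted sum of the criterion's weighted indicators, plus the sum
    of its modifier deductions, clamped to [0, 100]."""
    by_id = {r.indicator_id: r for r in indicator_results}
    base = 0.0
    deduction = 0.0
    for iid in criterion.indicators:
        if iid not in by_id:
            raise KeyError(f"criterion {criterion.id!r} is missing a result for "
                           f"indicator {iid!r}")
        ind = config.indicator(iid)
        if ind.role == "weighted":
            base += ind.weight * by_id[iid].score
        else:
            deduction += by_id[iid].score
    final = min(100.0, max(0.0, base + deduction))
    return CriterionResult(
        criterion_id=criterion.id,
        base_score=base,
        modifier_deduction=deduction,
        final_score=final,
        category=categorize(final, config.categories),
    )


def score_principle(criterion_results: Iterable[CriterionResult],
                    principle: PrincipleDefinition,
                    config: ProtocolConfig) -> PrincipleResult:
    """Weighted sum of criterion final scores; no modifiers here."""
    by_id = {r.criterion_id: r for r in criterion_results}
    score = 0.0
    for cid in principle.criteria:
        if cid not in by_id:
            raise KeyError(f"principle {principle.id!r} is missing a result for "
                           f"criterion {cid!r}")
        score += config.criterion(cid).weight * by_id[cid].final_score
    return PrincipleResult(
        principle_id=principle.id,
        score=score,
        category=categorize(score, config.categories),
    )


def score_overall(principle_results: Iterable[PrincipleResult],
                  config: ProtocolConfig,
                  farm_id: str = "",
                  indicator_results: Iterable[IndicatorResult] = (),
                  criterion_results: Iterable[CriterionResult] = (),
                  sampling_issues: Iterable[str] = ()) -> WelfareAssessment:
    """Combine the four principles into the overall score and category."""
    principle_results = tuple(principle_results)
    by_id = {r.principle_id: r for r in principle_results}
    overall = 0.0
    for prin in config.principles:
        if prin.id not in by_id:
            raise KeyError(f"missing principle result {prin.id!r}")
        overall += prin.weight * by_id[prin.id].score
    return WelfareAssessment(
        farm_id=farm_id,
        indicator_results=tuple(indicator_results),
        criterion_results=tuple(criterion_results),
        principle_results=principle_results,
        overall_score=overall,
        overall_category=categorize(overall, config.categories),
        sampling_issues=tuple(sampling_issues),
    )


def assess_farm(obs: FarmObservation, config: ProtocolConfig,
                strict: bool = False,
                sampling_report: Optional[SamplingReport] = None) -> WelfareAssessment:
    """Run the full pipeline on one farm audit.

    With ``strict=True`` an audit that misses the sampling design
    raises :class:`SamplingError` (certification use); otherwise the
    farm is scored anyway and the sampling issues are stamped into the
    assessment.
    """
    report = sampling_report or validate_sampling(obs, config)
    if strict and not report.ok:
        raise SamplingError(report)
    indicator_results = score_all_indicators(obs, config)
    criterion_results = [score_criterion(indicator_results, crit, config)
                         for crit in config.criteria]
    principle_results = [score_principle(criterion_results, prin, config)
                         for prin in config.principles]
    return score_overall(
        principle_results, config,
        farm_id=obs.farm_id,
        indicator_results=indicator_results,
        criterion_results=criterion_results,
        sampling_issues=tuple(f"{i.requirement}: {i.message}" for i in report.issues),
    )
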