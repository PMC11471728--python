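"""Criterion/principle/overall aggregation, modifiers, categorisation."""

import numpy as np
import pytest

from quailscore import assess_farm, categorize, score_overall
from quailscore.aggregate import score_criterion, score_principle
from quailscore.scoring import IndicatorResult


def _results(config, scores: dict[str, float]):
    return [IndicatorResult(indicator_id=iid, score=s, band_index=0)
            for iid, s in scores.items()]


def _principle_result(config, pid, value):
    from quailscore.aggregate import PrincipleResult

    return PrincipleResult(principle_id=pid, score=value,
                           category=categorize(value, config.categories))


def test_weighted_sum_within_criterion(config):
    """Hunger criterion: body 100 (0.60), feeder space 20 (0.30),
    cleanliness 100 (0.10) -> 76."""
    crit = config.criterion("prolonged_hunger")
    res = score_criterion(_results(config, {
        "body_condition": 100, "feeder_space": 20, "feeder_cleanliness": 100}),
        crit, config)
    assert res.final_score == pytest.approx(76.0)


def test_thermal_comfort_modifier_deduction(config):
    """Panting 100 with register ordinal 1 (-45) -> 55; ordinal 2 (-100)
    zeroes the criterion regardless of the panting score."""
    crit = config.criterion("thermal_comfort")
    partial = score_criterion(_results(config, {
        "panting_shivering_huddling": 100, "temperature_registers": -45}),
        crit, config)
    assert partial.final_score == pytest.approx(55.0)
    zeroed = score_criterion(_results(config, {
        "panting_shivering_huddling": 100, "temperature_registers": -100}),
        crit, config)
    assert zeroed.final_score == 0.0


def test_hazard_deduction_on_injuries(config):
    """Five perfect animal-based indicators with 3 hazardous elements
    (-30) -> 70; with -100 the criterion floors at 0."""
    crit = config.criterion("absence_of_injuries")
    base = {iid: 100 for iid in crit.indicators if iid != "risk_of_injuries"}
    res = score_criterion(_results(config, dict(base, risk_of_injuries=-30)),
                          crit, config)
    assert res.final_score == pytest.approx(70.0)
    res = score_criterion(_results(config, dict(base, risk_of_injuries=-100)),
                          crit, config)
    assert res.final_score == 0.0


def test_modifier_dominance(config):
    """Any active modifier can only lower a criterion's final score."""
    rng = np.random.default_rng(5)
    for crit in config.criteria:
        modifiers = [i for i in crit.indicators
                     if config.indicator(i).role == "modifier"]
        if not modifiers:
            continue
        for _ in range(50):
            scores = {iid: float(rng.choice([0, 20, 40, 60, 80, 100]))
                      for iid in crit.indicators
                      if config.indicator(iid).role == "weighted"}
            clean = score_criterion(
                _results(config, dict(scores, **{m: 0 for m in modifiers})),
                crit, config)
            active = score_criterion(
                _results(config, dict(scores, **{m: float(-rng.integers(1, 101))
                                                 for m in modifiers})),
                crit, config)
            assert active.final_score <= clean.final_score


def test_principle_weighted_sum_matches_printed_cohort_means(config):
    """Feeding from the printed criterion means 73.4/50.7 -> 63.2 after
    1-decimal rounding."""
    from quailscore.aggregate import CriterionResult

    results = [
        CriterionResult(criterion_id="prolonged_hunger", base_score=73.4,
                        modifier_deduction=0, final_score=73.4,
                        category="enhanced"),
        CriterionResult(criterion_id="prolonged_thirst", base_score=50.7,
                        modifier_deduction=0, final_score=50.7,
                        category="acceptable"),
    ]
    res = score_principle(results, config.principle("good_feeding"), config)
    assert res.score == pytest.approx(63.185)
    assert round(res.score, 1) == 63.2


def test_overall_is_fixed_weight_dot_product(config):
    prins = [_principle_result(config, pid, val) for pid, val in [
        ("good_feeding", 63.2), ("good_housing", 49.4),
        ("good_health", 62.6), ("appropriate_behaviour", 64.1)]]
    assessment = score_overall(prins, config)
    assert assessment.overall_score == pytest.approx(59.105)
    assert assessment.overall_category == "enhanced"


@pytest.mark.parametrize("value, expected", [
    (0.0, "not acceptable"),
    (19.999, "not acceptable"),
    (20.0, "acceptable"),
    (54.999, "acceptable"),
    (55.0, "enhanced"),      # "at least 55 points" certifies
    (79.999, "enhanced"),
    (80.0, "excellent"),
    (100.0, "excellent"),
])
def test_half_open_category_intervals(config, value, expected):
    assert categorize(value, config.categories) == expected


def test_all_scores_stay_in_range(config):
    """No admissible indicator vector pushes any criterion, principle or
    overall score outside [0, 100]."""
    rng = np.random.default_rng(17)
    for _ in range(200):
        results = []
        for ind in config.indicators:
            if ind.role == "weighted":
                score = float(rng.choice([0, 20, 30, 40, 55, 60, 80, 100]))
            else:
                score = float(-rng.integers(0, 101))
            results.append(IndicatorResult(indicator_id=ind.id, score=score,
                                           band_index=0))
        criterion_results = [score_criterion(results, c, config)
                             for c in config.criteria]
        principle_results = [score_principle(criterion_results, p, config)
                             for p in config.principles]
        assessment = score_overall(principle_results, config,
                                   criterion_results=criterion_results,
                                   indicator_results=results)
        for cr in criterion_results:
            assert 0 <= cr.final_score <= 100
        for pr in principle_results:
            assert 0 <= pr.score <= 100
        assert 0 <= assessment.overall_score <= 100


def test_cohort_mean_commutes_with_aggregation(config):
    """Fixed linear weights: the mean of per-farm overall scores equals
    the overall score of the mean principle scores."""
    from quailscore import generate_cohort, preset_profile

    farms = generate_cohort(6, [(preset_profile("study_like"), 1.0)], seed=99)
    assessments = [assess_farm(f, config) for f in farms]
    mean_overall = float(np.mean([a.overall_score for a in assessments]))
    mean_principles = [
        _principle_result(config, p.id, float(np.mean(
            [a.principle(p.id).score for a in assessments])))
        for p in config.principles]
    assert score_overall(mean_principles, config).overall_score == pytest.approx(
        mean_overall)


def test_assessment_deterministic(config, enhanced_farm):
    a = assess_farm(enhanced_farm, config)
    b = assess_farm(enhanced_farm, config)
    assert a == b
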