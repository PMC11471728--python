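"""Indicator scoring: derived measures, band resolution, table rows."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from quailscore import BirdRecord, FarmRegisters, evaluate_temperature_modifier
from quailscore.observations import (
    FacilityRecord,
    GroupObservation,
    NovelObjectPoint,
    SessionObservation,
)
from quailscore.scoring import (
    MissingMeasureError,
    build_raw_summary,
    classify_novel_object_point,
    derive_facility_measures,
    resolve_band,
    score_all_indicators,
    summarize_bird_prevalences,
    summarize_groups,
    summarize_novel_object,
    summarize_sessions,
)

from oracle import WORSE_WHEN_HIGHER, is_discrete, random_raw


def band_score(config, indicator_id, raw):
    _, band = resolve_band(config.indicator(indicator_id), raw)
    return band.score


# ---------------------------------------------------------------------------
# derived measures


def test_bird_prevalences_basic_arithmetic():
    birds = [BirdRecord(location_id="L1", lean=(i < 5), lameness=0)
             for i in range(250)]
    raw = summarize_bird_prevalences(birds)
    assert raw["lean_pct"] == pytest.approx(2.0)
    assert raw["lameness1_pct"] == 0.0
    assert raw["lameness2_pct"] == 0.0
    assert raw["plumage_soiled1_pct"] is None  # never assessed


def test_bird_prevalences_two_severities():
    birds = ([BirdRecord(location_id="L1", lameness=1)] * 3
             + [BirdRecord(location_id="L1", lameness=2)] * 1
             + [BirdRecord(location_id="L1", lameness=0)] * 196)
    raw = summarize_bird_prevalences(birds)
    assert raw["lameness1_pct"] == pytest.approx(1.5)
    assert raw["lameness2_pct"] == pytest.approx(0.5)


def test_per_condition_denominators():
    """Birds not assessed for a condition drop out of its denominator."""
    birds = ([BirdRecord(location_id="L1", wet=True)] * 2
             + [BirdRecord(location_id="L1", wet=False)] * 98
             + [BirdRecord(location_id="L1", lean=False)] * 100)
    raw = summarize_bird_prevalences(birds)
    assert raw["wet_pct"] == pytest.approx(2.0)
    assert raw["lean_pct"] == 0.0


def test_session_pooling_uses_totals_not_mean_of_rates():
    sessions = [
        SessionObservation(session_index=1, birds_observed=100, sited_count=50,
                           panting_shivering_huddling_count=0),
        SessionObservation(session_index=2, birds_observed=300, sited_count=30,
                           panting_shivering_huddling_count=0),
    ]
    raw = summarize_sessions(sessions)
    # totals: 80/400 = 20%, not the 40%/10% session-rate mean of 25%
    assert raw["sited_pct"] == pytest.approx(20.0)


def test_group_tallies_and_avoidance_pooling():
    groups = [
        GroupObservation(group_id="G1", cough_sneeze_events=2,
                         negative_social_events=0, avoid_still=8,
                         avoid_moving=1, avoid_fleeing=1),
        GroupObservation(group_id="G2", cough_sneeze_events=4,
                         negative_social_events=1, avoid_still=6,
                         avoid_moving=2, avoid_fleeing=2),
    ]
    raw = summarize_groups(groups)
    assert raw["cough_groups1"] == 1  # 1-2 events -> group score 1
    assert raw["cough_groups2"] == 1  # >2 events -> group score 2
    assert raw["negative_social_groups"] == 1
    assert raw["avoidance_moving_pct"] == pytest.approx(15.0)
    assert raw["avoidance_fleeing_pct"] == pytest.approx(15.0)


@pytest.mark.parametrize("a30, a60, expected", [
    (2, 2, 0),   # two approaches within 30 s
    (0, 4, 0),   # four within 60 s
    (1, 1, 1),   # exactly one within 30 s
    (0, 3, 1),   # exactly three within 60 s
    (0, 2, 2),
    (0, 0, 2),
])
def test_novel_object_point_classification(a30, a60, expected):
    point = NovelObjectPoint(point_id="P", approached_within_30s=a30,
                             approached_within_60s=a60)
    assert classify_novel_object_point(point) == expected


def test_facility_derivations():
    facility = FacilityRecord(
        birds_placed=10000, feeder_length_cm=3500, drinking_points=250,
        usable_area_cm2=10000 * 113, litter_scores=(0,) * 10,
        dust_scores=(0, 0, 0))
    registers = FarmRegisters(batch_mortality_pct=(1.0, 2.0, 3.0),
                              batch_firstweek_mortality_pct=(0.5, 1.0, 1.5),
                              culled_count=70, dead_count=30)
    raw = derive_facility_measures(facility, registers)
    assert raw["feeder_space_cm"] == pytest.approx(0.35)
    assert raw["birds_per_drinker"] == pytest.approx(40.0)
    assert raw["stocking_cm2"] == pytest.approx(113.0)
    assert raw["mortality_cycle_pct"] == pytest.approx(2.0)
    assert raw["mortality_firstweek_pct"] == pytest.approx(1.0)
    assert raw["culling_rate_pct"] == pytest.approx(70.0)


def test_culling_rate_undefined_without_registers():
    registers = FarmRegisters(culled_count=0, dead_count=0)
    facility = FacilityRecord(birds_placed=100, feeder_length_cm=100,
                              drinking_points=10, usable_area_cm2=15000)
    raw = derive_facility_measures(facility, registers)
    assert raw["culling_rate_pct"] is None


# ---------------------------------------------------------------------------
# temperature/humidity modifier


@pytest.mark.parametrize("present, thi, tmin, ordinal, deduction", [
    (False, None, None, 2, -100.0),   # no records at all
    (True, 31.0, 6.0, 0, 0.0),
    (True, 35.0, 3.0, 1, -45.0),
    (True, 38.4, 3.0, 1, -45.0),      # rounds to 38 -> still ordinal 1
    (True, 38.6, 3.0, 2, -100.0),     # rounds to 39
    (True, 30.0, 0.5, 2, -100.0),     # cold excursion below 1 degC
    (True, 30.0, 3.0, 1, -45.0),      # cool THI but temp under 5 degC
])
def test_temperature_modifier_ordinals(config, present, thi, tmin, ordinal, deduction):
    registers = FarmRegisters(climate_records_present=present,
                              thi_max=thi, temp_min_c=tmin)
    assert evaluate_temperature_modifier(registers, config) == (ordinal, deduction)


def test_thi_computed_from_temperature_humidity_pairs(config):
    registers = FarmRegisters(climate_records_present=True, temp_min_c=6.0,
                              temp_rh_pairs=((20.0, 60.0), (25.0, 50.0)))
    ordinal, _ = evaluate_temperature_modifier(registers, config)
    # max THI = 0.8*25 + 0.5*(25-14.4) + 46.4 = 71.7 -> heat stress
    assert ordinal == 2


# ---------------------------------------------------------------------------
# band resolution: printed table rows


@pytest.mark.parametrize("indicator_id, raw, expected", [
    # feeding tables
    ("body_condition", {"lean_pct": 0.0}, 100),
    ("body_condition", {"lean_pct": 2.5}, 0),   # boundary: >=2.5 -> 0
    ("feeder_space", {"feeder_space_cm": 0.35}, 60),
    ("feeder_space", {"feeder_space_cm": 0.29}, 0),
    ("birds_per_drinker", {"birds_per_drinker": 25.0}, 100),
    ("birds_per_drinker", {"birds_per_drinker": 46.0}, 0),
    ("feeder_cleanliness", {"feeder_clean_pct": 95.0, "feeder_very_dirty_n": 1.0}, 20),
    ("drinker_function", {"drinker_score0_pct": 100.0, "drinker_leaking_pct": 0.0}, 100),
    ("drinker_function", {"drinker_score0_pct": 90.0, "drinker_leaking_pct": 5.0}, 40),
    ("drinker_function", {"drinker_score0_pct": 40.0, "drinker_leaking_pct": 25.0}, 0),
    # housing tables
    ("sited_birds", {"sited_pct": 50.0}, 100),
    ("stocking_density", {"stocking_cm2": 140.0}, 100),
    ("stocking_density", {"stocking_cm2": 89.0}, 0),
    ("movement_space", {"movement_capable_pct": 60.0}, 55),
    ("litter_quality", {"litter_n1": 2.0, "litter_n2": 0.0, "litter_n3": 0.0,
                        "litter_n4": 0.0}, 80),
    ("litter_quality", {"litter_n1": 0.0, "litter_n2": 5.0, "litter_n3": 2.0,
                        "litter_n4": 1.0}, 20),
    ("dust_sheet", {"dust_n1": 1.0, "dust_n2": 0.0}, 80),
    ("dust_sheet", {"dust_n1": 0.0, "dust_n2": 3.0}, 0),
    ("light_quality", {"light_difficult_n": 0.0, "photoperiod_ok": 0.0}, 0),
    ("panting_shivering_huddling", {"panting_pct": 5.0}, 80),
    # health tables
    ("lameness", {"lameness1_pct": 0.5, "lameness2_pct": 0.0}, 100),
    ("lameness", {"lameness1_pct": 0.5, "lameness2_pct": 2.0}, 20),  # worst dim governs
    ("wounds", {"wounds1_pct": 0.3, "wounds2_pct": 0.3}, 60),
    ("mortality", {"mortality_cycle_pct": 1.5, "mortality_firstweek_pct": 0.8}, 100),
    ("mortality", {"mortality_cycle_pct": 1.5, "mortality_firstweek_pct": 6.0}, 0),
    ("culling", {"culling_rate_pct": 70.0}, 100),
    ("culling", {"culling_rate_pct": None}, 0),   # absence of registers
    ("coughing_sneezing", {"cough_groups1": 0.0, "cough_groups2": 0.0}, 100),
    # behaviour tables
    ("negative_social_behaviour", {"negative_social_groups": 0.0}, 100),
    ("negative_social_behaviour", {"negative_social_groups": 6.0}, 0),
    ("novel_object_test", {"novel_points0": 5.0, "novel_points2": 2.0}, 100),
    ("novel_object_test", {"novel_points0": 0.0, "novel_points2": 9.0}, 0),
    ("outdoor_access", {"outdoor_type": 2.0, "outdoor_capacity_pct": 90.0,
                        "outdoor_covered_pct": 45.0}, 100),
    ("outdoor_access", {"outdoor_type": 1.0, "outdoor_capacity_pct": 60.0,
                        "outdoor_covered_pct": 100.0}, 40),
    ("solar_light", {"solar_ordinal": 1.0}, 55),
    ("staff_training", {"staff_ordinal": 2.0}, 0),
    ("avoidance_distance", {"avoidance_moving_pct": 9.9,
                            "avoidance_fleeing_pct": 28.5}, 60),
    ("avoidance_distance", {"avoidance_moving_pct": 35.0,
                            "avoidance_fleeing_pct": 35.0}, 40),
    ("enrichment_use", {"enrichment_use_ordinal": 2.0}, 30),
])
def test_printed_band_rows(config, indicator_id, raw, expected):
    assert band_score(config, indicator_id, raw) == expected


def test_missing_measure_raises(config):
    with pytest.raises(MissingMeasureError):
        resolve_band(config.indicator("mortality"), {"mortality_cycle_pct": 1.0})


def test_score_all_indicators_covers_protocol(config, study_farm):
    results = score_all_indicators(study_farm, config)
    assert [r.indicator_id for r in results] == [i.id for i in config.indicators]
    for res, ind in zip(results, config.indicators):
        lo, hi = (-100, 0) if ind.role == "modifier" else (0, 100)
        assert lo <= res.score <= hi


def test_scores_independent_of_record_order(config, study_farm):
    shuffled = study_farm.model_copy(update={
        "birds": tuple(reversed(study_farm.birds)),
        "groups": tuple(reversed(study_farm.groups)),
        "sessions": tuple(reversed(study_farm.sessions)),
    })
    a = {r.indicator_id: r.score for r in score_all_indicators(study_farm, config)}
    b = {r.indicator_id: r.score for r in score_all_indicators(shuffled, config)}
    assert a == b


# ---------------------------------------------------------------------------
# monotonicity (randomized sweep + hypothesis spot checks)


def test_worsening_any_single_dimension_never_raises_score(config):
    """For every indicator, worsening one raw dimension while the others
    stay fixed never increases the awarded score."""
    rng = np.random.default_rng(20240901)
    for ind in config.indicators:
        dims = sorted({c.measure for b in ind.bands for c in b.when})
        for _ in range(400):
            raw = random_raw(rng, ind.measures)
            base = resolve_band(ind, raw)[1].score
            dim = dims[rng.integers(len(dims))]
            worse = dict(raw)
            amount = (float(rng.integers(1, 4)) if is_discrete(dim)
                      else float(rng.uniform(0.1, 30.0)))
            if dim in WORSE_WHEN_HIGHER:
                worse[dim] = raw[dim] + amount
            else:
                worse[dim] = max(0.0, raw[dim] - amount)
            after = resolve_band(ind, worse)[1].score
            assert after <= base, (ind.id, dim, raw[dim], worse[dim], base, after)


@settings(max_examples=300, deadline=None, derandomize=True)
@given(s1=st.floats(0, 40), s2=st.floats(0, 40),
       worse_by=st.floats(0.01, 20), dim=st.sampled_from(["s1", "s2"]))
def test_lameness_monotone_property(config, s1, s2, worse_by, dim):
    ind = config.indicator("lameness")
    raw = {"lameness1_pct": s1, "lameness2_pct": s2}
    base = resolve_band(ind, raw)[1].score
    key = "lameness1_pct" if dim == "s1" else "lameness2_pct"
    worse = dict(raw, **{key: raw[key] + worse_by})
    assert resolve_band(ind, worse)[1].score <= base


@settings(max_examples=300, deadline=None, derandomize=True)
@given(space=st.floats(0.1, 0.6), shrink=st.floats(0.001, 0.3))
def test_feeder_space_monotone_property(config, space, shrink):
    ind = config.indicator("feeder_space")
    before = resolve_band(ind, {"feeder_space_cm": space})[1].score
    after = resolve_band(ind, {"feeder_space_cm": space - shrink})[1].score
    assert after <= before


def test_band_raw_values_recorded_for_audit_trail(config):
    from quailscore.scoring import score_indicator

    result = score_indicator(config.indicator("mortality"),
                             {"mortality_cycle_pct": 2.5,
                              "mortality_firstweek_pct": 1.1})
    assert result.score == 80
    assert result.raw == {"mortality_cycle_pct": 2.5, "mortality_firstweek_pct": 1.1}
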