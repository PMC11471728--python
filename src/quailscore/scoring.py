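"""Raw-summary computation and band resolution for the 36 indicators.

The pipeline from audit data to indicator scores has two halves:

1. *Derived measures* — bird-level prevalences (per-condition
   denominators, so a condition not assessed on some birds simply
   shrinks that condition's denominator), pooled session percentages
   (totals over sessions, weighted by the birds each session observed),
   group tallies, novel-object point ordinals, facility ratios
   (feeder cm/bird, birds/drinker, usable cm²/bird) and register
   summaries (12-month mortality means, the culling rate
   culled/(culled+dead)×100, the THI/temperature ordinal).
2. *Band resolution* — each indicator's band rows are scanned best
   score first and the first row whose conjunctive conditions all hold
   wins; the trailing fallback row matches anything.  With the shipped
   config this scan is equivalent to worst-of-dimensions resolution of
   the compound "and/or" table rows.
"""

from __future__ import annotations

from typing import Iterable, Optional

from pydantic import BaseModel, ConfigDict, Field

from .observations import (
    BirdRecord,
    FacilityRecord,
    FarmObservation,
    FarmRegisters,
    GroupObservation,
    NovelObjectPoint,
    SessionObservation,
)
from .protocol import Band, IndicatorDefinition, ProtocolConfig, ThiModifierConfig

__all__ = [
    "IndicatorResult",
    "RawSummary",
    "summarize_bird_prevalences",
    "summarize_sessions",
    "summarize_groups",
    "summarize_novel_object",
    "derive_facility_measures",
    "evaluate_temperature_modifier",
    "compute_thi",
    "build_raw_summary",
    "resolve_band",
    "score_indicator",
    "score_all_indicators",
    "classify_novel_object_point",
    "MissingMeasureError",
]

RawSummary = dict[str, Optional[float]]


class MissingMeasureError(KeyError):
    """An indicator needs a measure the raw summary does not carry."""


class IndicatorResult(BaseModel):
    """One indicator's outcome: the raw values it consumed, the matched
    band and the awarded score (0..100 weighted, -100..0 modifier)."""

    model_config = ConfigDict(frozen=True)

    indicator_id: str
    score: float
    band_index: int
    band_label: Optional[str] = None
    raw: dict[str, Optional[float]] = Field(default_factory=dict)


# ---------------------------------------------------------------------------
# derived measures


def _prevalence(values: Iterable[Optional[int | bool]], positive) -> tuple[Optional[float], ...]:
    """Percent of assessed birds at each positive level; None when no
    bird was assessed for the condition."""
    assessed = [v for v in values if v is not None]
    if not assessed:
        return tuple(None for _ in positive)
    n = len(assessed)
    return tuple(100.0 * sum(1 for v in assessed if v == level) / n for level in positive)


def summarize_bird_prevalences(birds: Iterable[BirdRecord]) -> RawSummary:
    """Prevalence (%) of every bird-level condition at each severity."""
    birds = list(birds)
    out: RawSummary = {}
    out["lean_pct"], = _prevalence((b.lean for b in birds), (True,))
    out["plumage_soiled1_pct"], out["plumage_soiled2_pct"] = _prevalence(
        (b.plumage_cleanliness for b in birds), (1, 2))
    out["wet_pct"], = _prevalence((b.wet for b in birds), (True,))
    out["wounds1_pct"], out["wounds2_pct"] = _prevalence(
        (b.wounds for b in birds), (1, 2))
    out["lameness1_pct"], out["lameness2_pct"] = _prevalence(
        (b.lameness for b in birds), (1, 2))
    out["footpad1_pct"], out["footpad2_pct"] = _prevalence(
        (b.footpad for b in birds), (1, 2))
    out["toe_damage_pct"], = _prevalence((b.toe_damage for b in birds), (2,))
    out["hock1_pct"], out["hock2_pct"] = _prevalence(
        (b.hock_burn for b in birds), (1, 2))
    out["plumage_damage1_pct"], out["plumage_damage2_pct"] = _prevalence(
        (b.plumage_damage for b in birds), (1, 2))
    out["discharge_pct"], = _prevalence((b.discharge for b in birds), (True,))
    out["diarrhoea_pct"], = _prevalence((b.diarrhoea for b in birds), (True,))
    return out


def summarize_sessions(sessions: Iterable[SessionObservation]) -> RawSummary:
    """Pool session counts as totals over all sessions (weighting each
    session by the birds it observed), not means of session rates."""
    sessions = list(sessions)
    total = sum(s.birds_observed for s in sessions)
    if total == 0:
        return {"sited_pct": None, "panting_pct": None, "enrichment_active_pct": None}
    return {
        "sited_pct": 100.0 * sum(s.sited_count for s in sessions) / total,
        "panting_pct": 100.0 * sum(s.panting_shivering_huddling_count
                                   for s in sessions) / total,
        "enrichment_active_pct": 100.0 * sum(s.enrichment_active_count
                                             for s in sessions) / total,
    }


def summarize_groups(groups: Iterable[GroupObservation]) -> RawSummary:
    """Group tallies: coughing/sneezing group ordinals (1-2 events ->
    score 1, >2 -> score 2), groups with any negative-social event, and
    pooled avoidance-distance percentages over all birds counted."""
    groups = list(groups)
    cough1 = sum(1 for g in groups if 1 <= g.cough_sneeze_events <= 2)
    cough2 = sum(1 for g in groups if g.cough_sneeze_events > 2)
    negative = sum(1 for g in groups if g.negative_social_events > 0)
    total_birds = sum(g.group_size for g in groups)
    out: RawSummary = {
        "cough_groups1": float(cough1),
        "cough_groups2": float(cough2),
        "negative_social_groups": float(negative),
    }
    if total_birds:
        out["avoidance_still_pct"] = 100.0 * sum(g.avoid_still for g in groups) / total_birds
        out["avoidance_moving_pct"] = 100.0 * sum(g.avoid_moving for g in groups) / total_birds
        out["avoidance_fleeing_pct"] = 100.0 * sum(g.avoid_fleeing for g in groups) / total_birds
    else:
        out["avoidance_still_pct"] = None
        out["avoidance_moving_pct"] = None
        out["avoidance_fleeing_pct"] = None
    return out


def classify_novel_object_point(point: NovelObjectPoint) -> int:
    """Per-point novel-object ordinal: >=2 approaches within 30 s or
    >=4 within 60 s -> 0 (curious); exactly 1 within 30 s or 3 within
    60 s -> 1; anything else -> 2 (fearful)."""
    if point.approached_within_30s >= 2 or point.approached_within_60s >= 4:
        return 0
    if point.approached_within_30s == 1 or point.approached_within_60s == 3:
        return 1
    return 2


def summarize_novel_object(points: Iterable[NovelObjectPoint]) -> RawSummary:
    ordinals = [classify_novel_object_point(p) for p in points]
    return {
        "novel_points0": float(ordinals.count(0)),
        "novel_points1": float(ordinals.count(1)),
        "novel_points2": float(ordinals.count(2)),
    }


def _tally_pct(tallies: tuple[int, ...], index: int) -> Optional[float]:
    total = sum(tallies)
    return 100.0 * tallies[index] / total if total else None


def derive_facility_measures(facility: FacilityRecord,
                             registers: FarmRegisters) -> RawSummary:
    """Facility ratios and register summaries.

    Feeder space is trough cm per bird placed; birds per drinker and
    stocking density likewise use the day-0 placement count.  The
    culling rate is culled/(culled+dead)x100 over the last 12 months
    and is None (flagged: no usable registers) when culled+dead = 0.
    """
    out: RawSummary = {}
    out["feeder_space_cm"] = facility.feeder_length_cm / facility.birds_placed
    out["birds_per_drinker"] = facility.birds_placed / facility.drinking_points
    out["stocking_cm2"] = facility.usable_area_cm2 / facility.birds_placed

    out["feeder_clean_pct"] = _tally_pct(facility.feeder_cleanliness_tallies, 0)
    out["feeder_very_dirty_n"] = float(facility.feeder_cleanliness_tallies[2])
    out["drinker_score0_pct"] = _tally_pct(facility.drinker_condition_tallies, 0)
    out["drinker_leaking_pct"] = 100.0 * facility.drinker_leaking_fraction
    out["drinker_clean_pct"] = _tally_pct(facility.drinker_cleanliness_tallies, 0)

    for level in (1, 2, 3, 4):
        out[f"litter_n{level}"] = float(sum(1 for s in facility.litter_scores
                                            if s == level))
    for level in (1, 2):
        out[f"dust_n{level}"] = float(sum(1 for s in facility.dust_scores
                                          if s == level))
    out["light_difficult_n"] = float(facility.light_difficulty_locations)
    out["photoperiod_ok"] = float(facility.light_hours >= 8
                                  and facility.dark_hours >= 8)
    out["movement_capable_pct"] = 100.0 * facility.movement_capable_fraction
    out["hazard_n"] = float(facility.hazard_elements)
    out["outdoor_type"] = float({"none": 0, "winter_garden": 1,
                                 "range": 2}[facility.outdoor])
    out["outdoor_capacity_pct"] = 100.0 * facility.outdoor_capacity_fraction
    out["outdoor_covered_pct"] = 100.0 * facility.outdoor_covered_fraction
    out["solar_ordinal"] = float(facility.solar_light_score)
    out["staff_ordinal"] = float(facility.staff_training_score)
    out["emergency_ordinal"] = float(facility.emergency_killing_score)
    out["enrichment_use_ordinal"] = float(
        facility.enrichment_use_score if facility.enrichment_present else 3)

    batches = registers.batch_mortality_pct
    first = registers.batch_firstweek_mortality_pct
    out["mortality_cycle_pct"] = sum(batches) / len(batches) if batches else None
    out["mortality_firstweek_pct"] = sum(first) / len(first) if first else None
    died = registers.culled_count + registers.dead_count
    out["culling_rate_pct"] = (100.0 * registers.culled_count / died
                               if died > 0 else None)
    return out


def compute_thi(temp_c: float, rh_pct: float) -> float:
    """Temperature-humidity index from dry-bulb temperature (deg C) and
    relative humidity (%), NRC-style livestock formulation:
    ``0.8 T + (RH/100)(T - 14.4) + 46.4``."""
    return 0.8 * temp_c + (rh_pct / 100.0) * (temp_c - 14.4) + 46.4


def evaluate_temperature_modifier(registers: FarmRegisters,
                                  config: ProtocolConfig | ThiModifierConfig
                                  ) -> tuple[int, float]:
    """Ordinal (0/1/2) and deduction (0/-45/-100) of the climate-register
    modifier.

    Absent records score ordinal 2 outright.  Otherwise the maximum THI
    over the last 15 pre-slaughter days (supplied directly or computed
    from (T, RH) pairs) is rounded to the nearest integer: below 32
    with minimum temperature never under 5 degC is ordinal 0; up to 38
    with minimum temperature never under 1 degC is ordinal 1; a THI of
    39 or more, or any colder excursion, is ordinal 2.
    """
    cfg = config.thi_modifier if isinstance(config, ProtocolConfig) else config
    if not registers.climate_records_present:
        return 2, cfg.deductions[2]
    thi = registers.thi_max
    if thi is None:
        thi = max(compute_thi(t, rh) for t, rh in registers.temp_rh_pairs)
    thi = round(thi)
    tmin = registers.temp_min_c if registers.temp_min_c is not None else float("-inf")
    if thi < cfg.thi_comfort_max and tmin >= cfg.temp_comfort_min_c:
        return 0, cfg.deductions[0]
    if thi <= cfg.thi_warning_max and tmin >= cfg.temp_warning_min_c:
        return 1, cfg.deductions[1]
    return 2, cfg.deductions[2]


def build_raw_summary(obs: FarmObservation, config: ProtocolConfig) -> RawSummary:
    """Assemble the complete measure map an audit yields."""
    raw: RawSummary = {}
    raw.update(summarize_bird_prevalences(obs.birds))
    raw.update(summarize_sessions(obs.sessions))
    raw.update(summarize_groups(obs.groups))
    raw.update(summarize_novel_object(obs.novel_object_points))
    raw.update(derive_facility_measures(obs.facility, obs.registers))
    ordinal, _ = evaluate_temperature_modifier(obs.registers, config)
    raw["thi_ordinal"] = float(ordinal)
    return raw


# ---------------------------------------------------------------------------
# band resolution


def resolve_band(indicator: IndicatorDefinition, raw: RawSummary) -> tuple[int, Band]:
    """Scan the indicator's bands best-to-worst and return the first
    whose conditions all hold (index, band).  The fallback matches
    anything; a measure missing from ``raw`` entirely raises
    :class:`MissingMeasureError` (None values are legal and simply fail
    every condition, falling through to the fallback)."""
    for key in indicator.measures:
        if key not in raw:
            raise MissingMeasureError(
                f"indicator {indicator.id!r} needs measure {key!r} "
                "absent from the raw summary")
    for index, band in enumerate(indicator.bands):
        if band.matches(raw):
            return index, band
    raise AssertionError(f"no band matched for {indicator.id!r}")  # pragma: no cover


def score_indicator(indicator: IndicatorDefinition, raw: RawSummary) -> IndicatorResult:
    index, band = resolve_band(indicator, raw)
    return IndicatorResult(
        indicator_id=indicator.id,
        score=band.score,
        band_index=index,
        band_label=band.label,
        raw={key: raw.get(key) for key in indicator.measures},
    )


def score_all_indicators(obs: FarmObservation,
                         config: ProtocolConfig) -> list[IndicatorResult]:
    """Score every indicator of the protocol, in config order."""
    raw = build_raw_summary(obs, config)
    return [score_indicator(ind, raw) for ind in config.indicators]
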