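"""Independent band-resolution oracles and randomized raw generators.

Two alternative interpreters of the scoring tables, used to cross-check
the engine's best-to-worst conjunctive scan:

* ``literal_row_score`` re-evaluates every band row with its own tiny
  comparator and returns the best-scoring row that matches — a direct
  reading of "find the best row whose conditions hold".
* ``worst_of_dimensions_score`` resolves each severity dimension
  separately (best row whose bound on that dimension is met) and takes
  the worst dimension — the resolution rule compound "and/or" rows
  describe.  Only meaningful where every non-fallback row bounds every
  dimension.
"""

from __future__ import annotations

import numpy as np

# measures where a larger value means worse welfare; everything else is
# better when larger
WORSE_WHEN_HIGHER = {
    "lean_pct", "plumage_soiled1_pct", "plumage_soiled2_pct", "wet_pct",
    "wounds1_pct", "wounds2_pct", "lameness1_pct", "lameness2_pct",
    "footpad1_pct", "footpad2_pct", "toe_damage_pct", "hock1_pct", "hock2_pct",
    "plumage_damage1_pct", "plumage_damage2_pct", "discharge_pct",
    "diarrhoea_pct", "panting_pct", "avoidance_moving_pct",
    "avoidance_fleeing_pct", "drinker_leaking_pct", "mortality_cycle_pct",
    "mortality_firstweek_pct", "birds_per_drinker", "feeder_very_dirty_n",
    "litter_n1", "litter_n2", "litter_n3", "litter_n4", "dust_n1", "dust_n2",
    "light_difficult_n", "hazard_n", "cough_groups1", "cough_groups2",
    "negative_social_groups", "novel_points2", "thi_ordinal",
    "emergency_ordinal", "solar_ordinal", "staff_ordinal",
    "enrichment_use_ordinal",
}

# sampling ranges for randomized raw summaries, keyed by measure
_RANGES = {
    "feeder_space_cm": (0.2, 0.5),
    "birds_per_drinker": (10.0, 60.0),
    "stocking_cm2": (70.0, 170.0),
    "mortality_cycle_pct": (0.0, 14.0),
    "mortality_firstweek_pct": (0.0, 7.0),
    "culling_rate_pct": (0.0, 100.0),
    "sited_pct": (0.0, 70.0),
    "panting_pct": (0.0, 60.0),
}
_COUNT_MEASURES = {
    "feeder_very_dirty_n", "litter_n1", "litter_n2", "litter_n3", "litter_n4",
    "dust_n1", "dust_n2", "light_difficult_n", "hazard_n", "cough_groups1",
    "cough_groups2", "negative_social_groups", "novel_points0", "novel_points2",
}
_ORDINAL_MAX = {
    "thi_ordinal": 2, "emergency_ordinal": 2, "solar_ordinal": 2,
    "staff_ordinal": 2, "enrichment_use_ordinal": 3, "outdoor_type": 2,
    "photoperiod_ok": 1,
}


def is_discrete(measure: str) -> bool:
    """Counts and ordinals move in integer steps when perturbed."""
    return measure in _COUNT_MEASURES or measure in _ORDINAL_MAX


def random_raw(rng: np.random.Generator, measures) -> dict[str, float]:
    """One random raw summary covering the given measures, mixing exact
    zeros (band-edge relevant) with continuous draws."""
    raw = {}
    for key in measures:
        if key in _ORDINAL_MAX:
            raw[key] = float(rng.integers(0, _ORDINAL_MAX[key] + 1))
        elif key in _COUNT_MEASURES:
            raw[key] = float(rng.integers(0, 12))
        elif key in _RANGES:
            lo, hi = _RANGES[key]
            raw[key] = 0.0 if (lo == 0 and rng.random() < 0.15) else float(rng.uniform(lo, hi))
        elif key.endswith("_pct"):
            raw[key] = 0.0 if rng.random() < 0.3 else float(rng.uniform(0.0, 100.0))
        else:  # pragma: no cover - every measure should be classified
            raise KeyError(key)
    return raw


def _holds(value: float, op: str, bound: float) -> bool:
    return {"<": value < bound, "<=": value <= bound, ">=": value >= bound,
            ">": value > bound, "==": value == bound}[op]


def literal_row_score(indicator, raw: dict[str, float]) -> float:
    """Best score over all rows whose printed conditions all hold."""
    best = None
    for band in indicator.bands:
        if band.fallback or all(_holds(raw[c.measure], c.op, c.value)
                                for c in band.when):
            if best is None or band.score > best:
                best = band.score
    return best


def worst_of_dimensions_score(indicator, raw: dict[str, float]) -> float:
    """Per severity dimension, the best row whose bound on that dimension
    holds; the matched row is the worst of the per-dimension matches."""
    dims = sorted({c.measure for b in indicator.bands for c in b.when})
    worst = None
    for dim in dims:
        dim_score = None
        for band in indicator.bands:
            conds = [c for c in band.when if c.measure == dim]
            if band.fallback:
                matched = True
            elif not conds:
                continue  # row does not bound this dimension
            else:
                matched = all(_holds(raw[dim], c.op, c.value) for c in conds)
            if matched:
                dim_score = band.score
                break
        if worst is None or dim_score < worst:
            worst = dim_score
    return worst


def fully_dimensioned(indicator) -> bool:
    """True when every non-fallback row bounds every dimension, i.e. the
    worst-of-dimensions reading is well-defined for the indicator."""
    dims = {c.measure for b in indicator.bands for c in b.when}
    return all({c.measure for c in band.when} == dims
               for band in indicator.bands if not band.fallback)
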