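"""Declarative protocol model for the quail welfare assessment.

The scoring engine is data-driven: the whole assessment protocol — the
principle/criterion/indicator hierarchy with its fixed weights, every
threshold band of the scoring tables, the penalty modifiers and the
welfare-category scale — lives in one declarative config document
(YAML or JSON).  The meat-quail protocol ships as the bundled default
(``data/quail_meat_v1.yaml``); revised protocol versions are new config
files, not new code.

An *indicator* is either ``weighted`` (scores 0–100, contributing its
weight to the criterion's weighted sum) or a ``modifier`` (scores in
[−100, 0], applied as a deduction after the weighted sum).  Each
indicator carries an ordered list of :class:`Band` rows, best score
first, whose conjunctive conditions are tested against the farm's raw
summary measures; the last band is a catch-all fallback.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Literal, Optional

import yaml
from pydantic import BaseModel, ConfigDict, Field, model_validator

__all__ = [
    "BandCondition",
    "Band",
    "IndicatorDefinition",
    "CriterionDefinition",
    "PrincipleDefinition",
    "CategoryScale",
    "ThiModifierConfig",
    "SamplingDesign",
    "ProtocolConfig",
    "ValidationIssue",
    "ValidationReport",
    "MEASURE_UNITS",
    "load_protocol_config",
    "save_protocol_config",
    "validate_protocol_config",
    "default_protocol_config",
    "protocol_json_schema",
    "ProtocolError",
    "ProtocolValidationError",
]

Comparator = Literal["<", "<=", ">=", ">", "=="]

#: Registry of raw summary measures and their units.  Band conditions may
#: only reference keys listed here; a condition's unit tag (if given)
#: must match the measure's declared unit.
MEASURE_UNITS: dict[str, str] = {
    # bird-level prevalences (% of birds assessed for the condition)
    "lean_pct": "%",
    "plumage_soiled1_pct": "%",
    "plumage_soiled2_pct": "%",
    "wet_pct": "%",
    "wounds1_pct": "%",
    "wounds2_pct": "%",
    "lameness1_pct": "%",
    "lameness2_pct": "%",
    "footpad1_pct": "%",
    "footpad2_pct": "%",
    "toe_damage_pct": "%",
    "hock1_pct": "%",
    "hock2_pct": "%",
    "plumage_damage1_pct": "%",
    "plumage_damage2_pct": "%",
    "discharge_pct": "%",
    "diarrhoea_pct": "%",
    # pooled session observations
    "sited_pct": "%",
    "panting_pct": "%",
    "enrichment_active_pct": "%",
    # group observations
    "cough_groups1": "count",
    "cough_groups2": "count",
    "negative_social_groups": "count",
    "avoidance_still_pct": "%",
    "avoidance_moving_pct": "%",
    "avoidance_fleeing_pct": "%",
    # novel object test point tallies
    "novel_points0": "count",
    "novel_points1": "count",
    "novel_points2": "count",
    # facility-derived
    "feeder_space_cm": "cm/bird",
    "feeder_clean_pct": "%",
    "feeder_very_dirty_n": "count",
    "birds_per_drinker": "birds/drinker",
    "drinker_score0_pct": "%",
    "drinker_leaking_pct": "%",
    "drinker_clean_pct": "%",
    "litter_n1": "count",
    "litter_n2": "count",
    "litter_n3": "count",
    "litter_n4": "count",
    "dust_n1": "count",
    "dust_n2": "count",
    "light_difficult_n": "count",
    "photoperiod_ok": "flag",
    "stocking_cm2": "cm2/bird",
    "movement_capable_pct": "%",
    "hazard_n": "count",
    "outdoor_type": "ordinal",
    "outdoor_capacity_pct": "%",
    "outdoor_covered_pct": "%",
    "solar_ordinal": "ordinal",
    "staff_ordinal": "ordinal",
    "emergency_ordinal": "ordinal",
    "enrichment_use_ordinal": "ordinal",
    # register-derived
    "mortality_cycle_pct": "%",
    "mortality_firstweek_pct": "%",
    "culling_rate_pct": "%",
    "thi_ordinal": "ordinal",
}


class ProtocolError(Exception):
    """Raised when a protocol config cannot be parsed or loaded."""


class ProtocolValidationError(ProtocolError):
    """Raised when a parsed config violates protocol invariants."""

    def __init__(self, report: "ValidationReport"):
        self.report = report
        super().__init__(
            "invalid protocol config:\n"
            + "\n".join(f"  - {i.path}: {i.message}" for i in report.issues)
        )


class BandCondition(BaseModel):
    """One threshold test of a band row, e.g. ``lean_pct < 0.5``."""

    model_config = ConfigDict(frozen=True, extra="forbid")

    measure: str
    op: Comparator
    value: float
    unit: Optional[str] = None

    def holds(self, raw: dict[str, object]) -> bool:
        """Evaluate against a raw-summary mapping; a missing or None
        measure value never satisfies a condition."""
        x = raw.get(self.measure)
        if x is None or not isinstance(x, (int, float)):
            return False
        if self.op == "<":
            return x < self.value
        if self.op == "<=":
            return x <= self.value
        if self.op == ">=":
            return x >= self.value
        if self.op == ">":
            return x > self.value
        return x == self.value


class Band(BaseModel):
    """One scoring-table row: conjunctive conditions -> fixed score.

    Bands are listed best score first; the fallback band ("any other
    case/situation") has no conditions and matches anything.
    """

    model_config = ConfigDict(frozen=True, extra="forbid")

    score: float = Field(ge=-100, le=100)
    when: tuple[BandCondition, ...] = ()
    fallback: bool = False
    label: Optional[str] = None

    @model_validator(mode="after")
    def _fallback_has_no_conditions(self) -> "Band":
        if self.fallback and self.when:
            raise ValueError("fallback band must not carry conditions")
        return self

    def matches(self, raw: dict[str, object]) -> bool:
        return self.fallback or all(c.holds(raw) for c in self.when)


class SamplingRequirement(BaseModel):
    model_config = ConfigDict(frozen=True, extra="forbid")

    birds: Optional[int] = None
    locations: Optional[int] = None
    groups: Optional[int] = None
    sessions: Optional[int] = None
    points: Optional[int] = None


class IndicatorDefinition(BaseModel):
    model_config = ConfigDict(frozen=True, extra="forbid")

    id: str
    name: str
    basis: Literal["animal", "resource"]
    role: Literal["weighted", "modifier"]
    #: fraction of the criterion for weighted indicators; -1.0 marks a
    #: modifier (the tables print modifiers as "-100%").
    weight: float
    measures: tuple[str, ...]
    bands: tuple[Band, ...]
    sampling: Optional[SamplingRequirement] = None


class CriterionDefinition(BaseModel):
    model_config = ConfigDict(frozen=True, extra="forbid")

    id: str
    name: str
    weight: float = Field(gt=0, le=1)
    indicators: tuple[str, ...]


class PrincipleDefinition(BaseModel):
    model_config = ConfigDict(frozen=True, extra="forbid")

    id: str
    name: str
    weight: float = Field(gt=0, le=1)
    criteria: tuple[str, ...]


class CategoryBound(BaseModel):
    model_config = ConfigDict(frozen=True, extra="forbid")

    label: str
    lower: float = Field(ge=0, le=100)


class CategoryScale(BaseModel):
    """Ordered welfare categories with half-open lower bounds.

    The default scale is not acceptable [0,20), acceptable [20,55),
    enhanced [55,80), excellent [80,100].
    """

    model_config = ConfigDict(frozen=True, extra="forbid")

    levels: tuple[CategoryBound, ...]
    upper: float = 100.0

    def label_for(self, score: float) -> str:
        """Category label of an (unrounded) score in [0, upper]."""
        label = self.levels[0].label
        for level in self.levels:
            if score >= level.lower:
                label = level.label
        return label


class ThiModifierConfig(BaseModel):
    """Thresholds of the temperature/humidity-register modifier.

    THI values are rounded to the nearest integer before comparison:
    ordinal 0 requires rounded THI < ``thi_comfort_max`` and a minimum
    temperature never below ``temp_comfort_min_c``; ordinal 1 requires
    rounded THI <= ``thi_warning_max`` and minimum temperature never
    below ``temp_warning_min_c``; anything else — including absent
    climate records — is ordinal 2.
    """

    model_config = ConfigDict(frozen=True, extra="forbid")

    thi_comfort_max: float = 32.0
    thi_warning_max: float = 38.0
    temp_comfort_min_c: float = 5.0
    temp_warning_min_c: float = 1.0
    deductions: tuple[float, float, float] = (0.0, -45.0, -100.0)
    thi_formula: str = "nrc"


class SamplingDesign(BaseModel):
    """Minimum audit sampling effort required by the protocol."""

    model_config = ConfigDict(frozen=True, extra="forbid")

    min_birds: int = 250
    min_bird_locations: int = 10
    min_birds_per_location: int = 25
    min_groups: int = 10
    min_sessions: int = 3
    min_session_birds: int = 100
    min_novel_points: int = 10
    min_litter_locations: int = 10
    min_dust_locations: int = 3
    min_age_days: int = 26


class ValidationIssue(BaseModel):
    model_config = ConfigDict(frozen=True)

    path: str
    message: str


class ValidationReport(BaseModel):
    issues: list[ValidationIssue] = Field(default_factory=list)

    @property
    def ok(self) -> bool:
        return not self.issues

    def add(self, path: str, message: str) -> None:
        self.issues.append(ValidationIssue(path=path, message=message))

    def __str__(self) -> str:  # pragma: no cover - convenience
        if self.ok:
            return "protocol config valid"
        return "\n".join(f"{i.path}: {i.message}" for i in self.issues)


class ProtocolConfig(BaseModel):
    model_config = ConfigDict(frozen=True, extra="forbid")

    version: str
    principles: tuple[PrincipleDefinition, ...]
    criteria: tuple[CriterionDefinition, ...]
    indicators: tuple[IndicatorDefinition, ...]
    categories: CategoryScale
    thi_modifier: ThiModifierConfig = ThiModifierConfig()
    sampling: SamplingDesign = SamplingDesign()
    certification_threshold: float = 55.0

    # -- lookups ---------------------------------------------------------
    def principle(self, pid: str) -> PrincipleDefinition:
        return _by_id(self.principles, pid, "principle")

    def criterion(self, cid: str) -> CriterionDefinition:
        return _by_id(self.criteria, cid, "criterion")

    def indicator(self, iid: str) -> IndicatorDefinition:
        return _by_id(self.indicators, iid, "indicator")

    def criterion_of_indicator(self, iid: str) -> CriterionDefinition:
        for crit in self.criteria:
            if iid in crit.indicators:
                return crit
        raise KeyError(f"indicator {iid!r} not referenced by any criterion")

    def weighted_indicators(self, crit: CriterionDefinition) -> list[IndicatorDefinition]:
        return [self.indicator(i) for i in crit.indicators
                if self.indicator(i).role == "weighted"]

    def modifier_indicators(self, crit: CriterionDefinition) -> list[IndicatorDefinition]:
        return [self.indicator(i) for i in crit.indicators
                if self.indicator(i).role == "modifier"]


def _by_id(items, item_id: str, kind: str):
    for item in items:
        if item.id == item_id:
            return item
    raise KeyError(f"unknown {kind} id {item_id!r}")


# ---------------------------------------------------------------------------
# validation


def validate_protocol_config(config: ProtocolConfig) -> ValidationReport:
    """Check every protocol invariant; an empty report means valid.

    Checks weight conservation at all three levels, id resolution, band
    ordering/exhaustiveness, score ranges by role, measure-key and unit
    consistency, and the category scale.  Violations are report entries,
    never exceptions.
    """
    report = ValidationReport()
    tol = 1e-9

    # principle weights sum to 1
    total = sum(p.weight for p in config.principles)
    if abs(total - 1.0) > tol:
        report.add("principles", f"principle weights sum to {total:g}, expected 1.0")

    crit_ids = {c.id for c in config.criteria}
    ind_ids = {i.id for i in config.indicators}

    referenced_criteria: set[str] = set()
    for prin in config.principles:
        for cid in prin.criteria:
            if cid not in crit_ids:
                report.add(f"principles.{prin.id}", f"dangling criterion id {cid!r}")
            elif cid in referenced_criteria:
                report.add(f"principles.{prin.id}", f"criterion {cid!r} referenced twice")
            else:
                referenced_criteria.add(cid)
        cw = sum(c.weight for c in config.criteria if c.id in prin.criteria)
        if abs(cw - 1.0) > tol:
            report.add(f"principles.{prin.id}",
                       f"criterion weights sum to {cw:g}, expected 1.0")
    for cid in crit_ids - referenced_criteria:
        report.add(f"criteria.{cid}", "criterion not referenced by any principle")

    referenced_indicators: set[str] = set()
    for crit in config.criteria:
        wsum = 0.0
        for iid in crit.indicators:
            if iid not in ind_ids:
                report.add(f"criteria.{crit.id}", f"dangling indicator id {iid!r}")
                continue
            if iid in referenced_indicators:
                report.add(f"criteria.{crit.id}", f"indicator {iid!r} referenced twice")
            referenced_indicators.add(iid)
            ind = config.indicator(iid)
            if ind.role == "weighted":
                wsum += ind.weight
        if abs(wsum - 1.0) > tol:
            report.add(f"criteria.{crit.id}",
                       f"weighted indicator weights sum to {wsum:g}, expected 1.0")
    for iid in ind_ids - referenced_indicators:
        report.add(f"indicators.{iid}", "indicator not referenced by any criterion")

    for ind in config.indicators:
        path = f"indicators.{ind.id}"
        if ind.role == "weighted" and not (0 < ind.weight <= 1):
            report.add(path, f"weighted indicator weight {ind.weight:g} not in (0, 1]")
        if ind.role == "modifier" and ind.weight != -1.0:
            report.add(path, f"modifier indicator must carry weight -1.0, got {ind.weight:g}")

        if not ind.bands:
            report.add(path, "indicator has no bands")
            continue
        if not ind.bands[-1].fallback:
            report.add(path, "last band must be the fallback ('any other case') row")
        for k, band in enumerate(ind.bands[:-1]):
            if band.fallback:
                report.add(path, f"band {k} is a fallback but not last")
            if not band.when:
                report.add(path, f"band {k} has no conditions and is not the fallback")
        scores = [b.score for b in ind.bands]
        if any(b > a for a, b in zip(scores, scores[1:])):
            report.add(path, f"band scores not non-increasing: {scores}")
        lo, hi = (-100.0, 0.0) if ind.role == "modifier" else (0.0, 100.0)
        for k, band in enumerate(ind.bands):
            if not (lo <= band.score <= hi):
                report.add(path, f"band {k} score {band.score:g} outside [{lo:g}, {hi:g}]")
            for cond in band.when:
                if cond.measure not in MEASURE_UNITS:
                    report.add(path, f"band {k} references unknown measure {cond.measure!r}")
                elif cond.unit is not None and cond.unit != MEASURE_UNITS[cond.measure]:
                    report.add(path,
                               f"band {k} condition on {cond.measure!r} tagged unit "
                               f"{cond.unit!r}, measure is {MEASURE_UNITS[cond.measure]!r}")
                if cond.measure not in ind.measures:
                    report.add(path,
                               f"band {k} tests {cond.measure!r} not listed in measures")

    # category scale
    lowers = [lvl.lower for lvl in config.categories.levels]
    if lowers != sorted(lowers) or len(set(lowers)) != len(lowers):
        report.add("categories", f"category lower bounds not strictly increasing: {lowers}")
    if config.categories.levels and config.categories.levels[0].lower != 0:
        report.add("categories", "first category must start at 0")

    return report


# ---------------------------------------------------------------------------
# I/O


def _config_to_plain(config: ProtocolConfig) -> dict:
    return config.model_dump(mode="json", exclude_none=True)


def save_protocol_config(config: ProtocolConfig, path: str | Path,
                         format: Optional[str] = None) -> None:
    """Write a config as YAML or JSON (inferred from the suffix)."""
    path = Path(path)
    fmt = format or ("json" if path.suffix.lower() == ".json" else "yaml")
    plain = _config_to_plain(config)
    with open(path, "w") as fh:
        if fmt == "json":
            json.dump(plain, fh, indent=2)
        else:
            yaml.safe_dump(plain, fh, sort_keys=False)


def load_protocol_config(path: str | Path, format: Optional[str] = None) -> ProtocolConfig:
    """Load and fully validate a protocol config from YAML or JSON.

    Raises :class:`ProtocolError` on parse/schema failure and
    :class:`ProtocolValidationError` (carrying the full report) when the
    parsed config violates protocol invariants.
    """
    path = Path(path)
    fmt = format or ("json" if path.suffix.lower() == ".json" else "yaml")
    try:
        with open(path) as fh:
            raw = json.load(fh) if fmt == "json" else yaml.safe_load(fh)
    except (OSError, ValueError, yaml.YAMLError) as exc:
        raise ProtocolError(f"cannot parse protocol config {path}: {exc}") from exc
    try:
        config = ProtocolConfig.model_validate(raw)
    except Exception as exc:
        raise ProtocolError(f"protocol config schema violation in {path}: {exc}") from exc
    report = validate_protocol_config(config)
    if not report.ok:
        raise ProtocolValidationError(report)
    return config


def default_protocol_config() -> ProtocolConfig:
    """The bundled meat-quail protocol (4 principles, 12 criteria, 36
    indicators: 33 weighted plus 3 negative modifiers)."""
    from importlib.resources import files

    path = files("quailscore").joinpath("data", "quail_meat_v1.yaml")
    return load_protocol_config(Path(str(path)))


def protocol_json_schema() -> dict:
    """JSON Schema of the protocol config document."""
    return ProtocolConfig.model_json_schema()
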