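"""Data model and I/O for one farm's audit observations.

A :class:`FarmObservation` bundles everything a single audit visit
records: 250 individually scored birds from >=10 locations, 2-minute
group observations, repeated resting/thermoregulation sessions, novel
object test points, facility measurements and the farm registers
(mortality, culling, climate records).

Parsing and sampling validation are deliberately separate: a bundle
that parses but under-samples the protocol's design (fewer than 250
birds, fewer than 3 sessions, ...) loads fine and fails
:func:`validate_sampling` instead, so the tool can both gate
certification audits (strict mode) and score incomplete desk data
(advisory mode).

Two equivalent on-disk forms are supported: a single JSON document and
a CSV bundle (``birds.csv``, ``groups.csv``, ``sessions.csv``,
``novel_object.csv``, ``facility.csv``, ``registers.csv``, ``farm.csv``)
with list-valued register/facility fields serialised as
semicolon-joined strings.  Percentages are stored on the 0-100 scale
and dates as ISO-8601 strings.
"""

from __future__ import annotations

import csv
import json
from pathlib import Path
from typing import Any, Literal, Optional

from pydantic import BaseModel, ConfigDict, Field, model_validator

from .protocol import ProtocolConfig

__all__ = [
    "BirdRecord",
    "GroupObservation",
    "SessionObservation",
    "NovelObjectPoint",
    "FacilityRecord",
    "FarmRegisters",
    "FarmObservation",
    "SamplingIssue",
    "SamplingReport",
    "ObservationError",
    "read_farm_observation",
    "write_farm_observation",
    "write_assessment",
    "read_assessment",
    "validate_sampling",
    "collapse_wound_lesions",
]


class ObservationError(Exception):
    """Raised on unreadable or inconsistent observation bundles."""


def collapse_wound_lesions(n_lesions_gt_0_5cm: int, any_gt_1_5cm: bool) -> int:
    """Collapse a lesion-level wound record to the 0/1/2 bird ordinal:
    no lesions over 0.5 cm -> 0; exactly one lesion of 0.5-1.5 cm -> 1;
    more than one lesion, or any over 1.5 cm -> 2."""
    if n_lesions_gt_0_5cm == 0 and not any_gt_1_5cm:
        return 0
    if n_lesions_gt_0_5cm == 1 and not any_gt_1_5cm:
        return 1
    return 2


class BirdRecord(BaseModel):
    """Clinical scores of one individually sampled bird.

    Ordinals follow the quail three-point collapse of the broiler
    scales (0 good / 1 moderate / 2 severe; toe damage only 0/2).
    A ``None`` means the condition was not assessed on this bird and
    the bird drops out of that condition's prevalence denominator.
    """

    model_config = ConfigDict(extra="allow")

    location_id: str = Field(min_length=1)
    lean: Optional[bool] = None
    plumage_cleanliness: Optional[Literal[0, 1, 2]] = None
    wet: Optional[bool] = None
    wounds: Optional[Literal[0, 1, 2]] = None
    lameness: Optional[Literal[0, 1, 2]] = None
    footpad: Optional[Literal[0, 1, 2]] = None
    toe_damage: Optional[Literal[0, 2]] = None
    hock_burn: Optional[Literal[0, 1, 2]] = None
    plumage_damage: Optional[Literal[0, 1, 2]] = None
    discharge: Optional[bool] = None
    diarrhoea: Optional[bool] = None
    # optional lesion-level wound record, collapsed when wounds is absent
    n_lesions_gt_0_5cm: Optional[int] = Field(default=None, ge=0)
    any_gt_1_5cm: Optional[bool] = None

    @model_validator(mode="after")
    def _collapse_lesions(self) -> "BirdRecord":
        if self.wounds is None and self.n_lesions_gt_0_5cm is not None:
            object.__setattr__(
                self, "wounds",
                collapse_wound_lesions(self.n_lesions_gt_0_5cm,
                                       bool(self.any_gt_1_5cm)))
        return self


class GroupObservation(BaseModel):
    """One 2-minute group observation (social behaviour, coughing or
    sneezing events) plus the avoidance-distance tallies of the group."""

    model_config = ConfigDict(extra="allow")

    group_id: str
    location_id: str = ""
    cough_sneeze_events: int = Field(ge=0)
    negative_social_events: int = Field(ge=0)
    avoid_still: int = Field(ge=0)
    avoid_moving: int = Field(ge=0)
    avoid_fleeing: int = Field(ge=0)

    @property
    def group_size(self) -> int:
        return self.avoid_still + self.avoid_moving + self.avoid_fleeing


class SessionObservation(BaseModel):
    """One resting/thermoregulation scan session (>=100 birds)."""

    model_config = ConfigDict(extra="allow")

    session_index: int = Field(ge=1)
    birds_observed: int = Field(ge=0)
    sited_count: int = Field(ge=0)
    panting_shivering_huddling_count: int = Field(ge=0)
    enrichment_active_count: int = Field(default=0, ge=0)

    @model_validator(mode="after")
    def _counts_within_observed(self) -> "SessionObservation":
        for name in ("sited_count", "panting_shivering_huddling_count",
                     "enrichment_active_count"):
            if getattr(self, name) > self.birds_observed:
                raise ValueError(f"{name} exceeds birds_observed")
        return self


class NovelObjectPoint(BaseModel):
    """Approach counts of one novel-object test point."""

    model_config = ConfigDict(extra="allow")

    point_id: str
    approached_within_30s: int = Field(ge=0)
    approached_within_60s: int = Field(ge=0)

    @model_validator(mode="after")
    def _cumulative(self) -> "NovelObjectPoint":
        if self.approached_within_30s > self.approached_within_60s:
            raise ValueError("30 s approach count exceeds 60 s count")
        return self


class FacilityRecord(BaseModel):
    """Facility and management measurements collected once per audit."""

    model_config = ConfigDict(extra="allow")

    birds_placed: int = Field(gt=0)
    feeder_length_cm: float = Field(gt=0)
    drinking_points: int = Field(gt=0)
    # drinker condition tallies at scores 0/1/2 plus leaking fraction
    drinker_condition_tallies: tuple[int, int, int] = (0, 0, 0)
    drinker_leaking_fraction: float = Field(default=0.0, ge=0, le=1)
    # feeder cleanliness tallies at scores 0/1/2
    feeder_cleanliness_tallies: tuple[int, int, int] = (0, 0, 0)
    # drinker cleanliness tallies at scores 0/2
    drinker_cleanliness_tallies: tuple[int, int] = (0, 0)
    litter_scores: tuple[int, ...] = ()          # per location, 0..4
    dust_scores: tuple[int, ...] = ()            # per location, 0..2
    light_difficulty_locations: int = Field(default=0, ge=0)
    light_hours: float = Field(default=16.0, ge=0, le=24)
    dark_hours: float = Field(default=8.0, ge=0, le=24)
    usable_area_cm2: float = Field(gt=0)
    movement_capable_fraction: float = Field(default=1.0, ge=0, le=1)
    hazard_elements: int = Field(default=0, ge=0)
    outdoor: Literal["none", "winter_garden", "range"] = "none"
    outdoor_covered_fraction: float = Field(default=0.0, ge=0, le=1)
    outdoor_capacity_fraction: float = Field(default=0.0, ge=0, le=1)
    solar_light_score: Literal[0, 1, 2] = 2
    staff_training_score: Literal[0, 1, 2] = 2
    emergency_killing_score: Literal[0, 1, 2] = 2
    enrichment_present: bool = False
    enrichment_use_score: Literal[0, 1, 2, 3] = 3

    @model_validator(mode="after")
    def _ordinal_lists_in_range(self) -> "FacilityRecord":
        if any(not 0 <= s <= 4 for s in self.litter_scores):
            raise ValueError("litter scores must be 0..4")
        if any(not 0 <= s <= 2 for s in self.dust_scores):
            raise ValueError("dust scores must be 0..2")
        return self


class FarmRegisters(BaseModel):
    """Farm register data: 12-month batch mortality lists, culling and
    found-dead counts, and climate records from the last 15 days before
    slaughter (when present)."""

    model_config = ConfigDict(extra="allow")

    batch_mortality_pct: tuple[float, ...] = ()
    batch_firstweek_mortality_pct: tuple[float, ...] = ()
    culled_count: int = Field(default=0, ge=0)
    dead_count: int = Field(default=0, ge=0)
    climate_records_present: bool = False
    thi_max: Optional[float] = None
    temp_min_c: Optional[float] = None
    #: optional raw (temperature C, relative humidity %) pairs from
    #: which thi_max is computed when not supplied directly
    temp_rh_pairs: tuple[tuple[float, float], ...] = ()

    @model_validator(mode="after")
    def _consistent(self) -> "FarmRegisters":
        if len(self.batch_mortality_pct) != len(self.batch_firstweek_mortality_pct):
            raise ValueError("batch mortality lists differ in length")
        if any(p < 0 for p in self.batch_mortality_pct + self.batch_firstweek_mortality_pct):
            raise ValueError("mortality percentages must be >= 0")
        if self.climate_records_present and self.thi_max is None and not self.temp_rh_pairs:
            raise ValueError("climate records flagged present but no THI or T/RH data")
        return self


class FarmObservation(BaseModel):
    """Complete audit input bundle for one farm visit."""

    model_config = ConfigDict(extra="allow")

    farm_id: str
    visit_date: str = ""
    bird_age_days: int = Field(ge=0)
    birds: tuple[BirdRecord, ...] = ()
    groups: tuple[GroupObservation, ...] = ()
    sessions: tuple[SessionObservation, ...] = ()
    novel_object_points: tuple[NovelObjectPoint, ...] = ()
    facility: FacilityRecord
    registers: FarmRegisters


# ---------------------------------------------------------------------------
# sampling validation


class SamplingIssue(BaseModel):
    model_config = ConfigDict(frozen=True)

    requirement: str
    message: str


class SamplingReport(BaseModel):
    issues: list[SamplingIssue] = Field(default_factory=list)

    @property
    def ok(self) -> bool:
        return not self.issues

    def add(self, requirement: str, message: str) -> None:
        self.issues.append(SamplingIssue(requirement=requirement, message=message))


def validate_sampling(obs: FarmObservation, config: ProtocolConfig) -> SamplingReport:
    """Check the audit against the protocol's sampling design.

    Every unmet minimum becomes a report entry; nothing raises.  The
    caller decides whether entries are fatal (strict certification use)
    or advisory.
    """
    design = config.sampling
    report = SamplingReport()

    if obs.bird_age_days < design.min_age_days:
        report.add("bird_age", f"birds are {obs.bird_age_days} days old, "
                               f"minimum {design.min_age_days}")
    if len(obs.birds) < design.min_birds:
        report.add("birds", f"{len(obs.birds)} birds sampled, minimum {design.min_birds}")
    locations: dict[str, int] = {}
    for bird in obs.birds:
        locations[bird.location_id] = locations.get(bird.location_id, 0) + 1
    if len(locations) < design.min_bird_locations:
        report.add("bird_locations", f"{len(locations)} bird sampling locations, "
                                     f"minimum {design.min_bird_locations}")
    for loc, n in sorted(locations.items()):
        if n < design.min_birds_per_location:
            report.add("birds_per_location",
                       f"location {loc!r} has {n} birds, minimum "
                       f"{design.min_birds_per_location}")
    if len(obs.groups) < design.min_groups:
        report.add("groups", f"{len(obs.groups)} groups observed, minimum {design.min_groups}")
    if len(obs.sessions) < design.min_sessions:
        report.add("sessions", f"{len(obs.sessions)} scan sessions, minimum "
                               f"{design.min_sessions}")
    for sess in obs.sessions:
        if sess.birds_observed < design.min_session_birds:
            report.add("session_birds",
                       f"session {sess.session_index} observed {sess.birds_observed} "
                       f"birds, minimum {design.min_session_birds}")
    if len(obs.novel_object_points) < design.min_novel_points:
        report.add("novel_points", f"{len(obs.novel_object_points)} novel-object points, "
                                   f"minimum {design.min_novel_points}")
    if len(obs.facility.litter_scores) < design.min_litter_locations:
        report.add("litter_locations",
                   f"{len(obs.facility.litter_scores)} litter locations, minimum "
                   f"{design.min_litter_locations}")
    if len(obs.facility.dust_scores) < design.min_dust_locations:
        report.add("dust_locations",
                   f"{len(obs.facility.dust_scores)} dust sheet locations, minimum "
                   f"{design.min_dust_locations}")
    return report


# ---------------------------------------------------------------------------
# serialisation helpers

_LIST_SEP = ";"

_CSV_TABLES = ("farm", "birds", "groups", "sessions", "novel_object",
               "facility", "registers")


def _encode_value(value: Any) -> str:
    if value is None:
        return ""
    if isinstance(value, bool):
        return "1" if value else "0"
    if isinstance(value, (list, tuple)):
        return _LIST_SEP.join(_encode_value(v) for v in value)
    return str(value)


def _decode_scalar(text: str) -> Any:
    if text == "":
        return None
    try:
        return int(text)
    except ValueError:
        pass
    try:
        return float(text)
    except ValueError:
        return text


def write_farm_observation(obs: FarmObservation, path: str | Path,
                           format: Literal["json", "csv-bundle"] = "json") -> None:
    """Serialise an observation bundle to JSON or a CSV directory."""
    path = Path(path)
    if format == "json":
        path.parent.mkdir(parents=True, exist_ok=True)
        with open(path, "w") as fh:
            json.dump(obs.model_dump(mode="json"), fh, indent=1)
        return

    path.mkdir(parents=True, exist_ok=True)
    _write_rows(path / "farm.csv",
                ["farm_id", "visit_date", "bird_age_days"],
                [[obs.farm_id, obs.visit_date, obs.bird_age_days]])
    bird_cols = ["location_id", "lean", "plumage_cleanliness", "wet", "wounds",
                 "lameness", "footpad", "toe_damage", "hock_burn",
                 "plumage_damage", "discharge", "diarrhoea"]
    _write_rows(path / "birds.csv", bird_cols,
                [[_encode_value(getattr(b, c)) for c in bird_cols] for b in obs.birds])
    group_cols = ["group_id", "location_id", "cough_sneeze_events",
                  "negative_social_events", "avoid_still", "avoid_moving",
                  "avoid_fleeing"]
    _write_rows(path / "groups.csv", group_cols,
                [[_encode_value(getattr(g, c)) for c in group_cols] for g in obs.groups])
    sess_cols = ["session_index", "birds_observed", "sited_count",
                 "panting_shivering_huddling_count", "enrichment_active_count"]
    _write_rows(path / "sessions.csv", sess_cols,
                [[_encode_value(getattr(s, c)) for c in sess_cols] for s in obs.sessions])
    novel_cols = ["point_id", "approached_within_30s", "approached_within_60s"]
    _write_rows(path / "novel_object.csv", novel_cols,
                [[_encode_value(getattr(p, c)) for c in novel_cols]
                 for p in obs.novel_object_points])
    _write_kv(path / "facility.csv", obs.facility.model_dump(mode="json"))
    reg = obs.registers.model_dump(mode="json")
    # nested (T, RH) pairs flatten as "t:rh" items
    reg["temp_rh_pairs"] = [f"{t}:{rh}" for t, rh in reg.get("temp_rh_pairs", [])]
    _write_kv(path / "registers.csv", reg)


def _write_rows(path: Path, header: list[str], rows: list[list[Any]]) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(header)
        writer.writerows(rows)


def _write_kv(path: Path, mapping: dict[str, Any]) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["key", "value"])
        for key, value in mapping.items():
            writer.writerow([key, _encode_value(value)])


def _read_table(path: Path) -> list[dict[str, str]]:
    if not path.exists():
        raise ObservationError(f"missing table {path.name} in CSV bundle {path.parent}")
    with open(path, newline="") as fh:
        return list(csv.DictReader(fh))


_FACILITY_LIST_FIELDS = {
    "drinker_condition_tallies", "feeder_cleanliness_tallies",
    "drinker_cleanliness_tallies", "litter_scores", "dust_scores",
}
_REGISTER_LIST_FIELDS = {"batch_mortality_pct", "batch_firstweek_mortality_pct",
                         "temp_rh_pairs"}
_BOOL_FIELDS = {"lean", "wet", "discharge", "diarrhoea", "climate_records_present",
                "enrichment_present", "any_gt_1_5cm"}


def _decode_kv(rows: list[dict[str, str]], list_fields: set[str]) -> dict[str, Any]:
    out: dict[str, Any] = {}
    for row in rows:
        key, text = row["key"], row["value"]
        if key in list_fields:
            items = [t for t in text.split(_LIST_SEP) if t != ""]
            if key == "temp_rh_pairs":
                out[key] = [tuple(float(x) for x in item.split(":")) for item in items]
            else:
                out[key] = [_decode_scalar(t) for t in items]
        elif key in _BOOL_FIELDS:
            out[key] = bool(int(text)) if text != "" else None
        else:
            out[key] = _decode_scalar(text)
    return out


_STR_FIELDS = {"farm_id", "visit_date", "location_id", "group_id", "point_id"}


def _decode_record(row: dict[str, str]) -> dict[str, Any]:
    out: dict[str, Any] = {}
    for key, text in row.items():
        if key in _STR_FIELDS:
            out[key] = text
        elif key in _BOOL_FIELDS:
            out[key] = None if text == "" else bool(int(text))
        else:
            out[key] = _decode_scalar(text)
    return out


def read_farm_observation(path: str | Path,
                          format: Optional[Literal["json", "csv-bundle"]] = None
                          ) -> FarmObservation:
    """Read an observation bundle from JSON or a CSV directory.

    All ordinals are range-checked on load; an out-of-range value (for
    example lameness 5, the uncollapsed broiler scale) raises
    :class:`ObservationError` naming the offending row and field.
    """
    path = Path(path)
    if format is None:
        format = "csv-bundle" if path.is_dir() else "json"
    if format == "json":
        try:
            with open(path) as fh:
                payload = json.load(fh)
        except (OSError, ValueError) as exc:
            raise ObservationError(f"cannot read observation {path}: {exc}") from exc
        try:
            return FarmObservation.model_validate(payload)
        except Exception as exc:
            raise ObservationError(f"invalid observation document {path}: {exc}") from exc

    farm_rows = _read_table(path / "farm.csv")
    if len(farm_rows) != 1:
        raise ObservationError(f"farm.csv must hold exactly one row, got {len(farm_rows)}")
    payload = _decode_record(farm_rows[0])
    try:
        payload["birds"] = [
            _decode_record(r) for r in _read_table(path / "birds.csv")]
        payload["groups"] = [
            _decode_record(r) for r in _read_table(path / "groups.csv")]
        payload["sessions"] = [
            _decode_record(r) for r in _read_table(path / "sessions.csv")]
        payload["novel_object_points"] = [
            _decode_record(r) for r in _read_table(path / "novel_object.csv")]
        payload["facility"] = _decode_kv(_read_table(path / "facility.csv"),
                                         _FACILITY_LIST_FIELDS)
        payload["registers"] = _decode_kv(_read_table(path / "registers.csv"),
                                          _REGISTER_LIST_FIELDS)
    except ObservationError:
        raise
    try:
        return FarmObservation.model_validate(payload)
    except Exception as exc:
        raise ObservationError(f"invalid CSV bundle {path}: {exc}") from exc


# ---------------------------------------------------------------------------
# assessment serialisation


def write_assessment(assessment, path: str | Path,
                     format: Literal["json", "csv"] = "json") -> None:
    """Persist a scored assessment.

    JSON keeps the full breakdown tree and reads back exactly
    (:func:`read_assessment`); CSV flattens to one row per indicator,
    criterion and principle plus an overall row carrying both the
    numeric score and the category label.
    """
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    if format == "json":
        with open(path, "w") as fh:
            json.dump(assessment.model_dump(mode="json"), fh, indent=1)
        return
    rows: list[list[Any]] = []
    for res in assessment.indicator_results:
        rows.append(["indicator", res.indicator_id, res.score, "", ""])
    for res in assessment.criterion_results:
        rows.append(["criterion", res.criterion_id, res.final_score,
                     res.category, res.modifier_deduction])
    for res in assessment.principle_results:
        rows.append(["principle", res.principle_id, res.score, res.category, ""])
    rows.append(["overall", assessment.farm_id, assessment.overall_score,
                 assessment.overall_category, ""])
    _write_rows(path, ["level", "id", "score", "category", "modifier_deduction"], rows)


def read_assessment(path: str | Path):
    """Read back a JSON assessment written by :func:`write_assessment`."""
    from .aggregate import WelfareAssessment  # deferred: avoids import cycle

    path = Path(path)
    try:
        with open(path) as fh:
            payload = json.load(fh)
    except (OSError, ValueError) as exc:
        raise ObservationError(f"cannot read assessment {path}: {exc}") from exc
    return WelfareAssessment.model_validate(payload)
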