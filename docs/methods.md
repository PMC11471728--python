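# Methods

## The assessment model

`quailscore` evaluates one farm visit (birds at least 26 days old)
against a fixed-weight, three-level welfare protocol for meat quail:
36 indicators → 12 criteria → 4 principles → overall score. All weights
are constants of the protocol config; no weight varies with the score
it multiplies (this is a deliberate departure from the variable-weight
I-spline aggregation used by the original Welfare Quality® protocols,
which this protocol family replaced with a fixed score system).

Indicator scores come from threshold-band tables. A band row is a
conjunction of comparisons on raw summary measures with a fixed score;
rows are ordered best score first and the engine returns the first row
whose conditions all hold, with a trailing catch-all row ("any other
case") that matches anything. Comparator strictness is taken verbatim
from the tables: `<` is strict, `≥`/`≤` inclusive, so a farm with
exactly 2.5% lean birds falls in the `≥2.5%` row and scores 0.

### Compound ("and/or") rows

Several tables rate one condition at two severities (e.g. moderate and
severe lameness prevalence) and print rows like "<2.0% of birds with a
score of 1 and/or <0.5% of birds with a score of 2". These are encoded
as worst-of-dimensions: per severity dimension, find the best row whose
bound on that dimension is met; the matched row is the worst of the
per-dimension matches. In the shipped config this is realised purely by
the conjunctive top-down scan, with one transcription rule: a row that
leaves a dimension unstated inherits the bound of the better row above
it (the wounds 80-point row, "<0.5% score 1", carries "0% score 2" from
the 100-point row). This is the unique reading under which each table's
rows are mutually consistent and the score is monotone in every
severity; a dual-route test checks the scan against an independent
worst-of-dimensions interpreter on 10,000 randomized summaries per
indicator.

### Derived measures

* **Bird-level prevalences** use per-condition denominators: birds not
  assessed for a condition drop out of that condition's denominator
  rather than forcing a fixed n = 250.
* **Session pooling** (sited birds, panting/shivering/huddling,
  enrichment activity) uses totals over the ≥3 scan sessions — total
  positive birds over total birds observed — not the mean of session
  percentages, since sessions may differ in size and only minimum
  counts are prescribed.
* **Group observations**: a group scores 1 for coughing/sneezing at
  1–2 events in 2 minutes and 2 above that; any negative social event
  marks the group. Avoidance-distance percentages pool all birds
  counted across groups.
* **Novel-object points** classify as 0 when ≥2 birds approach within
  30 s or ≥4 within 60 s, as 1 at exactly one approach within 30 s or
  three within 60 s, else 2; the indicator bands on the tallies of
  points at 0 and at 2 (the printed rows never bound the score-1
  tally).
* **Facility ratios** divide by the day-0 placement count: feeder cm
  per bird, birds per drinking point, usable cm² per bird (external
  areas count only with 24-h access).
* **Registers**: mortality is the arithmetic mean over the last 12
  months' batch list (whole cycle, and first seven days); the culling
  rate is culled/(culled + found dead) × 100 and is undefined — scored
  by the fallback row, 0 points — when no usable register exists.

### The temperature/humidity modifier

Climate records from the last 15 days before slaughter yield an ordinal
0/1/2 mapping to deductions 0/−45/−100 on the thermal-comfort
criterion: ordinal 0 needs THI below 32 and a minimum temperature never
under 5 °C; ordinal 1 needs THI up to 38 and minimum temperature never
under 1 °C; a THI of 39 or more, any colder excursion, or *absent
records* is ordinal 2 (zeroing the criterion — in practice the single
most damaging item on real farms). Because the protocol leaves THI
values strictly between 38 and 39 unassigned, the THI is rounded to the
nearest integer before comparison. The THI formula itself is not fixed
by the protocol: registers may supply the maximum THI directly, or
(T, RH) pairs evaluated with the NRC-style formulation
`0.8·T + (RH/100)(T − 14.4) + 46.4` named in the config.

### Aggregation details

* Modifier deductions are summed after the weighted indicator sum and
  the criterion is clamped to [0, 100]; clamping is what makes a −100
  modifier dominate any animal-based score.
* All intermediate scores keep full floating-point precision; reports
  round to one decimal for display only, and categorisation always uses
  the unrounded value.
* Category intervals are half-open with lower bounds {0, 20, 55, 80}:
  "at least 55 points" certifies, so 55.0 is enhanced and 80.0
  excellent. Printed integer ranges (0–19, 20–54, …) are the rounded
  presentation of the same convention.
* Because the roll-up is linear with fixed weights, cohort means
  commute with aggregation: the mean of per-farm scores equals the
  score of mean inputs. This identity is what lets published cohort
  means be checked arithmetically (the published feeding criterion
  means 73.4/50.7 combine to 63.2; the four published principle means
  to 59.1). Two published principle means (housing 49.4, health 62.6)
  differ by 0.1 from the weighted combination of their own published
  criterion means — intermediate rounding in the source presentation —
  and the engine makes no attempt to replicate that.

## Protocol-as-data

One YAML document carries the whole protocol (version, principles,
criteria, indicators with bands, category scale, THI thresholds,
sampling design, certification threshold); a JSON twin and a JSON
Schema ship alongside. The validator enforces: weight conservation at
all three levels (weighted indicators per criterion, criteria per
principle, principles overall each sum to 1; modifiers carry weight
−1 and are excluded), id resolution, band exhaustiveness (fallback
present and last), non-increasing band scores, score ranges by role
([0, 100] weighted, [−100, 0] modifier), and measure/unit consistency
against the measure registry. The indicator count is 36 entries —
33 weighted plus the 3 modifiers; counting the modifiers separately
from the criteria they shadow is also how one arrives at the
alternative tally of 37 sometimes quoted for this protocol.

## Sampling design and strictness

The protocol's sampling minimums (250 birds from ≥10 locations with 25
per point, ≥10 groups, ≥3 sessions of ≥100 birds, ≥10 novel-object
points, ≥10 litter and ≥3 dust locations, age ≥26 days) are validated
separately from parsing. In strict mode (certification) violations
abort scoring; in advisory mode the farm is scored anyway and the
issues are stamped into the assessment. Validation is monotone: adding
observations never adds violations.

## The synthetic-farm generator

No per-farm audit data for this species are public, so the generator
is the package's test bed. It emulates: independent per-bird
Bernoulli/multinomial draws of all clinical ordinals at the protocol's
sampling sizes (no spatial clustering between locations — a
per-location offset hook exists but no clustering structure is
asserted), binomial session counts, per-group event draws, novel-object
approach counts consistent with the point-classification rule, facility
values fixed or uniform on an interval, batch mortality lists drawn
around a target mean with first-week mortality a fraction of the cycle
value, and register/climate availability as Bernoulli flags.

Category presets (`excellent`, `enhanced`, `acceptable`,
`not_acceptable`) place raw parameters at band midpoints, never at
edges, targeting mid-category overall scores (≈100 / 71 / 36 / ≈2), so
category recovery is robust both to 250-bird sampling noise and to the
comparator-strictness convention; recovery tests demand ≥95% over 200
seeds and in practice see ~100%. The `study_like` preset encodes the
published husbandry ranges of the audited Spanish cohort — stocking
density uniform on 89–147 cm²/bird, 30–52 birds per drinker, ~0.3 cm
feeder space per bird, flock mortality 0.5–10.5% with first-week
mortality 25–60% of it, climate records absent with probability 11/14,
under 8 h of darkness on every farm, no outdoor access, solar-light
access on 6 farms in 14, staff training mixed 8/5/1 — and its cohorts
are only required to *bracket* the published cohort level (grand mean
of 50 cohorts × 14 farms within [50, 68]), not replicate it: the true
farm-level joint distribution is unknown.

Determinism: `generate_farm(profile, seed)` is pure;
`generate_cohort` gives farm *i* the child seed
`SeedSequence(master, spawn_key=(i,))`, so cohorts reproduce exactly
across platforms and record their generating profile as ground truth.

What passing these tests does **not** show: agreement with real audits
(inter-observer reliability, spatial clustering of clinical conditions,
correlations between indicators — e.g. wet birds vs litter quality —
are all absent from the generator), nor validity of the protocol's
thresholds themselves.

## Numerical and design choices

* Weight-sum validation uses a 1e-9 absolute tolerance; the shipped
  weights are exact decimals.
* Band conditions against a missing (`None`) measure are false, so
  incomplete data fall through to the fallback row — matching the
  tables' "including the absence of registers" rows; a measure key
  absent from the summary altogether is an error (incomplete
  observation), not a silent zero.
* Outdoor access: a free-range area adequate for >80% of the flock
  scores 100 or 55 by covered fraction (≥40% / ≥20%); any other outdoor
  provision (winter garden, or a range missing those conditions) scores
  40; none scores 0. This keeps the indicator monotone in all three
  dimensions where the printed rows, read literally, conflict with the
  accompanying text.
* Drinker cleanliness bands on the percentage of clean drinkers exactly
  as tabulated; the prose's alternative absolute rule ("two or more
  dirty drinkers score 0") conflicts with it for large farms and is not
  used.
* Enrichment use bands on the auditor's whole-visit ordinal (0/1/2/3,
  absence of enrichment forcing 3); session-level enrichment-activity
  counts are carried as supporting data only, since the printed rows
  mix a percentage with an absolute bird count that only the auditor's
  overall estimate combines.
* Wound records accept either the collapsed 0/1/2 ordinal or a
  lesion-level record (count of lesions over 0.5 cm, any over 1.5 cm)
  collapsed as 0 → 0; exactly one 0.5–1.5 cm lesion → 1; otherwise 2.
* Feeder-space thresholds are implemented as printed (0.30–0.40 cm per
  bird) even though the unit looks implausibly tight; being config
  values, they can be revised without code changes.

## Test problem sizes

The suite exercises the dual-route oracle at 10,000 random summaries ×
36 indicators, the monotonicity sweep at 800 perturbations per
indicator plus derandomized property tests, category recovery at 200
seeds per preset, and the cohort-bracketing check at 50 cohorts × 14
farms; the whole suite runs in well under a minute on one CPU. These
sizes were chosen to make band-edge and tie-break defects essentially
certain to surface while keeping the suite quick to iterate on.

## Known limitations

* Prevalences are point estimates; no confidence intervals or
  finite-sample corrections are attached (the protocol scores point
  prevalences only).
* The broiler 0–5 gait scale is supported only through its documented
  collapse to 0/1/2; raw broiler scores are rejected at parse time.
* No alternative aggregation schemes (Choquet integrals, I-splines) and
  no uncertainty propagation through the roll-up.
* The generator cannot stand in for real audit data in studies of the
  protocol's validity or reliability.
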