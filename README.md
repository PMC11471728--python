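# quailscore

A scoring engine for on-farm welfare assessment of Japanese quail
(*Coturnix japonica*) reared for meat production.

Meat quail are farmed in the billions yet, unlike broilers, laying hens
or turkeys, had no dedicated welfare assessment protocol. `quailscore`
implements a Welfare Quality®-style audit protocol for this species as
reusable software: it takes the raw observations of a single farm audit
— clinical scores of 250 individually sampled birds from at least 10
locations, 2-minute group observations, repeated resting and
thermoregulation scan sessions, novel-object test points, facility
measurements and the farm registers — and turns them into indicator,
criterion and principle scores, a 0–100 overall welfare score and a
four-level welfare category. It is intended for auditors and
certification bodies, for farmers doing self-assessment and
benchmarking, and for researchers studying the protocol itself.

## The scoring model

The protocol is a three-level fixed-weight hierarchy:

* **36 indicators** (20 animal-based, 16 resource-based). Each indicator
  maps a raw summary — a prevalence, a ratio like cm of feeder trough
  per bird, a tally of locations at an ordinal score — onto a fixed
  point score through an ordered table of threshold *bands* (typically
  100/80/60/40/20/0, with a catch-all "any other case" row). Compound
  rows on two severity levels (e.g. lameness score 1 vs score 2
  prevalence) resolve by worst-of-dimensions: the matched row is the
  worst of the per-severity matches.
* **12 criteria.** Within a criterion the weighted indicators combine
  as Σ wᵢ·sᵢ. Three criteria additionally carry *modifier* indicators
  that only deduct points: missing or poor temperature/humidity
  registers (0/−45/−100, driven by THI and minimum-temperature
  thresholds), hazardous elements in the birds' surroundings (−10 per
  element down to −100) and deficient emergency-killing practice
  (0/−55/−100). Deductions apply after the weighted sum and the result
  is clamped to [0, 100], so a −100 modifier zeroes its criterion
  outright.
* **4 principles and the overall score.** Criterion scores roll up with
  fixed weights into good feeding, good housing, good health and
  appropriate behaviour; the overall score is
  `0.15·feeding + 0.30·housing + 0.30·health + 0.25·behaviour`.

The overall (and any intermediate) score maps onto four welfare
categories — not acceptable [0, 20), acceptable [20, 55), enhanced
[55, 80), excellent [80, 100] — with 55 points the certification
threshold.

The entire protocol — hierarchy, weights, every band row, modifier
thresholds, category bounds, sampling design — is data, not code: one
YAML document (`quailscore/data/quail_meat_v1.yaml`, JSON Schema
alongside) that the engine interprets, so revised thresholds are a new
config file.

## Worked example

There is no public per-farm audit dataset for this species, so the
package ships a seeded synthetic-farm generator with named welfare
profiles (`excellent`, `enhanced`, `acceptable`, `not_acceptable`, and
`study_like`, which emulates the husbandry conditions of audited
Spanish meat-quail farms). End to end:

```python
import quailscore as qs

config = qs.default_protocol_config()            # 4 / 12 / 36 structure
farm   = qs.generate_farm(qs.preset_profile("study_like"), seed=7)
result = qs.assess_farm(farm, config)
print(qs.render_scorecard(result, config=config))
```

prints (abridged):

```
# Welfare scorecard — farm study_like-7

Overall score: **57.2 / 100** (enhanced)
Certification (threshold 55): certified; 2.2 points above threshold

## Principles
- good_feeding: 77.8 (enhanced)
- good_housing: 45.2 (acceptable)
- good_health: 52.0 (acceptable)
- appropriate_behaviour: 65.2 (enhanced)

## Criteria
- prolonged_hunger: 76.0 (enhanced); base 76.0
- thermal_comfort: 0.0 (not acceptable); base 80.0,
  modifier deduction -100 — criterion zeroed by modifier
...
```

This farm would just be certified: it scores 57.2 overall, but the
missing climate registers zero its thermal-comfort criterion (the most
common failure on real farms) and only 0.31 cm of feeder space per bird
costs most of the feeder-space indicator — exactly the kind of
actionable diagnosis the scorecard is for.

The same flows are available from the shell:

```bash
quailscore simulate --profile study_like --n 14 --seed 42 --out farms/
quailscore assess farms/study_like-000.json --out assessed/
quailscore benchmark assessed/ --out bench/     # mean ± SD, categories, dot plot
quailscore validate-config my_protocol.yaml
```

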