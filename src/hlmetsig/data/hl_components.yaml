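# Default operationalization of the 8-component healthy-lifestyle (HL) score
# (2018 WCRF/AICR-style cut-offs). Each component is scored 1 (high
# adherence), 0.5 (intermediate), or 0 (low). Numeric rules are evaluated
# high-first, then intermediate, else low; interval endpoints are inclusive
# toward the healthier level. `domain` bounds the plausible raw range and is
# used by the synthetic generator when drawing raw values.
# All cut-offs are user-overridable; tests rely on the rule machinery, not
# on these particular nutrition values.
hl_components:
  healthy_weight:
    unit: kg/m2
    kind: numeric
    domain: [16.0, 45.0]
    high: {min: 18.5, max: 25.0, min_inclusive: true, max_inclusive: false}
    intermediate: {min: 25.0, max: 30.0, min_inclusive: true, max_inclusive: false}
  physical_activity:
    unit: min/week
    kind: numeric
    domain: [0.0, 600.0]
    high: {min: 150.0, min_inclusive: true}
    intermediate: {min: 75.0, max: 150.0, min_inclusive: true, max_inclusive: false}
  plant_food:
    unit: g/day fiber
    kind: numeric
    domain: [5.0, 60.0]
    high: {min: 30.0, min_inclusive: true}
    intermediate: {min: 15.0, max: 30.0, min_inclusive: true, max_inclusive: false}
  fast_processed_food:
    unit: servings/day
    kind: numeric
    domain: [0.0, 30.0]
    high: {max: 6.0, max_inclusive: true}
    intermediate: {min: 6.0, max: 10.0, min_inclusive: false, max_inclusive: true}
  red_processed_meat:
    unit: g/week
    kind: numeric
    domain: [0.0, 1200.0]
    high: {max: 300.0, max_inclusive: true}
    intermediate: {min: 300.0, max: 500.0, min_inclusive: false, max_inclusive: true}
  sugar_sweetened_beverages:
    unit: g/day
    kind: numeric
    domain: [0.0, 600.0]
    high: {max: 0.0, max_inclusive: true}
    intermediate: {min: 0.0, max: 250.0, min_inclusive: false, max_inclusive: true}
  alcohol:
    unit: g/day
    kind: numeric_by_sex
    female:
      domain: [0.0, 60.0]
      high: {max: 0.0, max_inclusive: true}
      intermediate: {min: 0.0, max: 14.0, min_inclusive: false, max_inclusive: true}
    male:
      domain: [0.0, 90.0]
      high: {max: 0.0, max_inclusive: true}
      intermediate: {min: 0.0, max: 28.0, min_inclusive: false, max_inclusive: true}
  smoking:
    unit: status
    kind: categorical
    mapping: {never: 1.0, former: 0.5, current: 0.0}
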