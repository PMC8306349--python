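# EXAMPLE HEI-2015 component scoring standards.
#
# This file illustrates the expected schema and carries commonly cited
# HEI-2015 scoring standards; it is shipped as a convenience EXAMPLE, not as an
# authoritative reference. Verify the values against official HEI-2015
# documentation (NCI / USDA) before any substantive use, and replace this file
# with your own standards table via the pipeline config.
#
# Schema per component:
#   name:               column name in the per-recall component-amounts table
#   kind:               adequacy | moderation
#   unit:               per_1000_kcal | percent_energy | ratio
#   standard_for_zero:  density earning 0 points
#   standard_for_max:   density earning max_points
#   max_points:         5 or 10 (must sum to 100 over the 13 components)
components:
  - name: total_fruits
    kind: adequacy
    unit: per_1000_kcal
    standard_for_zero: 0.0
    standard_for_max: 0.8
    max_points: 5
  - name: whole_fruits
    kind: adequacy
    unit: per_1000_kcal
    standard_for_zero: 0.0
    standard_for_max: 0.4
    max_points: 5
  - name: total_vegetables
    kind: adequacy
    unit: per_1000_kcal
    standard_for_zero: 0.0
    standard_for_max: 1.1
    max_points: 5
  - name: greens_and_beans
    kind: adequacy
    unit: per_1000_kcal
    standard_for_zero: 0.0
    standard_for_max: 0.2
    max_points: 5
  - name: whole_grains
    kind: adequacy
    unit: per_1000_kcal
    standard_for_zero: 0.0
    standard_for_max: 1.5
    max_points: 10
  - name: dairy
    kind: adequacy
    unit: per_1000_kcal
    standard_for_zero: 0.0
    standard_for_max: 1.3
    max_points: 10
  - name: total_protein_foods
    kind: adequacy
    unit: per_1000_kcal
    standard_for_zero: 0.0
    standard_for_max: 2.5
    max_points: 5
  - name: seafood_and_plant_proteins
    kind: adequacy
    unit: per_1000_kcal
    standard_for_zero: 0.0
    standard_for_max: 0.8
    max_points: 5
  - name: fatty_acids
    kind: adequacy
    unit: ratio
    standard_for_zero: 1.2
    standard_for_max: 2.5
    max_points: 10
  - name: refined_grains
    kind: moderation
    unit: per_1000_kcal
    standard_for_zero: 4.3
    standard_for_max: 1.8
    max_points: 10
  - name: sodium
    kind: moderation
    unit: per_1000_kcal
    standard_for_zero: 2.0
    standard_for_max: 1.1
    max_points: 10
  - name: added_sugars
    kind: moderation
    unit: percent_energy
    standard_for_zero: 26.0
    standard_for_max: 6.5
    max_points: 10
  - name: saturated_fats
    kind: moderation
    unit: percent_energy
    standard_for_zero: 16.0
    standard_for_max: 8.0
    max_points: 10
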