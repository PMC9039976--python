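# Synthetic stand-in for a pandemic-vulnerability-style ToxPi model:
# 14 slices grouped into 4 categories (color families). Slice names follow
# the public PVI vocabulary; weights and component lists are package
# inventions chosen for realistic structure, not published values.
name: PVI-style example (synthetic)
slices:
- name: Transmissible Cases
  category: Infection Rate
  weight: 3.0
  color: '#67000d'
  components:
  - column: transmissible_cases
- name: Disease Spread
  category: Infection Rate
  weight: 2.0
  color: '#cb181d'
  components:
  - column: disease_spread
- name: Population Mobility
  category: Population Concentration
  weight: 1.0
  color: '#08306b'
  components:
  - column: daytime_density
  - column: baseline_mobility
- name: Residential Density
  category: Population Concentration
  weight: 1.0
  color: '#2171b5'
  components:
  - column: residential_density
- name: Population Demographics
  category: Population Concentration
  weight: 1.0
  color: '#6baed6'
  components:
  - column: pct_minority_population
- name: Social Distancing
  category: Intervention Measures
  weight: 1.0
  color: '#00441b'
  components:
  - column: social_distancing_grade
    invert: true
- name: Testing
  category: Intervention Measures
  weight: 1.0
  color: '#238b45'
  components:
  - column: testing_rate
    invert: true
- name: Vaccination Rate
  category: Intervention Measures
  weight: 1.0
  color: '#74c476'
  components:
  - column: pct_fully_vaccinated
    invert: true
- name: Air Pollution
  category: Health & Environment
  weight: 1.0
  color: '#3f007d'
  components:
  - column: pm25_concentration
- name: Age Distribution
  category: Health & Environment
  weight: 1.0
  color: '#54278f'
  components:
  - column: pct_age_65_over
- name: Co-morbidities
  category: Health & Environment
  weight: 1.0
  color: '#6a51a3'
  components:
  - column: pct_diabetes
  - column: pct_obesity
- name: Health Disparities
  category: Health & Environment
  weight: 1.0
  color: '#807dba'
  components:
  - column: pct_uninsured
  - column: social_vulnerability_index
- name: Hospital Beds
  category: Health & Environment
  weight: 1.0
  color: '#9e9ac8'
  components:
  - column: hospital_beds_per_capita
    invert: true
- name: Ventilator Capacity
  category: Health & Environment
  weight: 1.0
  color: '#bcbddc'
  components:
  - column: ventilators_per_capita
    invert: true
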