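# Strain presets for the cohort simulator.
#
# Duration/longevity/fecundity fields are published strain means (days /
# eggs per female).  net_reproductive_rate is the published R0 used to
# calibrate preadult survival: because R0 equals total eggs over n0,
# P(newborn becomes an adult female) = R0 / fecundity, and preadult
# survival = that ratio / sex_ratio, split evenly across preadult stages.
WT:
  stage_duration_means: {egg: 3.00, larva: 5.11, pupa: 3.90}
  adult_longevity_means: {female: 13.27, male: 16.60}
  apop_mean: 0.00
  oviposition_days_mean: 4.93
  total_fecundity_mean: 151.9
  fecundity_dispersion: 10.0
  sex_ratio: 0.5
  net_reproductive_rate: 54.43
MU-1:
  stage_duration_means: {egg: 3.10, larva: 6.58, pupa: 4.08}
  adult_longevity_means: {female: 8.00, male: 9.21}
  apop_mean: 0.53
  oviposition_days_mean: 3.26
  total_fecundity_mean: 75.95
  fecundity_dispersion: 4.0
  sex_ratio: 0.5
  net_reproductive_rate: 12.03
MU-2:
  stage_duration_means: {egg: 3.00, larva: 6.14, pupa: 3.98}
  adult_longevity_means: {female: 8.07, male: 9.19}
  apop_mean: 0.19
  oviposition_days_mean: 4.07
  total_fecundity_mean: 88.04
  fecundity_dispersion: 5.0
  sex_ratio: 0.5
  net_reproductive_rate: 19.81
MU+14:
  stage_duration_means: {egg: 3.00, larva: 6.44, pupa: 4.16}
  adult_longevity_means: {female: 10.50, male: 11.07}
  apop_mean: 0.17
  oviposition_days_mean: 4.60
  total_fecundity_mean: 92.29
  fecundity_dispersion: 6.0
  sex_ratio: 0.5
  net_reproductive_rate: 26.92
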