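# Default synthetic-cohort parameters.
#
# Per-locus linear age trends (level = baseline + slope * age + noise) were
# calibrated so that, for 60 ages drawn uniformly on 23-70 years, the realized
# Pearson correlation magnitudes between methylation level and age land near
# the moderate-to-low values reported for buccal swabs (|r| ~ 0.28-0.60):
# with sd(age) ~ 13.9 y, r = slope*sd(age) / sqrt(slope^2*sd(age)^2 + noise_sd^2).
# C1orf132 loses methylation with age, hence the negative slope.
n_samples: 60
age_range: [23, 70]
integer_ages: true
locus_params:
  ELOVL2:
    baseline: 0.43
    slope: 0.0026
    noise_sd: 0.06
  FHL2:
    baseline: 0.30
    slope: 0.00105
    noise_sd: 0.05
  KLF14:
    baseline: 0.05
    slope: 0.00215
    noise_sd: 0.04
  C1orf132:
    baseline: 0.53
    slope: -0.0017
    noise_sd: 0.05
  TRIM59:
    baseline: 0.315
    slope: 0.0018
    noise_sd: 0.05
# replicate design: 2 bisulfite conversions x 2 amplifications per sample
n_conversions: 2
n_amplifications: 2
replicate_noise_sd: 0.01   # measurement scatter between replicates (level units)
conversion_shift: 0.0      # optional between-conversion batch effect (level units)
# capillary-electrophoresis intensity model
total_intensity_mean: 4000.0   # mean summed peak height per locus, RFU
total_intensity_sd: 1200.0     # between-injection spread of summed height, RFU
intensity_noise_cv: 0.05       # per-channel multiplicative noise (CV)
saturation_rfu: 30000.0        # detector ceiling for a single peak
# bisulfite-conversion control DNAs
meth_control_level: 0.98
unmeth_control_level: 0.02
seed: 0
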