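# Natural-history default parameters, fixture version v1.
#
# Functional forms follow the published adenoma-carcinoma microsimulation
# lineage (lognormal person-level frailty on a piecewise-log-linear
# initiation rate; saturating growth pinned by a Frechet time-to-10-mm;
# lognormal malignant-transition size threshold; lognormal sojourn;
# stage-dependent mixture-cure survival).  Coefficient values are this
# package's own calibration of those forms to pre-screening-era US
# colorectal epidemiology (adenoma prevalence by age, lifetime unscreened
# incidence and mortality of a 1975 birth cohort, stage distribution and
# 5-year relative survival); see docs/methods.md for targets and rationale.
# Every block carries a provenance tag; all values are overridable.

risk:
  # ln rate = alpha_i + female_effect*female + g(age); alpha_i ~ N(mean, sd^2)
  mean_log_risk: -5.65
  sd_log_risk: 1.10
  female_effect: -0.25
  min_age: 20.0
  age_knots: [20.0, 50.0, 60.0, 70.0]
  age_slopes: [0.045, 0.030, 0.015, 0.0]

growth:
  # d(t) = d_max - (d_max - d_init) exp(-k t); k set by t10 ~ Frechet
  d_init: 1.0
  d_max: 50.0
  frechet_shape_colon: 2.0
  frechet_scale_colon: 22.0
  frechet_shape_rectum: 2.0
  frechet_scale_rectum: 14.0

transition:
  # lognormal size threshold (mm); offsets shift the log-median
  log_size_mu: 3.40   # ln ~30 mm, male colon
  log_size_sigma: 0.72
  female_offset: 0.06
  rectum_offset: -0.20

sojourn:
  # lognormal years from preclinical onset to symptomatic diagnosis
  log_mu_colon: 0.96   # median ~2.6 y
  log_mu_rectum: 0.79  # median ~2.2 y
  log_sigma: 0.55

stage:
  # AJCC I-IV at diagnosis; screen-detected preclinical cancers are found
  # earlier in the sojourn, hence the left-shifted distribution
  symptomatic: [0.16, 0.28, 0.32, 0.24]
  screen: [0.44, 0.30, 0.18, 0.08]

survival:
  # mixture cure: S(t) = cure + (1 - cure) exp(-rate t), per stage
  cure: [0.88, 0.74, 0.52, 0.02]
  rate: [0.25, 0.30, 0.35, 0.45]

# adenoma location across six colorectal segments
# (rectum, sigmoid, descending, transverse, ascending, cecum)
segment_probs: [0.09, 0.24, 0.12, 0.24, 0.23, 0.08]

max_age: 100.0

provenance:
  risk: {form: crc_spin_publication, values: fixture_default}
  growth: {form: crc_spin_publication, values: fixture_default}
  transition: {form: crc_spin_publication, values: fixture_default}
  sojourn: {form: crc_spin_publication, values: fixture_default}
  stage: {form: fixture_default, values: fixture_default}
  survival: {form: fixture_default, values: fixture_default}
  segment_probs: {form: fixture_default, values: fixture_default}
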