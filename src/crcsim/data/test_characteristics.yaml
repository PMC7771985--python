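# Stool-test operating characteristics, fixture version v1.
#
# granular: site-by-size adenoma sensitivities and age-band specificities
#   for FIT and mt-sDNA from the DeeP-C cross-sectional screening study
#   (NCT01397747), with the published n/N retained for audit.  Values are
#   stored as proportions; the display layer re-renders percents.
#   Size columns: <=5 mm, 6-9 mm, >=10 mm.
#   Specificity age bands: <60, 60-64, 65-69, 70-74, 75+.
#   No granular HSgFOBT estimates exist; HSgFOBT runs in aggregate mode only.
#
# aggregate: the decision-analysis convention used for primary analyses,
#   where advanced-adenoma sensitivity proxies adenomas >=10 mm and
#   non-advanced sensitivity proxies 1-5 and 6-9 mm combined
#   (provenance: uspstf_decision_analysis transcription).
#   Size columns: 1-5 mm, 6-9 mm, >=10 mm.

granular:
  FIT:
    sensitivity:
      rectal:
        - {value: 0.033, n: 5, N: 150}
        - {value: 0.056, n: 5, N: 89}
        - {value: 0.301, n: 22, N: 73}
      distal:
        - {value: 0.070, n: 39, N: 558}
        - {value: 0.215, n: 68, N: 317}
        - {value: 0.393, n: 83, N: 211}
      proximal:
        - {value: 0.059, n: 73, N: 1236}
        - {value: 0.066, n: 40, N: 609}
        - {value: 0.160, n: 65, N: 406}
    sensitivity_crc: {value: 0.738, n: 48, N: 65}
    specificity_by_age:
      - {value: 0.978, n: 1361, N: 1392}
      - {value: 0.965, n: 355, N: 368}
      - {value: 0.956, n: 1483, N: 1551}
      - {value: 0.967, n: 697, N: 721}
      - {value: 0.939, n: 399, N: 425}
  mt-sDNA:
    sensitivity:
      rectal:
        - {value: 0.093, n: 14, N: 150}
        - {value: 0.213, n: 19, N: 89}
        - {value: 0.562, n: 41, N: 73}
      distal:
        - {value: 0.145, n: 81, N: 558}
        - {value: 0.278, n: 88, N: 317}
        - {value: 0.573, n: 121, N: 211}
      proximal:
        - {value: 0.158, n: 195, N: 1236}
        - {value: 0.199, n: 121, N: 609}
        - {value: 0.340, n: 138, N: 406}
    sensitivity_crc: {value: 0.923, n: 60, N: 65}
    specificity_by_age:
      - {value: 0.944, n: 1314, N: 1392}
      - {value: 0.924, n: 340, N: 368}
      - {value: 0.891, n: 1382, N: 1551}
      - {value: 0.861, n: 621, N: 721}
      - {value: 0.812, n: 345, N: 425}

aggregate:
  FIT:
    sensitivity_by_size: [0.076, 0.076, 0.238]
    sensitivity_crc: 0.738
    specificity: 0.964
  mt-sDNA:
    sensitivity_by_size: [0.172, 0.172, 0.424]
    sensitivity_crc: 0.923
    specificity: 0.898
  HSgFOBT:
    sensitivity_by_size: [0.075, 0.075, 0.239]
    sensitivity_crc: 0.700
    specificity: 0.925

# patient hours to complete one stool test (HSgFOBT needs three
# evacuation/collection/storage steps plus setup, hence 2 hours)
patient_hours:
  FIT: 1.0
  mt-sDNA: 1.0
  HSgFOBT: 2.0
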