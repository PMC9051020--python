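# Two-cohort emulation: 11 subjects with fixed corneal compensation,
# 25 with variable compensation.
seed: 1
statistic: ring_mean
sim:
  noise_sd: 1.5
cohorts:
  - {label: cohort1, mode: fixed, n_subjects: 11}
  - {label: cohort2, mode: variable, n_subjects: 25}
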