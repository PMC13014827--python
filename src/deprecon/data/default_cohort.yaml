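# Default synthetic cohort calibrated to the published study marginals.
# Two arms sized ~223/107; count means per arm match the reported 6-month
# utilization table; utility-change means per arm reproduce the reported
# half-year QALY gains (0.0275 / 0.0611) through gain = delta_u / 4.
#
# The baseline score SD is kept at 2.5 (the study-implied per-person SD is
# ~5.1); a tighter spread keeps six-month scores away from the instrument
# floor so that clipping does not bias the calibrated change means.
n_total: 330
p_discontinue: 0.3242
seed: 20240617
group_mean_counts:
  continuation:
    primary_care: 9.03
    specialist: 1.67
    pc_emergency: 0.58
    hospital_emergency: 0.32
  discontinuation:
    primary_care: 8.20
    specialist: 1.63
    pc_emergency: 0.31
    hospital_emergency: 0.34
covariate_marginals:
  sex: {men: 0.3003, women: 0.6997}
  income_band: {low: 0.7057, high: 0.2943}
  cci_band: {"0-2": 0.4152, "3-4": 0.3879, ">=5": 0.1969}
  minor_mental_disorder: {"no": 0.964, "yes": 0.036}
  # printed indication percentages sum to ~93.4%; "other" absorbs the remainder
  indication: {anxiety: 0.2372, insomnia: 0.5676, both: 0.0871, other: 0.1081}
age_mean_sd: [66.72, 12.41]
bzd_duration_mean_sd: [4.04, 5.11]
wonca_baseline_mean_sd: [18.48, 2.5]
utility_change_mean_sd_by_group:
  continuation: [0.11, 0.07]
  discontinuation: [0.2444, 0.07]
frailty_sd: 0.0
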