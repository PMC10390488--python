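# Synthetic reference scenario: a gefitinib-arm-shaped trial of 159
# patients (median TTP near 9 months, exponential deaths with median 24.4
# months, 30-month follow-up). Generated data, not trial data.
n_patients: 159
ttp_dist: lognormal
ttp_median: 9.0
ttp_sigma: 0.7
os_median: 24.4
censor_rate: 0.0
follow_up_months: 30.0
seed: 0
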