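# Default model, treatment and population configuration.
# Units are documented next to each field; every value can be overridden by
# a user config file with the same structure.

follow_up_months: 30.0      # simulated follow-up (right-censoring cut-off)
capacity_factor: 1.5        # initial carrying capacity / initial cell count

growth:                     # per-clone tumor-growth submodel (human setting)
  lambda_prolif: 0.044      # 1/day, maximal proliferation rate
  delta0: 0.005             # 1/day, baseline death of proliferating cells
  delta_q: 0.001            # 1/day, death of quiescent cells
  k_pq: 0.1                 # 1/day, quiescence entry outside the viable rim
  k_qp: 0.005               # 1/day, quiescence exit inside the viable rim
  k_cl: 0.05                # 1/day, clearance of dead cells
  v_cell: 1.0e-9            # cm^3 per cell
  d_rim: 1.0                # cm, viable rim depth (vascularised human tumor)
  k_max: 1.0e+12             # cells, maximal carrying capacity
  alpha_ang: 0.008          # 1/day, neo-angiogenic capacity growth
  rho_imm: 5.0e-4           # 1/day, immune-pressure recruitment
  h_imm: 1.0e+10             # cells, immune half-saturation
  d_imm: 0.1                # 1/day, immune-pressure decay
  kappa_imm: 1.0            # 1/day per unit pressure, immune kill
  gamma_drug: 0.01          # 1/day, drug-induced death coefficient

signaling:
  s0: 1.0
  g_egfr: {exon19del: 0.25, l858r: 0.25}   # proliferative gain per variant
  rho_res: {t790m: 0.5, kras: 0.8}         # drug-effect attenuation per mutation

pk:                         # one-compartment oral gefitinib
  dose_mg: 250.0
  interval_h: 24.0
  F: 0.6                    # bioavailability
  ka: 0.5                   # 1/h
  ke: 0.0169                # 1/h (half-life ~41 h)
  vd_l: 1400.0              # L

pd:
  imax: 0.95
  ic50_base: 0.05           # mg/L
  hill: 1.0
  potency:                  # IC50 multipliers per mutation
    exon19del: 0.8
    l858r: 1.25
    t790m: 15.0
    kras: 4.0
    pik3ca: 1.0

regimen:
  - {start_day: 0.0, dose_mg: 250.0, interval_h: 24.0, end_day: null}

recist:
  reference: nadir          # or "baseline"
  rel_threshold: 0.2        # fractional increase of the largest dimension
  abs_diameter_cm: 0.5      # absolute increase of the diameter

validation:
  n_bootstrap_pi: 1000
  n_lr_tests: 7000
  pi_level: 0.95
  coverage_threshold_pct: 80.0
  lr_threshold_pct: 80.0
  alpha: 0.05

vpop:
  luxlung7:                 # trial-arm descriptor frequencies
    size_multiplier: 10
    n_real_events: 119      # progression events in the real arm
    categoricals:
      sex: {male: 0.33333333333333331, female: 0.66666666666666663}
      egfr_variant: {exon19del: 0.58490566037735849, l858r: 0.41509433962264151}
      smoking: {never: 0.66666666666666663, former: 0.11949685534591195,
                current: 0.21383647798742139}
      ethnicity: {asian: 0.55345911949685533, non_asian: 0.44654088050314467}
      stage: {IIIb: 0.018867924528301886, IV: 0.98113207547169812}
      kras: {carrier: 0.025, none: 0.975}
      pik3ca: {carrier: 0.03, none: 0.97}
    continuous:
      age: {dist: truncnorm, center: 63.0, range: [36.0, 89.0], coverage: 0.99,
            bounds: [36.0, 89.0]}
      r0_cm: {dist: truncnorm, center: 1.5, sd: 0.6, bounds: [0.4, 4.0]}
      prolif_frac: {dist: uniform, lo: 0.3, hi: 0.95}
      f_res: {dist: lognormal, median: 1.2e-2, sigma: 1.5, bounds: [1.0e-7, 0.5]}
      m_prolif: {dist: truncnorm, center: 0.0, sd: 0.12, bounds: [-0.35, 0.35]}
      rho_imm: {dist: lognormal, median: 5.0e-4, sigma: 1.0, bounds: [1.0e-7, 0.02]}
      kappa_imm: {dist: lognormal, median: 1.0, sigma: 0.4, bounds: [0.1, 5.0]}
      alpha_ang: {dist: lognormal, median: 8.0e-3, sigma: 1.0, bounds: [2.0e-4, 0.5]}
      pace: {dist: lognormal, median: 1.0, sigma: 0.45, bounds: [0.2, 5.0]}
  general:                  # general-population variant (sensitivity runs)
    size_multiplier: 10
    n_real_events: 119
    categoricals:
      sex: {male: 0.33333333333333331, female: 0.66666666666666663}
      egfr_variant: {exon19del: 0.5, l858r: 0.5}
      smoking: {never: 0.66666666666666663, former: 0.11949685534591195,
                current: 0.21383647798742139}
      ethnicity: {asian: 0.55345911949685533, non_asian: 0.44654088050314467}
      stage: {IIIb: 0.018867924528301886, IV: 0.98113207547169812}
      kras: {carrier: 0.025, none: 0.975}
      pik3ca: {carrier: 0.03, none: 0.97}
    continuous:
      age: {dist: truncnorm, center: 63.0, range: [36.0, 89.0], coverage: 0.99,
            bounds: [36.0, 89.0]}
      r0_cm: {dist: truncnorm, center: 1.5, sd: 0.6, bounds: [0.4, 4.0]}
      prolif_frac: {dist: uniform, lo: 0.3, hi: 0.95}
      f_res: {dist: lognormal, median: 1.2e-2, sigma: 1.5, bounds: [1.0e-7, 0.5]}
      m_prolif: {dist: truncnorm, center: 0.0, sd: 0.12, bounds: [-0.35, 0.35]}
      rho_imm: {dist: lognormal, median: 5.0e-4, sigma: 1.0, bounds: [1.0e-7, 0.02]}
      kappa_imm: {dist: lognormal, median: 1.0, sigma: 0.4, bounds: [0.1, 5.0]}
      alpha_ang: {dist: lognormal, median: 8.0e-3, sigma: 1.0, bounds: [2.0e-4, 0.5]}
      pace: {dist: lognormal, median: 1.0, sigma: 0.45, bounds: [0.2, 5.0]}

baseline:                   # real trial-arm counts and summaries
  categorical:
    sex: {male: 53, female: 106}
    egfr_variant: {exon19del: 93, l858r: 66}
    smoking: {never: 106, former: 19, current: 34}
    ethnicity: {asian: 88, non_asian: 71}
    stage: {IIIb: 3, IV: 156}
  continuous:
    age: {n: 159, median: 63.0, range: [36.0, 89.0], coverage: 0.99}
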