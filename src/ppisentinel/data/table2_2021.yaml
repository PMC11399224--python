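# Packaged two-period cohort preset.
#
# Margins (age/sex/stay distributions, per-factor exposure fractions, PPI
# prescription rate) are calibrated to the characteristics of a three-month
# tertiary-care discharge cohort of ~5000 inpatient cases; the baseline
# period carries the pre-surveillance incident rates and the intervention
# period the post-surveillance rates. Exposure targets are fractions of
# included cases. The seed here is a placeholder: loaders override it.
seed: 0

periods:
  - label: baseline
    n_cases: 5643
    admission_start: 2020-07-01
    admission_end: 2020-09-30
    missing_rate: 0.0129394        # 67 / 5178
    inappropriate_rate: 0.0635380  # 329 / 5178
  - label: intervention
    n_cases: 5534
    admission_start: 2021-07-01
    admission_end: 2021-09-30
    missing_rate: 0.0047319        # 24 / 5072
    inappropriate_rate: 0.0532334  # 270 / 5072

consent_refusal_rate: 0.083
sex_female: 0.509

# continuous age in years at admission; ">= 65" weight equals the target
# fraction of cases aged 65+, and the open-ended band's upper edge is set
# so the overall mean age lands on 58.3 years
age_bands:
  - {lo: 18.1, hi: 30.0, weight: 0.106146}
  - {lo: 30.0, hi: 55.0, weight: 0.292079}
  - {lo: 55.0, hi: 65.0, weight: 0.160135}
  - {lo: 65.0, hi: 87.75, weight: 0.441641}

# length of stay in days (mean ~5.5)
stay_bands:
  - {lo: 0.25, hi: 3.0, weight: 0.39700}
  - {lo: 3.0, hi: 6.0, weight: 0.34022}
  - {lo: 6.0, hi: 15.0, weight: 0.20492}
  - {lo: 15.0, hi: 25.0, weight: 0.05786}

# target fraction of cases exposed to each risk factor during the stay
exposure_targets:
  nsaid: 0.087342                  # 443 / 5072
  cox2: 0.0017744                  # 9 / 5072
  low_dose_aspirin: 0.164235       # 833 / 5072
  antiplatelet_non_aspirin: 0.036475   # 185 / 5072
  therapeutic_ac: 0.083005         # 421 / 5072
  corticosteroid_ge10: 0.0088722   # 45 / 5072
  ssri: 0.0437697                  # 222 / 5072
  thrombocytes_lt30: 0.0076892     # 39 / 5072

ppi_target: 0.330047               # 1674 / 5072
mean_filler_drugs: 9.0
on_demand_nsaid_rate: 0.3
normal_tc_lab_rate: 0.4

# relative frequency of the alert row realised by a missing-PPI incident;
# weighted toward the antiplatelet-related constellations
missing_row_weights:
  1: 0.06
  2: 0.06
  3: 0.03
  4: 0.05
  5: 0.18
  6: 0.02
  7: 0.12
  8: 0.08
  9: 0.30
  10: 0.04
  11: 0.06
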