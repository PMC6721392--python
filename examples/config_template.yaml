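# mixstrat run configuration template.
# Every key is optional; omitted keys fall back to the package defaults
# (the calibrated group parameters, the default thresholds, Holm correction).

# --- classification thresholds ------------------------------------------
# Boundary convention: a value exactly at a cut is positive.
thresholds:
  ptau_high: 68.0          # pg/mL; CSF Ptau at/above this is "Ptau positive"
  ab_ratio_low: 0.07       # amyloid 42/40 ratio at/below this is positive
  md_z_high: 2.0           # diffusivity z at/above this marks vascular injury
  t_memory_low: 40.0       # T-score at/below this is a memory deficit
  t_executive_low: 40.0    # T-score at/below this is an executive deficit
  albumin_index_high: 6.5  # blood-brain-barrier leakage cut (feature matcher)
  ad_axis_rule: either     # either | both | ptau_only | amyloid_only

# --- statistics ----------------------------------------------------------
classify_method: dichotomy # dichotomy | feature_matrix
correction: holm           # holm | bonferroni (pairwise tests, per variable)

# --- synthetic cohort (simulate mode) ------------------------------------
cohort:
  seed: 1
  group_sizes:             # biological group sizes; defaults shown
    SIVD: 53
    AD: 25
    MX: 22
    MI: 18
    LA: 29
    CONTROL: 25
  # confusion: row-stochastic P(clinical | biological); omit for the default
  # reassignment model (dual-pathology patients read clinically as AD/SIVD).
  # confusion:
  #   MX: {MX: 0.409, AD: 0.364, SIVD: 0.227}

# --- per-group generator overrides (rarely needed) -----------------------
# group_params:
#   MX:
#     continuous:          # variable: [mean, sd]
#       ptau: [118.86, 57.82]
#       md_z: [3.20, 1.65]
#       ...                # all 13 continuous variables are required
#     binary:              # flag: probability
#       wmh_present: 0.8
#       hyperreflexia: 0.8
#       imbalance: 0.8
#       infarct: 0.0
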