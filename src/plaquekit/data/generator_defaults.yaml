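# Default calibration of the synthetic serial IVUS-VH cohort generator.
#
# Group-level numbers (cohort sizes, vessel-length, per-segment change
# distributions, pullback LAPS change, TCFA fate probabilities, lipid
# covariates) reproduce the study conditions of a 61-patient two-group
# serial statin trial: 17 diabetic (DM) and 44 non-diabetic (non-DM)
# patients, ~70-73 mm analyzed vessel, 1-year follow-up.
# Baseline phenotype mixes are constrained so the TCFA segment share matches
# the reported 48.9% (DM) / 45.1% (non-DM); the split of the remaining mass
# over NL/PIT/FP/FcP/ThCFA is not reported and is a documented choice.

groups:
  DM:
    n_patients: 17
    vessel_length_mm: {mean: 70.5, sd: 15.8}          # analyzed length
    baseline_vessel_area_mm2: {mean: 15.79, sd: 5.67} # per-segment mean EEM CSA
    baseline_pav_pct: {mean: 45.7, sd: 5.0}           # per-segment PAV
    delta_plaque_area_mm2: {mean: 0.21, sd: 0.97}     # per-segment 1-year change
    delta_vessel_area_mm2: {mean: 0.22, sd: 1.4}      # per-segment EEM change
    delta_plaque_vessel_correlation: 0.93  # plaque growth tracks outward
                                           # remodeling; fixed jointly by the
                                           # three printed change SDs
    delta_pav_pct: {mean: 0.7, sd: 2.8}
    delta_pullback_laps: {mean: 0.13, sd: 1.79}       # per-patient change
    delta_plaque_pav_correlation: 0.85  # joint structure of the plaque/PAV
                                        # changes implied by the group's
                                        # vessel-area change SD (1.4 mm2)
    baseline_phenotype_probs:
      NL: 0.05
      PIT: 0.15
      FP: 0.12
      FcP: 0.07
      ThCFA: 0.121
      TCFA: 0.489
    new_tcfa_prob: 0.203          # baseline non-TCFA segment turning TCFA
    persistent_tcfa_prob: 0.821   # baseline TCFA segment staying TCFA
    remodeling_gain_prob: 0.05    # diffuse lesion developing a positively
                                  # remodeled focal profile by follow-up
    remodeling_loss_prob: 0.0
    ldl_baseline_mmol_l: {mean: 2.42, sd: 0.53}
    ldl_change_mmol_l: {mean: -0.3, sd: 0.52}
    ldl_plaque_correlation: 0.0   # LDLc change vs mean plaque-area change
  non_DM:
    n_patients: 44
    vessel_length_mm: {mean: 72.9, sd: 18.6}
    baseline_vessel_area_mm2: {mean: 16.66, sd: 5.62}
    baseline_pav_pct: {mean: 44.6, sd: 8.0}
    delta_plaque_area_mm2: {mean: -0.47, sd: 1.15}
    delta_vessel_area_mm2: {mean: -0.56, sd: 1.8}
    delta_plaque_vessel_correlation: 0.974
    delta_pav_pct: {mean: -1.4, sd: 2.5}
    delta_pullback_laps: {mean: -0.23, sd: 1.66}
    delta_plaque_pav_correlation: 0.89  # implied by the vessel-area change
                                        # SD (1.8 mm2)
    baseline_phenotype_probs:
      NL: 0.07
      PIT: 0.17
      FP: 0.13
      FcP: 0.07
      ThCFA: 0.109
      TCFA: 0.451
    new_tcfa_prob: 0.126
    persistent_tcfa_prob: 0.713
    remodeling_gain_prob: 0.0     # non-DM plaques regress with negative
    remodeling_loss_prob: 0.05    # remodeling: focal profiles resolve
    ldl_baseline_mmol_l: {mean: 2.46, sd: 1.04}
    ldl_change_mmol_l: {mean: -0.66, sd: 1.09}
    ldl_plaque_correlation: 0.47

shared:
  frame_spacing_mm: 0.5        # uniform gated frame spacing
  min_length_mm: 30.0          # inclusion criterion: pullback at least 30 mm
  patient_intercept_frac: 0.3  # share of delta SD attributable to the patient
  characterized_fraction: 0.9  # F+FF+NC+DC as a fraction of plaque CSA
  label_drift_prob: 0.1        # non-TCFA follow-up one-step phenotype drift
  stretch_range: [0.92, 1.08]  # follow-up registration stretch per landmark leg
  focal_segment_prob: 0.3      # segments carrying a focal (positively
                               # remodeled) lesion profile
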