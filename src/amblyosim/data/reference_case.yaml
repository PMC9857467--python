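# Reference-case parameter configuration for the amblyopia vision-testing
# microsimulation. Probabilities are annual unless noted; costs are 2019 CAD.
# Keys mirror amblyosim.parameters.ParameterSet exactly.

# --- epidemiology at model entry (age 3) ---
prevalence_amblyopia: 0.058
prevalence_risk_factor: 0.202

# --- uptake of testing and care ---
p_optometric_exam_uptake: 0.880
p_primary_care_screen: 0.610     # conditional on attending a well-child visit
p_school_screen: 0.810
p_well_child_visit: 0.840
p_treatment_adherence: 0.75
p_social_assistance: 0.04

# --- treatment success by age at treatment ---
p_treatment_success_by_age:
  3: 0.89
  4: 0.76
  5: 0.65

# --- primary-care referral pathway (by age, screen result) ---
referral_after_positive_pc:
  3: 0.66
  4: 0.91
  5: 0.86
referral_after_inconclusive_pc:
  3: 0.59
  4: 0.59
  5: 0.50
adherence_after_positive_pc:
  3: 0.63
  4: 0.62
  5: 0.42
adherence_after_inconclusive_pc:
  3: 0.34
  4: 0.33
  5: 0.56

# --- school referral pathway (age 5) ---
referral_school_positive: 1.00
referral_school_inconclusive: 1.00
adherence_school: 0.66

# --- inconclusive screen probabilities by true condition class ---
p_inconclusive_pc:
  amblyopia: 0.05
  risk_factor: 0.03
  healthy_or_treated: 0.02
p_inconclusive_school:
  amblyopia: 0.30
  risk_factor: 0.12
  healthy_or_treated: 0.05

# --- test operating characteristics ---
sens_pc_amblyopia: 0.659
sens_pc_risk_factor: 0.586
spec_pc: 0.398
sens_school_amblyopia: 0.867
sens_school_risk_factor: 0.882
spec_school: 0.121
accuracy_optometrist: 0.95

# --- annual transition probabilities ---
p_death_by_age:
  3: 0.00014
  4: 0.00011
  5: 0.00009
  6: 0.00008
  7: 0.00008
  8: 0.00007
  9: 0.00008
  10: 0.00008
  11: 0.00009
  12: 0.0001
  13: 0.00013
  14: 0.00016
  15: 0.00021
  16: 0.00027
  17: 0.00033
  18: 0.00039
p_healthy_to_risk_factor: 0.033      # ages 3-5 only
p_risk_factor_to_amblyopia: 0.32     # ages 3-5 only
p_success_to_healthy: 0.472          # VA >= 20/25 after successful treatment
p_success_to_treated: 0.528
p_vision_loss_5_15: 0.00004
p_vision_loss_16_18: 0.00005

# --- health-state utility weights ---
utilities:
  healthy: 1.00
  untreated_amblyopia: 0.96
  untreated_risk_factor: 0.96
  treated_amblyopia: 0.99
  vision_loss: 0.93
  dead: 0.0

# --- unit costs (2019 CAD) ---
cost_well_child_visit: 41.34
cost_pc_screen: 11.50
cost_school_screen: 10.00
cost_nurse_training_per_child: 0.01
cost_opto_diagnostic: 42.50
cost_opto_followup: 25.15
cost_glasses: 120.70
glasses_interval_years: 3

# --- analysis settings ---
discount_rate: 0.015
wtp_threshold: 50000.0
n_individuals: 25000
horizon_years: 15
entry_age: 3
exit_age: 17
optometric_exam_age: 3
cad_per_usd: 1.3268

# --- PSA dispersion defaults (per-key overrides allowed) ---
dispersion:
  beta_ess: 100.0
  lognormal_p975_ratio: 1.2
  normal_cv: 0.10
  per_key: {}
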