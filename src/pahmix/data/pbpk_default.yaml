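# Default two-compound PBPK parameter fixture: a 73 kg reference human with
# flow-limited liver / fat / richly-perfused / slowly-perfused / blood
# compartments. Physiological fractions are conventional reference-human
# values; partition coefficients and the oral absorption rate are documented
# placeholders for highly lipophilic PAHs (identical for both compounds).
# Microsomal kinetic parameters are the fitted human-liver-microsome values
# for benzo[a]pyrene (BaP) and dibenzo[def,p]chrysene (DBC);
# ki_as_inhibitor_uM is each compound's competitive-inhibition constant
# against the other compound's high-affinity metabolic phase.
physiology:
  body_weight_kg: 73.0
  cardiac_output_L_min: 5.2
  microsomal_protein_mg_per_g_liver: 30.0
  liver_density_g_per_ml: 1.05
  volume_fractions:
    liver: 0.026
    fat: 0.21
    richly_perfused: 0.05
    slowly_perfused: 0.545
    blood: 0.079
  flow_fractions:
    liver: 0.25
    fat: 0.05
    richly_perfused: 0.45
    slowly_perfused: 0.25
compounds:
  - name: BaP
    molecular_weight: 252.31
    oral_absorption_k_per_h: 0.5
    partition_coefficients:
      liver: 10.0
      fat: 200.0
      richly_perfused: 10.0
      slowly_perfused: 4.0
    vmax1_invitro_nmol_min_mg: 0.0063
    km1_uM: 0.088
    clint2_invitro_ml_min_mg: 0.0012
    ki_as_inhibitor_uM: 0.061
  - name: DBC
    molecular_weight: 302.37
    oral_absorption_k_per_h: 0.5
    partition_coefficients:
      liver: 10.0
      fat: 200.0
      richly_perfused: 10.0
      slowly_perfused: 4.0
    vmax1_invitro_nmol_min_mg: 0.00090
    km1_uM: 0.060
    clint2_invitro_ml_min_mg: 0.0017
    ki_as_inhibitor_uM: 0.44
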