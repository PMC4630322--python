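{
  "parameter_file_version": "1.0",
  "hgb_molecular_weight_g_per_mol": 64450.0,
  "hgb_blood_concentration_min_g_per_L": 122.0,
  "hgb_blood_concentration_max_g_per_L": 150.0,
  "large_vessel_hgb_molar_mM": 0.002,
  "tissue_hematocrit_ratio": 0.8,
  "oxyphoric_power": 4,
  "blood_saturation": 0.75,
  "hill_coefficient": 2.73,
  "p50_mmHg": 26.0,
  "solubility_alpha_mmol_per_L_per_mmHg": 0.00139,
  "blood_hgb_o2_mM": 0.0048,
  "boundary_oxygen_mM": 0.00053,
  "boundary_glucose_mM": 0.005,
  "boundary_waste_mM": 0.0,
  "boundary_growth_factor_mM": 0.0,
  "boundary_growth_inhibitor_mM": 0.0,
  "diffusion_oxygen_cm2_per_h": 0.0594,
  "diffusion_glucose_cm2_per_h": 0.00152,
  "diffusion_waste_cm2_per_h": 0.002124,
  "diffusion_growth_factor_cm2_per_h": 1e-06,
  "diffusion_growth_inhibitor_cm2_per_h": 1e-06,
  "rate_proliferating_oxygen": 108.0,
  "rate_proliferating_glucose": 162.0,
  "rate_proliferating_waste": 240.0,
  "rate_proliferating_growth_factor": 1.0,
  "rate_proliferating_growth_inhibitor": 0.0,
  "rate_quiescent_oxygen": 50.0,
  "rate_quiescent_glucose": 80.0,
  "rate_quiescent_waste": 110.0,
  "rate_quiescent_growth_factor": 0.5,
  "rate_quiescent_growth_inhibitor": 1.0,
  "rate_necrotic_oxygen": 0.0,
  "rate_necrotic_glucose": 0.0,
  "rate_necrotic_waste": 0.0,
  "rate_necrotic_growth_factor": 0.0,
  "rate_necrotic_growth_inhibitor": 2.0,
  "oxygen_per_glucose_aerobic": 6.0,
  "atp_per_glucose_aerobic": 30.0,
  "atp_per_glucose_anaerobic": 2.0,
  "atp_per_waste": 3.5,
  "h_proliferating_atp": 828.0,
  "h_quiescent_atp": 393.4,
  "health_decay_per_h": 1.0,
  "necrosis_threshold": 0.5,
  "proliferation_threshold": 1.5,
  "base_mitosis_probability": 0.0315,
  "mitosis_noise_sigma": 0.01,
  "hayflick_limit": 60,
  "mutation_increment_prob": 0.05,
  "stem_spawn_period_iterations": 70,
  "dissolution_delay_iterations": 100,
  "cell_radius_cm": 0.001,
  "spring_k_pp": 1.0,
  "spring_k_pq": 0.5,
  "spring_k_qq": 0.25,
  "neighbor_cutoff_factor": 1.2,
  "chemotaxis_alpha": 1.0,
  "chemotaxis_beta": 1.0,
  "chemotaxis_gamma": 0.5
}
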