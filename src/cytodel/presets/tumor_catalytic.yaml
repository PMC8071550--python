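# Catalytic target inactivator (k_cat 2.35/min, the RAS-cleaving
# enzyme rate) against an abundant target (1e5 copies/cell),
# dosed to 200 nM plasma in the no-convection tumor.
agent:
  molecular_weight_kda: 70.0
  kd_receptor_m: 6.8e-11
  kon_receptor_m_s: 100000.0
  plasma_half_life_h: 2.55
  cytosolic_half_life_h: 6.0
  mode: catalytic
  k_cat_per_min: 2.35
  kd_target_m: 1.0e-10
  kon_target_m_s: 1000000.0
  escape_fraction: 0.02
tissue:
  capillary_radius_um: 8.0
  krogh_radius_um: 108.0
  void_fraction: 0.2
  vascular_permeability_cm_s: 3.0e-07
  interstitial_diffusivity_cm2_s: 1.0e-08
  reference_mw_kda: 70.0
  fluid_velocity_at_wall_um_s: 0.0
  reflection_coefficient: 0.9
  cell_density_per_ml: 290000000.0
  receptors_per_cell: 540000.0
  k_internalize_per_min: 0.002
  receptor_steady_state: true
target:
  copies_per_cell: 100000.0
  cytosol_volume_pl: 1.0
  target_half_life_h: 24.0
regimen:
  pattern: single
  peak_m: 2.0e-07
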