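# Default scenario: 70 kDa EpCAM-targeted protein, high-cellularity breast
# tumor without functional lymphatics (no interstitial convection).
# Receptor affinity (68 pM), size, plasma half-life (laronidase), cell
# density, receptor density (5.4e5/cell; 5.3e5 is also reported for MCF-7)
# and EpCAM internalization rate are literature values; transport
# coefficients, escape fraction and cytosolic kinetics are package
# calibration defaults (see docs/methods.md).
agent:
  molecular_weight_kda: 70.0
  kd_receptor_m: 6.8e-11
  kon_receptor_m_s: 1.0e+5
  plasma_half_life_h: 2.55
  cytosolic_half_life_h: 6.0
  mode: binder
  k_cat_per_min: 0.0
  kd_target_m: 1.0e-10
  kon_target_m_s: 1.0e+6
  escape_fraction: 0.02
tissue:
  capillary_radius_um: 8.0
  krogh_radius_um: 108.0
  void_fraction: 0.2
  vascular_permeability_cm_s: 3.0e-7
  interstitial_diffusivity_cm2_s: 1.0e-8
  reference_mw_kda: 70.0
  fluid_velocity_at_wall_um_s: 0.0
  reflection_coefficient: 0.9
  cell_density_per_ml: 2.9e+8
  receptors_per_cell: 5.4e+5
  k_internalize_per_min: 0.002
  receptor_steady_state: true
target:
  copies_per_cell: 1.0e+4
  cytosol_volume_pl: 1.0
  target_half_life_h: 24.0
regimen:
  pattern: single
  peak_m: 1.0e-6
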