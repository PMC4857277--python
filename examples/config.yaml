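# Full-experiment configuration for `plaqrecon run --config examples/config.yaml`.
population:
  seed: 1
  n_patients: 4
  arteries_per_patient: 2
  sections_per_artery: 2
  within_artery_rho: 0.3
methods: [group_average, plaque_specific, oracle]
gee_source: refit
compute_stress: true
prestress: true
p_prestress_mmhg: 100.0
p_sys_mmhg: 140.0
mesh_params:
  fine_deg: 5.0
  coarse_deg: 9.0
  n_nc_layers: 3
  n_behind_layers: 2
  n_media_layers: 3
  n_buffer_layers: 2
out_dir: results/run1
seed: 1
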