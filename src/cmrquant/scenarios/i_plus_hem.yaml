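# I+HEM: large infarct with considerable hemorrhage, severe edema and MVO.
arm: "I+HEM"
matrix: [128, 128]
n_slices: 10
voxel_size_mm: [1.9, 1.9, 5.0]
geometry:
  endo_radius_mm: 12.0
  epi_radius_mm: 22.0
  lesion_theta_center_deg: 120.0
  lesion_theta_width_deg: 110.0
  edema_slices: [1, 8]
  edema_transmurality: 1.0
  infarct_width_frac: 0.75
  infarct_transmurality: 0.8
  infarct_slices: [2, 7]
  hemorrhage_width_frac: 0.45
  hemorrhage_radial_band: [0.2, 0.6]
  hemorrhage_slices: [2, 7]
  mvo_fraction: 0.15
tissue:
  remote_t2_ms: 38.0
  remote_t2star_ms: 35.0
  edema_t2_ms: 51.3
  hemorrhage_t2_ms: 28.0
  hemorrhage_t2star_ms: 12.0
  t1_remote_ms: 400.0
  t1_infarct_ms: 120.0
  t1_mvo_ms: 520.0
  amplitude: 100.0
noise:
  model: rician
  snr: 20.0
cine:
  edv_ml: 60.0
  esv_ml: 30.0
  n_phases: 20
seed: 0
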