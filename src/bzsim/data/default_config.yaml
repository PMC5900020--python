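# Default study settings (bulk conductivities in S/m; lengths mm; times ms)
geometry:
  sheet_size: 30.0
  scar_diameter: 10.0
  bz_thickness: 2.0
  resolution: 0.05        # target mean edge length (50 um)
  stimulus_radius: 0.5    # half-disc at the center of the bottom edge
cell:
  model: tt2006_epi
  Cm: 1.0                 # uF/cm^2
  prepace_beats: 100
  gKs_scale:
    normal: 1.0
    longer: 0.5
    shorter: 2.0
tissue:
  beta: 0.14              # surface-to-volume ratio, 1/um
  cycle_length: 500.0
  n_beats: 5
  dt: 0.02
  output_dt: 1.0
conductivity:             # longitudinal, transverse (S/m)
  normal_anisotropic: [0.1890, 0.0690]
  decreased_transverse: [0.1890, 0.0069]
  decreased_isotropic: [0.0689, 0.0689]
maps:
  activation_threshold_mV: -20.0
  repolarization_threshold_mV: -70.0
  gradient_thresholds_ms_per_mm: [3.2, 5.0]
presets:
  desk:                   # coarse desk-scale settings, same code path
    resolution: 0.15
    dt: 0.1
    n_ionic_substeps: 2
  paper:
    resolution: 0.05
    dt: 0.02
    n_ionic_substeps: 1
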