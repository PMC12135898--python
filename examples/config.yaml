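# Example configuration for `gradstab simulate` / `gradstab run`.
# Any omitted key keeps its library default; the synth defaults emulate the
# full study design (400 ROIs, 230 volumes at TR 2 s, 28 patients + 17
# controls). This reduced profile completes in about a minute.

synth:
  n_patients: 8
  n_controls: 8
  n_roi: 100
  n_volumes: 230
  tr_s: 2.0
  stability_shift: 1.0      # planted post-session stabilisation strength
  n_effect_roi: 20
  planted_corr: -0.6
  seed: 1

pipeline:
  fd_threshold_mm: 0.2
  band_hz: [0.01, 0.1]
  density: 0.2              # row sparsification (0.1 at the 400-ROI scale)
  embedding: {alpha: 0.5, diffusion_time: 0.0, n_components: 10}
  dpl_affinity_mode: sparse-cosine
  window_s: 60.0
  step_s: 2.0
  stability_groups: [patient]

stats:
  alpha: 0.05
  n_tests: 100              # Bonferroni divisor (400 at full scale)
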