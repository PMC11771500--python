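# Extraluminal cuff occlusion of the default urethral cross-section.
geometry:
  kind: cross_section
  element_size_mm: 0.2
  quarter: true
materials:
  lining: {model: ogden, mu_kPa: 20.0, alpha: 6.178}
  spongiosum: {model: ogden, mu_kPa: 1.1, alpha: 6.178}
scenario:
  kind: cuff
  pressure_kPa: 8.0
  n_steps: 40
solver:
  newton_tol: 1.0e-6
seed: 0
output_dir: aussim_out
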