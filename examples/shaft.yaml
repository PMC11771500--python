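# Intraluminal device insertion and distal-shaft arm deployment.
geometry:
  kind: cross_section
  element_size_mm: 0.2
  quarter: true
scenario:
  kind: shaft
  delta_mm: 0.5
  n_arms: 4
  tip_radius_mm: 0.5
  n_steps: 60
seed: 0
output_dir: aussim_out
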