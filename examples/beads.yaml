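# Two-plane micro-bead scene at the reference acquisition geometry.
scene:
  kind: beads
  n: 2
  diameter: 1.0
  z_planes: [690.0, 710.0]
  shape: [252, 252]

acquisition:
  n_heights: 6
  z_start: 720.0
  z_step: 20.0
  noise_sigma: 0.0

recovery:
  tol: 1.0e-4
  max_iter: 20

deconvolution:
  method: gold
  beta: 0.001
  n_iter: 15
  z_start: 660.0
  z_stop: 740.0
  z_step: 5.0

seed: 1
output_dir: out
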