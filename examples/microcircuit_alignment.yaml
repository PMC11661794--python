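# Lateral interneuron circuit learning to cancel top-down feedback
# (loop alignment) with frozen forward weights and no output nudging.
name: microcircuit-alignment-demo
seed: 5
network:
  kind: layered
  sizes: [10, 30, 5]
  tau: 10.0
  activation: hard_sigmoid
  weight_sd: 0.5
  weight_clip: 1.5
stimulus:
  generator: patterns
  n_classes: 5
  input_dim: 10
  presentation_ms: 10.0
  n_samples: 800
  noise_sd: 0.2
  beta: 0.0
integration:
  integrator: explicit
  dt: 0.25
  record_every: 400
microcircuit:
  n_interneurons: [40]
  beta_I: 0.5
  eta_IP: 0.01
  eta_PI: 0.01
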