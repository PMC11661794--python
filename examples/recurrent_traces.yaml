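# Recurrent trace learning: 56 of 96 neurons nudged by correlated surrogate
# field traces; hidden neurons learn to embed them (run with `nla train`).
name: recurrent-trace-learning
seed: 7
network:
  kind: recurrent
  n: 96
  n_in: 0
  n_out: 56
  tau: 10.0
  activation: logistic
stimulus:
  generator: fields
  n_channels: 56
  corr_length_ms: 150.0
  latent_rank: 4
  duration: 16000.0
  beta: 0.1
integration:
  integrator: implicit
  dt: 1.0
  record_every: 100
learning:
  eta: 2.0e-3
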