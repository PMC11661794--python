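# Smooth-stimulus simulation of a layered network riding its moving equilibrium.
name: moving-equilibrium-demo
seed: 1
network:
  kind: layered
  sizes: [5, 20, 10, 3]
  tau: 10.0
  activation: logistic
stimulus:
  generator: smooth_mix
  n_channels: 5
  amplitude: 1.0
  offset: 0.5
  duration: 300.0
integration:
  integrator: implicit
  dt: 0.1
  record_every: 10
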