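# Methods

## Model

The package simulates networks of rate neurons whose somatic voltages
`u` obey a *prospective* leaky-integrator law derived from an energy
principle.  Each neuron compares its somatic voltage with its basal
dendritic prediction; the instantaneous mismatch is

    ē_i = u_i − Σ_j W_ij r̄_j ,

where `r̄ = (r̄_in, ρ(u))` stacks the low-pass filtered input rates and the
network rates, and `W = (W_in, W_net)` the corresponding synaptic weights.
The network energy is the sum of squared mismatches plus a target cost on a
subset `O` of output neurons, weighted by the nudging strength β:

    L = ½ Σ_i ē_i² + (β/2) Σ_{o∈O} (u*_o − u_o)² .

Requiring stationarity of the time-integral of `L` with respect to
discounted *future* voltages yields dynamics in which rates and errors enter
with a linear lookahead `(1 + τ d/dt)`:

    τ u̇ = −u + W (r̄ + τ dr̄/dt) + (ē + τ dē/dt) ,
    ē   = ρ'(u) ∘ W_netᵀ (u − W r̄) + β ē* ,      ē*_o = u*_o − u_o .

The lookahead exactly cancels the membrane low-pass filter, so after a
transient of order τ the trajectory rides the **moving equilibrium**
`u = W r̄(u) + ē(u)`: the output is at every instant a function of the
filtered input and the feedback error, independent of network depth.  The
per-step diagnostic `‖u − W r̄ − ē‖ / (1 + ‖u‖)` ("equilibrium residual")
quantifies how closely a simulation tracks this manifold.

Two consequences are implemented as executable checks:

1. **Real-time gradient learning.**  The local rule
   `dW/dt = η (u − W r̄) r̄ᵀ` is gradient descent on `L` at every moment of
   the trajectory, and on the cost `C` alone in the weak-nudging limit
   (errors up-scaled by 1/β).  The package verifies both statements against
   a perturb-and-re-equilibrate central-difference oracle and against
   classical per-step backpropagation on the instantaneous feedforward pass.
2. **Microcircuit error learning.**  Instead of the transposed weights, a
   pyramidal–interneuron circuit can extract the errors: interneuron
   voltages are a convex combination
   `u^I = (1−β^I) W^IP r̄ + β^I B^IP u_next`, the apical voltage is
   `ē^A = B u_next − W^PI u^I`, and both lateral weight families descend
   their own mismatch energies.  This drives the lateral loop `W^PI W^IP`
   into alignment with the vertical loop `B W_next` (Frobenius angle → 0),
   after which the apical voltages carry the B-backpropagated errors.

## Numerical integration

The voltage law is an implicit ODE (`u̇` appears on both sides).  Two
forward-Euler integrators advance it:

* **implicit** — the right-hand side is evaluated with the previous step's
  `u̇`; the derivative of the error is `ē'(u)·u̇_prev + ∂ē/∂t`.
* **explicit** — `u̇` is isolated by solving `τ H u̇ = −f − τ ∂f/∂t` with
  `f = u − W r̄ − ē` and `H = 1 − W_net ρ' − ē'`.  With transposed feedback
  `H` is symmetric and is factorised by Cholesky (a failure there raises a
  stability error advising smaller β); with random fixed feedback
  (microcircuit) `H` is genuinely asymmetric and an LU solve is used —
  symmetrising first would solve a different system.

Both steppers carry the *same* analytic `∂/∂t` terms
(`∂f/∂t = −W_in dr̄_in/dt − ∂ē/∂t`, with `dr̄_in/dt = (r_in − r̄_in)/τ` taken
from the filter identity and `du*/dt` by backward difference), so they solve
the same ODE and agree to O(dt) — the cross-integrator test finds ~5·10⁻⁵
relative sup-norm difference at dt = 0.1 ms.  By default `ē'` omits the
`diag(ρ'' ∘ W_netᵀ ē)` curvature term of smooth activations
(`include_curvature` restores it): the ρ''-free Hessian equals
`(1 − ρ' W_netᵀ)(1 − W_net ρ') + β·mask`, which is structurally positive
semidefinite for feedforward nets, whereas the curvature diagonal can make
`H` indefinite when the mismatch is large (e.g. during warm-up).

Initialisation "in the infinite past" is approximated by a warm-up window
(default 10 membrane time constants) during which the first stimulus frame
is held; nothing is recorded or learned during warm-up.  The implicit
stepper re-attaches to the equilibrium manifold only at rate 1/τ after a
genuine discontinuity in the stimulus (its lagged derivative cannot follow a
delta); the explicit stepper preserves the manifold through discontinuities
and is therefore used for pattern-sequence experiments, as well as whenever
plasticity is on.

A numba-compiled replica of the explicit stepper with interleaved plasticity
(`nla._fast`) runs the long training experiments ~5× faster; a test pins it
to the reference implementation at 10⁻¹² tolerance.

## Parameters

| parameter | default | meaning |
|---|---|---|
| τ | 10 ms | membrane and input-filter time constant |
| β | 0.1 | output nudging strength (0 = free-running) |
| β^I | 0 – 0.9 | interneuron nudging (training aid for the lateral circuit) |
| η | 10⁻³ – 0.2 /ms | learning rate; stability requires η·T_pres·‖r̄‖² ≲ 1 |
| dt | 0.05 – 1 ms | Euler step; 0.05 ms for 5 ms presentations |
| weight init | N(0, 0.1²) clip ±0.3 or N(0, 0.01²) clip ±0.03 | per experiment class |
| feedback init (B, B^IP) | 5·N(0, 0.01²) clip ±0.15 | fixed random backprojections |

## Synthetic data

The generators produce every input the experiments need; all are pure
functions of a seed.

* **Sinusoidal drives** (phase-advance experiments) and **smooth
  multichannel mixes** (sums of low-frequency sinusoids with random phases;
  optional per-channel frequency detuning so long traces fill their
  amplitude region rather than retracing one curve — used when the trace is
  training data for function learning).
* **Pattern sequences**: piecewise-constant noisy instances of fixed random
  class prototypes with one-hot target voltages switching instantaneously
  with the input.  Prototypes have sparse supports (25% of channels) —
  image-like, largely class-distinct features.  With dense uniform
  prototypes the 0.5τ-presentation task is dominated by an irreducible
  ~29% error floor (a ridge-regression oracle on the filtered input attains
  no better), because the input filter mixes consecutive patterns; the
  floor would mask the lookahead-vs-ablation contrast the task exists to
  measure.  Even with sparse prototypes a floor of roughly a quarter of the
  patterns remains at 0.5τ — short-presentation performance is limited by
  the input filter, not by the learning rule.
* **Teacher targets**: `u*(t)` is the instantaneous feedforward map of the
  low-pass filtered input through a frozen teacher network (the teacher's
  ODE is never integrated; the target is by definition an instantaneous
  function).
* **Surrogate field potentials**: correlated Ornstein–Uhlenbeck channels
  (shared low-rank latent drive plus private noise, scaled to roughly
  ±1–2) with a train/test split and a nudged/free channel partition for the
  pattern-completion protocol.  They emulate the smoothness and shared
  structure of intracranial field recordings, not their spectra or
  non-stationarity: passing the completion test shows the network can embed
  and reproduce correlated traces, not that it models physiological data.

## Experiment design choices

These are desk-scale reductions of simulations originally run at much
larger width and duration; sizes were chosen so each experiment completes
in seconds to a couple of minutes.

* **Moving equilibrium**: 5-20-10-3 logistic net, smooth inputs/targets,
  dt = 0.1 ms, β = 0.1.
* **Gradient oracle**: 8-neuron recurrent logistic net; damped fixed-point
  iteration (α = 0.1, tol 10⁻¹⁰) re-equilibrates after each ±10⁻⁵ weight
  perturbation — deliberately independent of the production integrators.
* **Backprop limit**: 10-8-4 net, β ∈ {10⁻¹, 10⁻², 10⁻³}.
* **Loop alignment**: 10-30(40 interneurons)-5.  The frozen forward weights
  use unit-norm rows scaled by gain 6 with per-unit thresholds centred in
  the input range (via a bias channel): at this scale the hidden dimension
  exceeds the input dimension, so the hidden-rate covariance must draw its
  rank from the nonlinearity, and near-step units give it a usable
  spectrum.  Interneuron nudging is strong during training (β^I = 0.9); the
  apical-error readout against `B ē₂` is taken at β^I = 0 because nudging
  attenuates the apical voltage by exactly (1 − β^I).  The negative control
  uses 3 interneurons (< min(30, 5) = 5), for which exact alignment is
  rank-impossible.
* **Fast-pattern classification**: 64-50-10 step-linear net with a
  learnable per-layer bias (constant-rate-1 input channel), presentations of
  0.5τ at dt = 0.05 ms, β = 0.1, η = 0.02/ms, 4000 training presentations.
  Hidden thresholds start at +0.3 so the step-linear units begin inside
  their active range at this reduced width; without the offset, units near
  threshold are progressively silenced by the weakly negative mean error
  that the switch-lag pairing produces, and the network loses capacity over
  long runs.  The no-lookahead ablation (`τ u̇ = −u + W r̄ + ē`) is trained
  and evaluated identically.
* **Teacher–student**: matched 2-3-1 logistic networks.  The teacher is
  standardised — unit-norm hidden input directions with gain 0.6 and an
  output scaled to a fixed signal size — because strongly nonlinear
  3-hidden-unit fits are seed-brittle (a nonconvex recovery that fails for
  a noticeable fraction of random teachers regardless of training time).
  β = 0.3, η = 0.2/ms dropping to 0.05 after 60% of the 120 s run.  The
  "initial cost" is measured on the untrained nudged student with
  plasticity off, since learning at this rate already reduces the cost
  within the first seconds.

## Numerical and degenerate-case conventions

* The low-pass filter uses the exact exponential update
  `x̄[k] = x̄[k−1]·e^(−dt/τ) + x[k−1]·(1 − e^(−dt/τ))`, initialised at the
  first sample; the lookahead derivative is the causal backward difference,
  with the first sample copied from the second.
* Structurally absent synapses (including the diagonal of recurrent nets)
  are masked out of every weight update.
* Output rows of `B` and `W^PI` are structurally zero: the top layer
  receives only target nudging.
* Interneurons are linear and their voltage is assigned algebraically at
  the end of each step; their own time constant is absorbed into the
  pyramidal dynamics.
* Non-finite voltages raise an error naming the step; weight norms beyond a
  configurable bound abort training with diagnostics.
* A single integer seed drives every initialisation and generator; records
  store it together with a configuration hash.

## Known limitations

* The implicit stepper degrades to O(dt)-after-transient accuracy at
  stimulus discontinuities; use the explicit stepper for step-like inputs.
* Tests on synthetic data show the mechanisms work as derived; they do not
  show that real cortical recordings are reproduced.  In particular, the
  surrogate field traces share only the gross statistical structure of such
  data.
* At 0.5τ presentations an error floor set by input filtering bounds
  attainable classification accuracy; the meaningful comparison at that
  time scale is against the per-step backprop reference and the
  no-lookahead ablation, not absolute accuracy.
* Backprojection weights are fixed random (feedback alignment); learning
  them is out of scope, as are conductance-based neurons, spiking dynamics
  and threshold adaptation.
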