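"""Seeded generators for every stimulus class the experiments need.

Four families of inputs drive the simulations:

* sinusoidally modulated noisy input rates (phase-advance experiments),
* piecewise-constant pattern sequences with one-hot target voltages
  (the time-continuous classification task),
* teacher-network targets that are instantaneous functions of the low-pass
  filtered input (function-learning / teacher–student experiments), and
* smooth correlated multichannel traces (surrogate field potentials for the
  recurrent pattern-completion experiment).

All generators are pure functions of a :class:`GeneratorConfig`: a fixed seed
yields byte-identical output.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from .network import Activation, NetworkParams, StimulusTrace, feedforward_pass
from .signal import Series, low_pass

__all__ = [
    "GeneratorConfig",
    "gen_sinusoid",
    "gen_smooth_mix",
    "gen_pattern_task",
    "gen_teacher_targets",
    "gen_surrogate_field_traces",
    "PatternTask",
    "SurrogateFieldData",
    "add_bias_channel",
]


@dataclass(frozen=True)
class GeneratorConfig:
    """Shared generator settings: seed, time step (ms) and duration (ms)."""

    seed: int
    dt: float
    duration: float

    def __post_init__(self) -> None:
        if self.dt <= 0 or self.duration <= 0:
            raise ValueError("dt and duration must be positive")

    @property
    def n_steps(self) -> int:
        return int(round(self.duration / self.dt))

    def rng(self) -> np.random.Generator:
        return np.random.default_rng(self.seed)


def gen_sinusoid(
    freq: float,
    amplitude: float,
    offset: float,
    noise_sd: float,
    cfg: GeneratorConfig,
    n_channels: int = 1,
) -> StimulusTrace:
    """Sinusoidally modulated noisy input rates; no targets.

    ``r_in(t) = offset + amplitude·sin(2π f t) + N(0, noise_sd²)`` on every
    channel (independent noise per channel).
    """
    if freq < 0:
        raise ValueError("freq must be non-negative")
    rng = cfg.rng()
    t = cfg.dt * np.arange(cfg.n_steps)
    base = offset + amplitude * np.sin(2.0 * np.pi * freq * 1e-3 * t)
    r = base[:, None] + rng.normal(0.0, noise_sd, size=(cfg.n_steps, n_channels)) \
        if noise_sd > 0 else np.tile(base[:, None], (1, n_channels))
    return StimulusTrace(r, np.zeros((cfg.n_steps, 0)), cfg.dt)


def gen_smooth_mix(
    cfg: GeneratorConfig,
    n_channels: int = 1,
    freqs_hz: Sequence[float] = (1.0, 2.0, 3.0),
    amplitude: float = 0.5,
    offset: float = 0.0,
    freq_jitter: float = 0.0,
) -> StimulusTrace:
    """Smooth multichannel test signal: per-channel sum of sinusoids with
    random phases and amplitudes; used for operator and equilibrium tests.

    ``freq_jitter`` scales a per-channel random detuning of each base
    frequency (uniform in ±jitter·f), making the channels incommensurate so
    a long trace fills its amplitude region instead of retracing one curve —
    useful when the trace serves as training data for function learning.
    """
    rng = cfg.rng()
    t = cfg.dt * np.arange(cfg.n_steps)
    r = np.full((cfg.n_steps, n_channels), float(offset))
    for f in freqs_hz:
        amp = amplitude * rng.uniform(0.5, 1.0, size=n_channels) / len(freqs_hz)
        phase = rng.uniform(0.0, 2.0 * np.pi, size=n_channels)
        f_eff = f * (1.0 + freq_jitter * rng.uniform(-1.0, 1.0, size=n_channels))
        r += amp[None, :] * np.sin(
            2.0 * np.pi * 1e-3 * f_eff[None, :] * t[:, None] + phase[None, :]
        )
    return StimulusTrace(r, np.zeros((cfg.n_steps, 0)), cfg.dt)


@dataclass
class PatternTask:
    """A pattern-classification stimulus stream with its labels."""

    stimulus: StimulusTrace
    labels: np.ndarray            # (n_samples,) class index per presentation
    prototypes: np.ndarray        # (n_classes, input_dim)
    steps_per_pattern: int


def gen_pattern_task(
    n_classes: int,
    input_dim: int,
    presentation_ms: float,
    n_samples: int,
    noise_sd: float,
    cfg: GeneratorConfig,
    target_hi: float = 1.0,
    target_lo: float = 0.0,
    beta: float = 0.1,
    sparsity: float = 0.25,
) -> PatternTask:
    """Piecewise-constant noisy pattern sequence with one-hot target voltages.

    Class prototypes are fixed random points in [0, 1]^input_dim with a
    sparse support (a fraction ``sparsity`` of the channels active at
    U[0.5, 1], the rest zero — image-like, largely class-distinct features);
    each presentation holds a noisy instance of a uniformly drawn class for
    ``presentation_ms`` while the target voltage is ``target_hi`` on the
    class output and ``target_lo`` elsewhere, switching instantaneously with
    the input.  ``sparsity=1`` gives dense uniform prototypes.
    ``cfg.duration`` is ignored; the stream length is
    ``n_samples · presentation_ms``.
    """
    if n_classes < 2:
        raise ValueError("need at least two classes")
    if not 0 < sparsity <= 1:
        raise ValueError("sparsity must lie in (0, 1]")
    rng = cfg.rng()
    if sparsity >= 1.0:
        protos = rng.uniform(0.0, 1.0, size=(n_classes, input_dim))
    else:
        protos = np.zeros((n_classes, input_dim))
        k = max(1, int(round(sparsity * input_dim)))
        for c in range(n_classes):
            on = rng.choice(input_dim, size=k, replace=False)
            protos[c, on] = rng.uniform(0.5, 1.0, size=k)
    labels = rng.integers(0, n_classes, size=n_samples)
    steps = int(round(presentation_ms / cfg.dt))
    if steps < 1:
        raise ValueError("presentation_ms must cover at least one time step")
    r = np.empty((n_samples * steps, input_dim))
    u_star = np.full((n_samples * steps, n_classes), float(target_lo))
    for i, lab in enumerate(labels):
        inst = protos[lab]
        if noise_sd > 0:
            inst = np.clip(inst + rng.normal(0.0, noise_sd, size=input_dim), 0.0, 1.0)
        r[i * steps:(i + 1) * steps] = inst
        u_star[i * steps:(i + 1) * steps, lab] = target_hi
    stim = StimulusTrace(r, u_star, cfg.dt, beta=beta)
    return PatternTask(stim, labels, protos, steps)


def gen_teacher_targets(
    teacher: NetworkParams,
    act: Activation,
    r_in: np.ndarray,
    dt: float,
    beta: float = 0.1,
) -> StimulusTrace:
    """Targets as an instantaneous function of the low-pass filtered input.

    The teacher is a feedforward network evaluated at its error-free
    equilibrium: ``u*_o(t) = F*(r̄_in(t))`` with layer-wise
    ``u_l = W_l r̄_{l−1}``.  The teacher's own ODE is never integrated — the
    target is by definition an instantaneous map of ``r̄_in``.
    """
    r_in = np.atleast_2d(np.asarray(r_in, dtype=float))
    r_bar = low_pass(Series(r_in, dt), teacher.tau).values
    n_steps = r_in.shape[0]
    n_out = len(teacher.output_indices)
    u_star = np.empty((n_steps, n_out))
    for k in range(n_steps):
        u_star[k] = feedforward_pass(teacher, act, r_bar[k])[-1]
    return StimulusTrace(r_in, u_star, dt, beta=beta)


@dataclass
class SurrogateFieldData:
    """Correlated surrogate field-potential traces with a train/test split."""

    train: StimulusTrace
    test: StimulusTrace
    test_nudge_mask: np.ndarray   # False on the free-running channels


def gen_surrogate_field_traces(
    n_channels: int,
    corr_length_ms: float,
    cfg: GeneratorConfig,
    latent_rank: int = 3,
    private_sd: float = 0.3,
    amplitude: float = 0.8,
    train_fraction: float = 0.5,
    free_fraction: float = 0.25,
    beta: float = 0.1,
) -> SurrogateFieldData:
    """Smooth correlated multichannel traces (surrogate field potentials).

    Channels share a low-rank latent Ornstein–Uhlenbeck drive (correlation
    time ``corr_length_ms``) plus private OU noise, scaled so the traces span
    roughly ±1–2.  The record is split into a training and a test window, and
    a random ``free_fraction`` of channels is marked un-nudged for the
    pattern-completion protocol.  The traces are targets for output neurons;
    the input dimension is zero.
    """
    if n_channels < 2:
        raise ValueError("need at least two channels")
    if corr_length_ms <= 0:
        raise ValueError("corr_length_ms must be positive")
    rng = cfg.rng()
    n = cfg.n_steps
    a = np.exp(-cfg.dt / corr_length_ms)
    kick = np.sqrt(1.0 - a * a)

    def ou(cols: int) -> np.ndarray:
        z = np.empty((n, cols))
        z[0] = rng.normal(size=cols)
        noise = rng.normal(size=(n - 1, cols))
        for k in range(1, n):
            z[k] = a * z[k - 1] + kick * noise[k - 1]
        return z

    latent = ou(latent_rank)
    mixing = rng.normal(size=(latent_rank, n_channels)) / np.sqrt(latent_rank)
    x = latent @ mixing + private_sd * ou(n_channels)
    x *= amplitude / np.std(x, axis=0, keepdims=True)
    split = int(round(train_fraction * n))
    free = rng.choice(n_channels, size=max(1, int(round(free_fraction * n_channels))),
                      replace=False)
    mask = np.ones(n_channels, dtype=bool)
    mask[free] = False
    empty = np.zeros((0, 0))
    train = StimulusTrace(np.zeros((split, 0)), x[:split], cfg.dt, beta=beta)
    test = StimulusTrace(np.zeros((n - split, 0)), x[split:], cfg.dt, beta=beta,
                         nudge_mask=mask)
    return SurrogateFieldData(train, test, mask)


def add_bias_channel(stim: StimulusTrace) -> StimulusTrace:
    """Append a constant-rate-1 input channel (bias unit) to a stimulus."""
    ones = np.ones((stim.n_steps, 1))
    return StimulusTrace(np.hstack([stim.r_in, ones]), stim.u_star, stim.dt,
                         stim.beta, stim.nudge_mask)
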