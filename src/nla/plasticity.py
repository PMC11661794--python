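"""Real-time dendritic error plasticity and its reference gradients.

The learning rule is strictly local — "postsynaptic error times low-pass
filtered presynaptic rate":

    dW/dt = η (u − W r̄) r̄ᵀ .

Along the moving-equilibrium trajectory this rule is gradient descent on the
Lagrangian ``L = E^M + β C`` for any nudging strength β, and on the cost
``C`` alone in the weak-nudging limit β → 0 when the error is up-scaled by
1/β.  Two independent oracles make those statements executable:

* :func:`finite_difference_dL_dW` perturbs each weight, re-equilibrates the
  self-consistent state by damped fixed-point iteration (deliberately not one
  of the production integrators), and central-differences the Lagrangian;
* :func:`backprop_reference` runs classical error backpropagation on the
  instantaneous feedforward pass of a layered network at a single time step.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Optional

import numpy as np

from .network import (
    Activation,
    NetworkParams,
    NetworkState,
    StimulusTrace,
    TrajectoryRecord,
    _STEPPERS,
    apical_error_dynamic,
    embed_target_error,
    equilibrium_residual,
    feedforward_pass,
    iterate_samples,
    lagrangian,
    mismatch_error,
)

__all__ = [
    "LearningConfig",
    "GradientBundle",
    "rt_deep_update",
    "backprop_reference",
    "solve_equilibrium",
    "finite_difference_dL_dW",
    "finite_difference_dC_dW",
    "train_online",
    "TrainingDivergenceError",
]


class TrainingDivergenceError(RuntimeError):
    """Raised when weight norms exceed the configured bound during training."""


class EquilibrationError(RuntimeError):
    """Raised when the fixed-point oracle does not converge."""


@dataclass
class LearningConfig:
    """Plasticity settings for the online trainer.

    ``eta`` is the learning rate; ``eta_schedule`` optionally maps simulation
    time (ms) to a rate as a piecewise-constant list of ``(t_from_ms, eta)``
    pairs.  ``update_cadence`` applies the accumulated update every k steps
    (1 = continuously active plasticity, the default and the model's normal
    operating mode).  ``weight_bound`` aborts training when any |W| exceeds it.
    """

    eta: float = 1e-3
    eta_schedule: Optional[list[tuple[float, float]]] = None
    plasticity_on: bool = True
    update_cadence: int = 1
    weight_bound: float = 1e3

    def __post_init__(self) -> None:
        if self.eta < 0:
            raise ValueError("eta must be non-negative")
        if self.update_cadence < 1:
            raise ValueError("update_cadence must be >= 1")

    def rate_at(self, t_ms: float) -> float:
        if self.eta_schedule is None:
            return self.eta
        eta = self.eta
        for t_from, value in self.eta_schedule:
            if t_ms >= t_from:
                eta = value
        return eta


@dataclass
class GradientBundle:
    """Per-weight-matrix gradients aligned with :class:`NetworkParams`."""

    dW_in: np.ndarray
    dW_net: np.ndarray

    def as_vector(self) -> np.ndarray:
        return np.concatenate([self.dW_in.ravel(), self.dW_net.ravel()])

    def masked(self, params: NetworkParams) -> "GradientBundle":
        return GradientBundle(self.dW_in * params.mask_in, self.dW_net * params.mask_net)


def rt_deep_update(
    u: np.ndarray, r_bar: np.ndarray, params: NetworkParams, eta: float = 1.0
) -> GradientBundle:
    """Local plasticity ``η (u − W r̄) r̄ᵀ`` split into input/network blocks.

    Entries for structurally absent connections are zeroed.
    """
    e_mm = mismatch_error(params, u, r_bar)
    m = params.n_in
    g = GradientBundle(
        eta * np.outer(e_mm, r_bar[:m]),
        eta * np.outer(e_mm, r_bar[m:]),
    )
    return g.masked(params)


def backprop_reference(
    params: NetworkParams,
    act: Activation,
    r_bar_in: np.ndarray,
    u_star: np.ndarray,
    beta: float,
    nudge_mask: Optional[np.ndarray] = None,
) -> GradientBundle:
    """Classical error backpropagation on the pure feedforward pass.

    The instantaneous pass ``u_l = W_l r̄_{l−1}`` carries no error correction;
    the output error ``ē_N = β (u* − u_N)`` (masked) is propagated backwards
    through the transposed forward weights modulated by ρ', and the gradient
    for layer l is ``ē_l r̄_{l−1}ᵀ``.
    """
    sls = params.layer_slices()
    if nudge_mask is None:
        nudge_mask = np.ones(len(u_star), dtype=bool)
    us = feedforward_pass(params, act, r_bar_in)
    rs = [np.atleast_1d(r_bar_in)] + [act(u)[0] for u in us[:-1]]
    rps = [act(u)[1] for u in us]
    errors: list[np.ndarray] = [np.zeros(0)] * len(us)
    errors[-1] = beta * np.where(nudge_mask, u_star - us[-1], 0.0)
    for l in range(len(us) - 2, -1, -1):
        W_next = params.W_net[sls[l + 1], sls[l]]
        errors[l] = rps[l] * (W_next.T @ errors[l + 1])
    dW_in = np.zeros_like(params.W_in)
    dW_net = np.zeros_like(params.W_net)
    r_in = np.atleast_1d(r_bar_in)
    for l in range(len(us)):
        dW_in[sls[l]] = np.outer(errors[l], r_in)  # mask keeps bias columns only
        if l > 0:
            dW_net[sls[l], sls[l - 1]] = np.outer(errors[l], rs[l])
    return GradientBundle(dW_in, dW_net).masked(params)


def solve_equilibrium(
    params: NetworkParams,
    act: Activation,
    r_bar_in: np.ndarray,
    u_star: np.ndarray,
    beta: float,
    nudge_mask: Optional[np.ndarray] = None,
    u0: Optional[np.ndarray] = None,
    alpha: float = 0.1,
    tol: float = 1e-10,
    max_iter: int = 100_000,
) -> np.ndarray:
    """Self-consistent state ``u = W r̄(u) + ē(u)`` by damped fixed-point iteration.

    ``u ← u + α (W r̄ + ē − u)``; deliberately independent of the production
    Euler integrators so it can serve as their oracle.  Raises
    :class:`EquilibrationError` on non-convergence.
    """
    if nudge_mask is None:
        nudge_mask = np.ones(len(u_star), dtype=bool)
    u = np.zeros(params.n) if u0 is None else np.asarray(u0, dtype=float).copy()
    m = params.n_in
    r_bar = np.empty(m + params.n)
    r_bar[:m] = np.atleast_1d(r_bar_in)
    for _ in range(max_iter):
        r_bar[m:], _ = act(u)
        e_star = embed_target_error(params, u, u_star, nudge_mask)
        e_bar = apical_error_dynamic(params, act, u, r_bar, beta, e_star)
        step = params.W_in @ r_bar[:m] + params.W_net @ r_bar[m:] + e_bar - u
        u = u + alpha * step
        if np.max(np.abs(step)) < tol:
            return u
    raise EquilibrationError(
        f"fixed-point iteration did not reach tol={tol} in {max_iter} iterations"
    )


def _fd_gradient(
    scalar_of_state: Callable[[np.ndarray, NetworkParams], float],
    params: NetworkParams,
    act: Activation,
    r_bar_in: np.ndarray,
    u_star: np.ndarray,
    beta: float,
    nudge_mask: Optional[np.ndarray],
    epsilon: float,
    tol: float,
) -> GradientBundle:
    if epsilon <= 0:
        raise ValueError("epsilon must be positive")
    base = solve_equilibrium(params, act, r_bar_in, u_star, beta, nudge_mask, tol=tol)

    def value(p: NetworkParams) -> float:
        u = solve_equilibrium(p, act, r_bar_in, u_star, beta, nudge_mask, u0=base, tol=tol)
        return scalar_of_state(u, p)

    out = GradientBundle(np.zeros_like(params.W_in), np.zeros_like(params.W_net))
    for W, mask, dW in (
        (params.W_in, params.mask_in, out.dW_in),
        (params.W_net, params.mask_net, out.dW_net),
    ):
        for idx in np.argwhere(mask):
            i, j = idx
            p = params.copy()
            target = p.W_in if W is params.W_in else p.W_net
            target[i, j] = W[i, j] + epsilon
            hi = value(p)
            target[i, j] = W[i, j] - epsilon
            lo = value(p)
            dW[i, j] = (hi - lo) / (2.0 * epsilon)
    return out


def finite_difference_dL_dW(
    params: NetworkParams,
    act: Activation,
    r_bar_in: np.ndarray,
    u_star: np.ndarray,
    beta: float,
    nudge_mask: Optional[np.ndarray] = None,
    epsilon: float = 1e-5,
    tol: float = 1e-12,
) -> GradientBundle:
    """Total derivative dL/dW through the self-consistent state (oracle).

    Each structurally present weight is perturbed by ±ε, the network is
    re-equilibrated, and the Lagrangian is central-differenced.  Because the
    state gradient vanishes at equilibrium, this total derivative equals the
    partial one, i.e. ``−ē r̄ᵀ`` — which is exactly what the local rule
    implements.
    """
    nm = np.ones(len(u_star), dtype=bool) if nudge_mask is None else nudge_mask

    def L_of(u: np.ndarray, p: NetworkParams) -> float:
        m = p.n_in
        r_bar = np.concatenate([np.atleast_1d(r_bar_in), act(u)[0]])
        e_star = embed_target_error(p, u, u_star, nm)
        return lagrangian(p, u, r_bar, beta, e_star)[0]

    return _fd_gradient(L_of, params, act, r_bar_in, u_star, beta, nudge_mask, epsilon, tol)


def finite_difference_dC_dW(
    params: NetworkParams,
    act: Activation,
    r_bar_in: np.ndarray,
    u_star: np.ndarray,
    beta: float,
    nudge_mask: Optional[np.ndarray] = None,
    epsilon: float = 1e-5,
    tol: float = 1e-12,
) -> GradientBundle:
    """Total derivative dC/dW of the output cost through the equilibrated state."""
    nm = np.ones(len(u_star), dtype=bool) if nudge_mask is None else nudge_mask

    def C_of(u: np.ndarray, p: NetworkParams) -> float:
        e_star = embed_target_error(p, u, u_star, nm)
        return 0.5 * float(e_star @ e_star)

    return _fd_gradient(C_of, params, act, r_bar_in, u_star, beta, nudge_mask, epsilon, tol)


def train_online(
    params: NetworkParams,
    act: Activation,
    stim: StimulusTrace,
    cfg: LearningConfig,
    integrator: str = "explicit",
    warmup_tau: float = 10.0,
    record_every: int = 100,
    plasticity_gate: Optional[Callable[[int], bool]] = None,
) -> tuple[NetworkParams, TrajectoryRecord]:
    """Interleave one integrator step and one plasticity application per dt.

    Synaptic plasticity is continuously active (Euler update ``W += Ẇ dt``
    each step); both the weight derivative and the voltage derivative are
    computed from the same pre-step state.  ``plasticity_gate`` may suppress
    updates on selected steps (used by the "no plasticity during transients"
    ablation); warm-up steps never update weights.  Returns the trained
    parameters (the input ``params`` is not modified) and a trajectory record
    that additionally logs weight norms in ``meta['w_norm']``.
    """
    p = params.copy()
    stepper = _STEPPERS[integrator]
    state = NetworkState.zeros(p.n)
    dt = stim.dt
    m = p.n_in
    logs: dict[str, list] = {k: [] for k in ("t", "u", "r_bar", "e_bar", "L", "E_M", "C", "residual")}
    w_norms: list[float] = []
    for k, sample in iterate_samples(stim, p.tau, warmup_tau):
        u = state.u
        r_net, _ = act(u)
        r_bar = np.concatenate([sample.r_bar_in, r_net])
        if cfg.plasticity_on and k >= 0 and (plasticity_gate is None or plasticity_gate(k)):
            if k % cfg.update_cadence == 0:
                eta = cfg.rate_at(k * dt)
                e_mm = mismatch_error(p, u, r_bar)
                scale = eta * dt * cfg.update_cadence
                p.W_in += scale * np.outer(e_mm, r_bar[:m]) * p.mask_in
                p.W_net += scale * np.outer(e_mm, r_bar[m:]) * p.mask_net
                if k % 256 == 0 and (
                    max(np.max(np.abs(p.W_in), initial=0.0), np.max(np.abs(p.W_net)))
                    > cfg.weight_bound
                ):
                    raise TrainingDivergenceError(
                        f"weight magnitude exceeded {cfg.weight_bound} at step {k} "
                        f"(t={k * dt:.1f} ms); reduce eta or beta"
                    )
        if k >= 0 and k % record_every == 0:
            e_star = embed_target_error(p, u, sample.u_star, sample.nudge_mask)
            e_bar = apical_error_dynamic(p, act, u, r_bar, sample.beta, e_star)
            L, E_M, C = lagrangian(p, u, r_bar, sample.beta, e_star)
            logs["t"].append(k * dt)
            logs["u"].append(u.copy())
            logs["r_bar"].append(r_bar)
            logs["e_bar"].append(e_bar)
            logs["L"].append(L)
            logs["E_M"].append(E_M)
            logs["C"].append(C)
            logs["residual"].append(equilibrium_residual(p, u, r_bar, e_bar))
            w_norms.append(float(np.linalg.norm(p.W_in) ** 2 + np.linalg.norm(p.W_net) ** 2) ** 0.5)
        state = stepper(p, act, state, sample, dt, step=k)
    rec = TrajectoryRecord(
        np.asarray(logs["t"]), np.asarray(logs["u"]), np.asarray(logs["r_bar"]),
        np.asarray(logs["e_bar"]), np.asarray(logs["L"]), np.asarray(logs["E_M"]),
        np.asarray(logs["C"]), np.asarray(logs["residual"]),
        {"integrator": integrator, "w_norm": np.asarray(w_norms)},
    )
    return p, rec
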