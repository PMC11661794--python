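"""Least-action network dynamics with prospective rates and dendritic errors.

The model is a recurrent rate network whose somatic voltages ``u`` follow a
prospective leaky-integrator law derived from an energy principle.  Writing
``r̄ = (r̄_in, ρ(u))`` for the low-pass filtered rates, ``W = (W_in, W_net)``
for the synaptic weights, and

    ē   = ρ'(u) ∘ W_netᵀ (u − W r̄) + β ē*            (dendritic error)
    ē*  = u* − u  on nudged output neurons, else 0     (target error)

the voltage dynamics are

    τ u̇ = −u + W (r̄ + τ dr̄/dt) + (ē + τ dē/dt) ,

i.e. rates and errors enter with a linear lookahead that cancels the membrane
low-pass filter.  After a transient of order τ the trajectory rides the
*moving equilibrium* ``u = W r̄(u) + ē(u)``: the output voltage is at every
instant a function of the filtered input and the feedback error, regardless
of network depth.

Two integrators advance the same ODE:

* the **implicit** stepper evaluates the right-hand side with the previous
  step's voltage derivative (the rule a physical substrate could run), and
* the **explicit** stepper isolates ``u̇`` by solving
  ``τ H u̇ = −f − τ ∂f/∂t`` with ``f = u − W r̄ − ē`` and Hessian
  ``H = 1 − W_net ρ' − ē'`` via a symmetrised Cholesky factorisation.

Energies: mismatch ``E^M = ½‖u − W r̄‖²``, cost ``C = ½‖ē*‖²`` on nudged
outputs, Lagrangian ``L = E^M + β C``.
"""

from __future__ import annotations

import hashlib
import warnings
from dataclasses import dataclass, field
from typing import Callable, Optional, Sequence

import numpy as np
from scipy.linalg import cho_factor, cho_solve

__all__ = [
    "Activation",
    "NetworkParams",
    "NetworkState",
    "StimulusTrace",
    "TrajectoryRecord",
    "NumericalDivergenceError",
    "StabilityError",
    "rho_eval",
    "mismatch_error",
    "apical_error_dynamic",
    "error_jacobian",
    "error_time_derivative",
    "lagrangian",
    "hessian",
    "equilibrium_residual",
    "implicit_euler_step",
    "explicit_euler_step",
    "simulate",
    "feedforward_pass",
    "make_layered_params",
    "make_recurrent_params",
]


class NumericalDivergenceError(RuntimeError):
    """Raised when a voltage update produces non-finite values."""


class StabilityError(RuntimeError):
    """Raised when the Hessian of the energy is not positive definite.

    A non-PD Hessian means the implicit ODE cannot be inverted at the current
    state; reduce the nudging strength β or use a functionally feedforward
    topology (for which the Hessian is PD at small β).
    """


# ---------------------------------------------------------------------------
# activation functions
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Activation:
    """Voltage-to-rate transfer function ρ with its first two derivatives.

    Supported kinds:

    ``logistic``
        ρ(u) = 1 / (1 + exp(−u)); smooth, bounded, ρ' ≤ 1/4.
    ``hard_sigmoid``
        ρ(u) = 0 for u ≤ 0, u for 0 < u < 1, 1 for u ≥ 1 (step-linear).
    ``threshold_linear``
        ρ(u) = max(u, 0) (rectified linear).
    ``linear``
        ρ(u) = u; used for interneurons and analytic checks.
    """

    kind: str = "logistic"

    _KINDS = ("logistic", "hard_sigmoid", "threshold_linear", "linear")

    def __post_init__(self) -> None:
        if self.kind not in self._KINDS:
            raise ValueError(f"unknown activation kind {self.kind!r}; choose from {self._KINDS}")

    @property
    def smooth(self) -> bool:
        return self.kind == "logistic"

    def __call__(self, u: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Return ``(ρ(u), ρ'(u))`` elementwise."""
        u = np.asarray(u, dtype=float)
        if self.kind == "logistic":
            r = 1.0 / (1.0 + np.exp(-u))
            return r, r * (1.0 - r)
        if self.kind == "hard_sigmoid":
            r = np.minimum(np.maximum(u, 0.0), 1.0)
            return r, ((u > 0.0) & (u < 1.0)).astype(float)
        if self.kind == "threshold_linear":
            r = np.maximum(u, 0.0)
            return r, (u > 0.0).astype(float)
        return u.copy(), np.ones_like(u)

    def second(self, u: np.ndarray) -> np.ndarray:
        """ρ''(u); identically zero for the piecewise-linear kinds."""
        u = np.asarray(u, dtype=float)
        if self.kind == "logistic":
            r = 1.0 / (1.0 + np.exp(-u))
            return r * (1.0 - r) * (1.0 - 2.0 * r)
        return np.zeros_like(u)


def rho_eval(act: Activation, u: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Evaluate rate and rate derivative; thin functional wrapper."""
    return act(u)


# ---------------------------------------------------------------------------
# parameter / state containers
# ---------------------------------------------------------------------------


@dataclass
class NetworkParams:
    """All synaptic matrices and the membrane time constant.

    ``W_in`` has shape (n, m) for m input channels (m may be 0), ``W_net``
    is (n, n).  ``output_indices`` selects the subset of network neurons that
    can be nudged toward targets.  ``layer_sizes`` (network neurons only)
    declares a functionally feedforward partition under which ``W_net`` is
    strictly lower block-triangular; it is required by the layered routines
    (backprop reference, microcircuit) and optional otherwise.  ``mask_in`` /
    ``mask_net`` mark structurally present connections: plasticity is zeroed
    outside them.
    """

    W_in: np.ndarray
    W_net: np.ndarray
    tau: float
    output_indices: np.ndarray
    layer_sizes: Optional[tuple[int, ...]] = None
    mask_in: Optional[np.ndarray] = None
    mask_net: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        self.W_in = np.atleast_2d(np.asarray(self.W_in, dtype=float))
        self.W_net = np.asarray(self.W_net, dtype=float)
        self.output_indices = np.asarray(self.output_indices, dtype=int)
        n = self.W_net.shape[0]
        if self.W_net.shape != (n, n):
            raise ValueError("W_net must be square")
        if self.W_in.shape[0] != n:
            raise ValueError("W_in and W_net disagree on the number of network neurons")
        if self.tau <= 0:
            raise ValueError("tau must be positive")
        if self.layer_sizes is not None and sum(self.layer_sizes) != n:
            raise ValueError("layer_sizes must partition the network neurons")
        if self.mask_in is None:
            self.mask_in = np.ones_like(self.W_in, dtype=bool)
        if self.mask_net is None:
            self.mask_net = np.ones_like(self.W_net, dtype=bool)

    @property
    def n(self) -> int:
        return self.W_net.shape[0]

    @property
    def n_in(self) -> int:
        return self.W_in.shape[1]

    def layer_slices(self) -> list[slice]:
        if self.layer_sizes is None:
            raise ValueError("params carry no layer structure")
        edges = np.concatenate([[0], np.cumsum(self.layer_sizes)])
        return [slice(int(a), int(b)) for a, b in zip(edges[:-1], edges[1:])]

    def copy(self) -> "NetworkParams":
        return NetworkParams(
            self.W_in.copy(), self.W_net.copy(), self.tau, self.output_indices.copy(),
            self.layer_sizes, self.mask_in.copy(), self.mask_net.copy(),
        )


@dataclass
class NetworkState:
    """Instantaneous voltages plus the previous-step voltage derivative."""

    u: np.ndarray
    u_dot_prev: np.ndarray
    t: float = 0.0

    @classmethod
    def zeros(cls, n: int, t: float = 0.0) -> "NetworkState":
        return cls(np.zeros(n), np.zeros(n), t)


@dataclass
class StimulusTrace:
    """Time-aligned input rates, target voltages and nudging protocol.

    ``r_in``: array (n_steps, m); ``u_star``: array (n_steps, n_out) over the
    network's output indices (may be empty when beta == 0); ``beta``: nudging
    strength; ``nudge_mask``: boolean (n_out,) — outputs with mask False
    contribute neither to the target error nor to the cost.
    """

    r_in: np.ndarray
    u_star: np.ndarray
    dt: float
    beta: float = 0.0
    nudge_mask: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        self.r_in = np.atleast_2d(np.asarray(self.r_in, dtype=float))
        self.u_star = np.atleast_2d(np.asarray(self.u_star, dtype=float))
        if self.r_in.shape[0] < 1:
            raise ValueError("stimulus must contain at least one step")
        if self.dt <= 0:
            raise ValueError("dt must be positive")
        if self.beta < 0:
            raise ValueError("beta must be non-negative")
        if self.u_star.size and self.u_star.shape[0] != self.r_in.shape[0]:
            raise ValueError("r_in and u_star must share their number of steps")
        n_out = self.u_star.shape[1] if self.u_star.size else 0
        if self.nudge_mask is None:
            self.nudge_mask = np.ones(n_out, dtype=bool)
        else:
            self.nudge_mask = np.asarray(self.nudge_mask, dtype=bool)
            if self.nudge_mask.shape != (n_out,):
                raise ValueError("nudge_mask must match the number of output traces")

    @property
    def n_steps(self) -> int:
        return self.r_in.shape[0]


@dataclass
class TrajectoryRecord:
    """Per-step log of a simulation: voltages, rates, errors and energies."""

    t: np.ndarray
    u: np.ndarray
    r_bar: np.ndarray
    e_bar: np.ndarray
    L: np.ndarray
    E_M: np.ndarray
    C: np.ndarray
    residual: np.ndarray
    meta: dict = field(default_factory=dict)

    def save(self, path) -> None:
        np.savez(
            path, t=self.t, u=self.u, r_bar=self.r_bar, e_bar=self.e_bar,
            L=self.L, E_M=self.E_M, C=self.C, residual=self.residual,
            meta=np.array(repr(self.meta)),
        )

    def to_csv(self, path) -> None:
        import csv

        with open(path, "w", newline="") as fh:
            w = csv.writer(fh)
            n = self.u.shape[1]
            w.writerow(
                ["time_ms"] + [f"u_{i}" for i in range(n)]
                + ["L", "E_M", "C", "residual"]
            )
            for k in range(len(self.t)):
                w.writerow(
                    [self.t[k]] + list(self.u[k])
                    + [self.L[k], self.E_M[k], self.C[k], self.residual[k]]
                )


# ---------------------------------------------------------------------------
# elementary quantities
# ---------------------------------------------------------------------------


def full_rates(act: Activation, u: np.ndarray, r_bar_in: np.ndarray) -> np.ndarray:
    """Concatenate input and network low-pass rates in the column order of W."""
    r_net, _ = act(u)
    return np.concatenate([np.atleast_1d(r_bar_in), r_net])


def mismatch_error(params: NetworkParams, u: np.ndarray, r_bar: np.ndarray) -> np.ndarray:
    """Somato-dendritic mismatch ``ē = u − W r̄`` (basal prediction residual)."""
    m = params.n_in
    if r_bar.shape[0] != m + params.n:
        raise ValueError(
            f"r_bar must stack {m} input and {params.n} network rates, got {r_bar.shape[0]}"
        )
    return u - params.W_in @ r_bar[:m] - params.W_net @ r_bar[m:]


def embed_target_error(
    params: NetworkParams, u: np.ndarray, u_star: np.ndarray, nudge_mask: np.ndarray
) -> np.ndarray:
    """Target error ``ē* = u* − u`` embedded in network coordinates (masked)."""
    e = np.zeros(params.n)
    if u_star.size:
        out = params.output_indices
        e[out] = np.where(nudge_mask, u_star - u[out], 0.0)
    return e


def apical_error_dynamic(
    params: NetworkParams,
    act: Activation,
    u: np.ndarray,
    r_bar: np.ndarray,
    beta: float,
    e_star: np.ndarray,
) -> np.ndarray:
    """Dendritic error ``ē = ρ'(u) ∘ W_netᵀ (u − W r̄) + β ē*``.

    This is the direct evaluation used by the stepping algorithm; on the
    stationary trajectory it is self-consistent with the fixed-point error
    equation ``ē = ρ'(u) ∘ W_netᵀ ē + β ē*``.
    """
    _, rp = act(u)
    return rp * (params.W_net.T @ mismatch_error(params, u, r_bar)) + beta * e_star


def error_jacobian(
    params: NetworkParams,
    act: Activation,
    u: np.ndarray,
    r_bar: np.ndarray,
    beta: float,
    nudge_mask: np.ndarray,
    include_curvature: bool = False,
) -> np.ndarray:
    """State-Jacobian ``∂ē/∂u`` of :func:`apical_error_dynamic`.

    ``J = diag(ρ'' ∘ W_netᵀ ē_mm) + ρ' ∘ W_netᵀ (1 − W_net ρ') − β M`` with
    ``M`` the diagonal output-nudging mask.  The curvature term vanishes for
    piecewise-linear activations; ``include_curvature=False`` drops it for
    smooth ones as well.
    """
    n = params.n
    _, rp = act(u)
    inner = np.eye(n) - params.W_net * rp[None, :]
    J = rp[:, None] * (params.W_net.T @ inner)
    if beta:
        m = np.zeros(n)
        m[params.output_indices] = nudge_mask.astype(float)
        J -= beta * np.diag(m)
    if include_curvature and act.smooth:
        e_mm = mismatch_error(params, u, r_bar)
        J += np.diag(act.second(u) * (params.W_net.T @ e_mm))
    return J


def error_time_derivative(
    params: NetworkParams,
    act: Activation,
    u: np.ndarray,
    r_bar_in_dot: np.ndarray,
    beta: float,
    u_star_dot: np.ndarray,
    nudge_mask: np.ndarray,
) -> np.ndarray:
    """Explicit time-dependence ``∂ē/∂t`` at fixed voltage.

    The mismatch drifts with the filtered input, the target error with the
    target trace: ``∂ē/∂t = −ρ' ∘ W_netᵀ W_in dr̄_in/dt + β M du*/dt``.
    """
    _, rp = act(u)
    out = np.zeros(params.n)
    if params.n_in:
        out -= rp * (params.W_net.T @ (params.W_in @ r_bar_in_dot))
    if beta and u_star_dot.size:
        out[params.output_indices] += beta * np.where(nudge_mask, u_star_dot, 0.0)
    return out


def lagrangian(
    params: NetworkParams,
    u: np.ndarray,
    r_bar: np.ndarray,
    beta: float,
    e_star: np.ndarray,
) -> tuple[float, float, float]:
    """Return ``(L, E_M, C)`` for the given state."""
    e_mm = mismatch_error(params, u, r_bar)
    E_M = 0.5 * float(e_mm @ e_mm)
    C = 0.5 * float(e_star @ e_star)
    return E_M + beta * C, E_M, C


def hessian(
    params: NetworkParams,
    act: Activation,
    u: np.ndarray,
    r_bar: np.ndarray,
    beta: float,
    nudge_mask: np.ndarray,
    include_curvature: bool = False,
) -> np.ndarray:
    """Energy Hessian ``H = 1 − W_net ρ' − ē'`` (not yet symmetrised)."""
    _, rp = act(u)
    J = error_jacobian(params, act, u, r_bar, beta, nudge_mask, include_curvature)
    return np.eye(params.n) - params.W_net * rp[None, :] - J


def equilibrium_residual(
    params: NetworkParams, u: np.ndarray, r_bar: np.ndarray, e_bar: np.ndarray
) -> float:
    """Normalised distance ``‖u − W r̄ − ē‖ / (1 + ‖u‖)`` from the moving equilibrium."""
    res = mismatch_error(params, u, r_bar) - e_bar
    return float(np.linalg.norm(res) / (1.0 + np.linalg.norm(u)))


# ---------------------------------------------------------------------------
# integrators
# ---------------------------------------------------------------------------


@dataclass
class StimulusSample:
    """One time slice of the stimulus as seen by a stepper."""

    r_in: np.ndarray          # raw input rates
    r_bar_in: np.ndarray      # low-pass filtered input rates (filter state)
    u_star: np.ndarray        # target voltages over output indices
    u_star_dot: np.ndarray    # backward-difference target derivative
    beta: float
    nudge_mask: np.ndarray


def _assemble(
    params: NetworkParams,
    act: Activation,
    u: np.ndarray,
    sample: "StimulusSample",
    include_curvature: bool,
) -> dict:
    """Shared per-step quantities for both integrators (each computed once)."""
    n = params.n
    tau = params.tau
    W_net = params.W_net
    r_net, rp = act(u)
    e_mm = u - params.W_in @ sample.r_bar_in - W_net @ r_net
    backproj = W_net.T @ e_mm
    beta = sample.beta
    e_star = np.zeros(n)
    if sample.u_star.size:
        out = params.output_indices
        e_star[out] = np.where(sample.nudge_mask, sample.u_star - u[out], 0.0)
    e_bar = rp * backproj + beta * e_star
    inner = np.eye(n) - W_net * rp[None, :]
    J = rp[:, None] * (W_net.T @ inner)
    if beta:
        m = np.zeros(n)
        m[params.output_indices] = sample.nudge_mask.astype(float)
        J -= beta * np.diag(m)
    if include_curvature and act.smooth:
        J += np.diag(act.second(u) * backproj)
    r_bar_in_dot = (sample.r_in - sample.r_bar_in) / tau
    drive_dot = params.W_in @ r_bar_in_dot
    e_dt = -rp * (W_net.T @ drive_dot)
    if beta and sample.u_star.size:
        e_dt[params.output_indices] += beta * np.where(
            sample.nudge_mask, sample.u_star_dot, 0.0
        )
    return {
        "r_net": r_net, "rp": rp, "e_mm": e_mm, "e_bar": e_bar,
        "J": J, "e_dt": e_dt, "drive_dot": drive_dot,
    }


def _check_finite(u: np.ndarray, step: int, what: str) -> None:
    if not np.all(np.isfinite(u)):
        raise NumericalDivergenceError(
            f"non-finite {what} at step {step}; reduce dt or the nudging strength"
        )


def implicit_euler_step(
    params: NetworkParams,
    act: Activation,
    state: NetworkState,
    sample: StimulusSample,
    dt: float,
    step: int = 0,
    include_curvature: bool = False,
) -> NetworkState:
    """One forward-Euler step of the implicit ODE.

    The voltage derivative on the right-hand side is replaced by the previous
    step's ``u̇``:

        r  = ρ(u) + τ ρ'(u) ∘ u̇_prev
        ē  = ρ'(u) ∘ W_netᵀ (u − W r̄) + β ē*
        dē/dt ≈ ē'(u) u̇_prev + ∂ē/∂t
        τ u̇ = −u + W_in r_in + W_net r + ē + τ dē/dt
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    u = state.u
    tau = params.tau
    q = _assemble(params, act, u, sample, include_curvature)
    e_bar_dot = q["J"] @ state.u_dot_prev + q["e_dt"]
    r_prospective = q["r_net"] + tau * q["rp"] * state.u_dot_prev
    drive = params.W_in @ sample.r_in + params.W_net @ r_prospective
    u_dot = (-u + drive + q["e_bar"] + tau * e_bar_dot) / tau
    u_new = u + dt * u_dot
    _check_finite(u_new, step, "voltage (implicit step)")
    return NetworkState(u_new, u_dot, state.t + dt)


def _spd_solve(H: np.ndarray, rhs: np.ndarray, symmetric: Optional[bool] = None) -> np.ndarray:
    """Solve ``H x = rhs``, by Cholesky when H is symmetric.

    With transposed feedback the Hessian is symmetric by construction (up to
    roundoff), so it is symmetrised and factorised by Cholesky; a
    factorisation failure there means H is not positive definite and raises
    :class:`StabilityError` advising smaller β or a feedforward topology.
    With random fixed feedback (feedback alignment, microcircuit) H is
    genuinely asymmetric — symmetrising would solve the wrong system — so the
    system is solved by LU instead, with a least-squares fallback and a
    warning if H is singular.  ``symmetric`` lets callers that know the
    structure skip the symmetry test.
    """
    if symmetric is None:
        symmetric = bool(
            np.max(np.abs(H - H.T)) <= 1e-9 * max(np.max(np.abs(H)), 1.0)
        )
    if symmetric:
        Hs = 0.5 * (H + H.T)
        try:
            c = cho_factor(Hs, check_finite=False)
            return cho_solve(c, rhs, check_finite=False)
        except np.linalg.LinAlgError:
            raise StabilityError(
                "energy Hessian is not positive definite; reduce beta or use "
                "a feedforward topology"
            )
    try:
        return np.linalg.solve(H, rhs)
    except np.linalg.LinAlgError:
        warnings.warn("energy Hessian is singular; using least-squares solve",
                      RuntimeWarning)
        x, *_ = np.linalg.lstsq(H, rhs, rcond=None)
        if not np.all(np.isfinite(x)):
            raise StabilityError(
                "energy Hessian solve diverged; reduce beta or use a "
                "feedforward topology"
            )
        return x


def explicit_euler_step(
    params: NetworkParams,
    act: Activation,
    state: NetworkState,
    sample: StimulusSample,
    dt: float,
    step: int = 0,
    include_curvature: bool = False,
) -> NetworkState:
    """One forward-Euler step of the explicit ODE ``τ H u̇ = −f − τ ∂f/∂t``.

    ``f = u − W r̄ − ē`` and ``∂f/∂t = −W_in dr̄_in/dt − ∂ē/∂t``; the linear
    system is solved by Cholesky on the symmetrised Hessian.
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    u = state.u
    tau = params.tau
    q = _assemble(params, act, u, sample, include_curvature)
    f = q["e_mm"] - q["e_bar"]
    H = np.eye(params.n) - params.W_net * q["rp"][None, :] - q["J"]
    df_dt = -q["drive_dot"] - q["e_dt"]
    u_dot = _spd_solve(tau * H, -f - tau * df_dt, symmetric=True)
    u_new = u + dt * u_dot
    _check_finite(u_new, step, "voltage (explicit step)")
    return NetworkState(u_new, u_dot, state.t + dt)


def no_lookahead_euler_step(
    params: NetworkParams,
    act: Activation,
    state: NetworkState,
    sample: StimulusSample,
    dt: float,
    step: int = 0,
    include_curvature: bool = False,
) -> NetworkState:
    """Ablation stepper without prospective coding: ``τ u̇ = −u + W r̄ + ē``.

    Rates and errors enter without their lookahead terms, so every layer adds
    roughly one membrane time constant of delay to the propagation of input
    changes; used as the negative control for the instantaneity property.
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    u = state.u
    r_net, _ = act(u)
    r_bar = np.concatenate([sample.r_bar_in, r_net])
    e_star = embed_target_error(params, u, sample.u_star, sample.nudge_mask)
    e_bar = apical_error_dynamic(params, act, u, r_bar, sample.beta, e_star)
    u_dot = (-u + params.W_in @ sample.r_bar_in + params.W_net @ r_net + e_bar) / params.tau
    u_new = u + dt * u_dot
    _check_finite(u_new, step, "voltage (no-lookahead step)")
    return NetworkState(u_new, u_dot, state.t + dt)


_STEPPERS: dict[str, Callable] = {
    "implicit": implicit_euler_step,
    "explicit": explicit_euler_step,
    "no_lookahead": no_lookahead_euler_step,
}


# ---------------------------------------------------------------------------
# simulation driver
# ---------------------------------------------------------------------------


def _config_hash(*parts) -> str:
    h = hashlib.sha256()
    for p in parts:
        h.update(repr(p).encode())
    return h.hexdigest()[:16]


def iterate_samples(stim: StimulusTrace, tau: float, warmup_tau: float):
    """Yield ``(k, StimulusSample)`` with the input low-pass filter advanced
    in lockstep and a warm-up window (first frame held) prepended.

    Warm-up steps carry k < 0; the filter state is initialised at the first
    raw input value.
    """
    dt = stim.dt
    a = float(np.exp(-dt / tau))
    n_warm = int(np.ceil(warmup_tau * tau / dt))
    r_bar_in = stim.r_in[0].copy()
    zero_dot = np.zeros(stim.u_star.shape[1] if stim.u_star.size else 0)
    for k in range(-n_warm, stim.n_steps):
        kk = max(k, 0)
        r_in = stim.r_in[kk]
        u_star = stim.u_star[kk] if stim.u_star.size else np.zeros(0)
        if k <= 0 or not stim.u_star.size:
            u_star_dot = zero_dot
        else:
            u_star_dot = (stim.u_star[k] - stim.u_star[k - 1]) / dt
        yield k, StimulusSample(r_in, r_bar_in.copy(), u_star, u_star_dot,
                                stim.beta, stim.nudge_mask)
        r_bar_in = a * r_bar_in + (1.0 - a) * r_in


def simulate(
    params: NetworkParams,
    act: Activation,
    stim: StimulusTrace,
    integrator: str = "implicit",
    warmup_tau: float = 10.0,
    record_every: int = 1,
    u0: Optional[np.ndarray] = None,
    seed: Optional[int] = None,
) -> TrajectoryRecord:
    """Integrate the voltage dynamics over a stimulus and log diagnostics.

    A warm-up window of ``warmup_tau`` membrane time constants with the first
    stimulus frame held constant is prepended (standing in for initialisation
    in the infinite past); only the stimulus-proper part is recorded.
    """
    if stim.n_steps < 1:
        raise ValueError("stimulus must contain at least one step")
    if stim.u_star.size and stim.u_star.shape[1] != len(params.output_indices):
        raise ValueError("u_star width must match the number of output neurons")
    stepper = _STEPPERS[integrator]
    state = NetworkState.zeros(params.n) if u0 is None else NetworkState(
        np.asarray(u0, dtype=float).copy(), np.zeros(params.n)
    )
    logs: dict[str, list] = {k: [] for k in ("t", "u", "r_bar", "e_bar", "L", "E_M", "C", "residual")}
    for k, sample in iterate_samples(stim, params.tau, warmup_tau):
        if k >= 0 and k % record_every == 0:
            u = state.u
            r_net, _ = act(u)
            r_bar = np.concatenate([sample.r_bar_in, r_net])
            e_star = embed_target_error(params, u, sample.u_star, sample.nudge_mask)
            e_bar = apical_error_dynamic(params, act, u, r_bar, sample.beta, e_star)
            L, E_M, C = lagrangian(params, u, r_bar, sample.beta, e_star)
            logs["t"].append(k * stim.dt)
            logs["u"].append(u.copy())
            logs["r_bar"].append(r_bar)
            logs["e_bar"].append(e_bar)
            logs["L"].append(L)
            logs["E_M"].append(E_M)
            logs["C"].append(C)
            logs["residual"].append(equilibrium_residual(params, u, r_bar, e_bar))
        state = stepper(params, act, state, sample, stim.dt, step=k)
    meta = {
        "integrator": integrator,
        "warmup_tau": warmup_tau,
        "seed": seed,
        "config_hash": _config_hash(params.W_in.shape, params.W_net.shape,
                                    params.tau, stim.beta, stim.dt),
    }
    return TrajectoryRecord(
        np.asarray(logs["t"]), np.asarray(logs["u"]), np.asarray(logs["r_bar"]),
        np.asarray(logs["e_bar"]), np.asarray(logs["L"]), np.asarray(logs["E_M"]),
        np.asarray(logs["C"]), np.asarray(logs["residual"]), meta,
    )


# ---------------------------------------------------------------------------
# layered helpers and builders
# ---------------------------------------------------------------------------


def feedforward_pass(
    params: NetworkParams, act: Activation, r_bar_in: np.ndarray
) -> list[np.ndarray]:
    """Instantaneous error-free pass ``u_l = W_l r̄_{l−1}`` through a layered net.

    Returns the list of per-layer voltage vectors (no error correction); this
    is the reference network the classical backprop comparison runs on.
    """
    sls = params.layer_slices()
    us: list[np.ndarray] = []
    r_in = np.atleast_1d(r_bar_in)
    r_prev: Optional[np.ndarray] = None
    for i, sl in enumerate(sls):
        u_l = params.W_in[sl] @ r_in  # deep layers see only bias columns, if any
        if i > 0:
            u_l = u_l + params.W_net[sl, sls[i - 1]] @ r_prev
        us.append(u_l)
        r_prev, _ = act(u_l)
    return us


def init_weights(
    rng: np.random.Generator, shape: tuple[int, ...], sd: float, clip: float
) -> np.ndarray:
    """Gaussian N(0, sd²) weights clipped at ±clip (the simulation default)."""
    return np.clip(rng.normal(0.0, sd, size=shape), -clip, clip)


def make_layered_params(
    rng: np.random.Generator,
    sizes: Sequence[int],
    tau: float = 10.0,
    weight_sd: float = 0.1,
    weight_clip: float = 0.3,
    bias: bool = False,
) -> NetworkParams:
    """Build a functionally feedforward network ``sizes[0] → ... → sizes[-1]``.

    ``sizes[0]`` is the input dimension; the remaining entries are network
    layers, the last of which is the output layer.  With ``bias=True`` a
    constant-rate-1 input channel is appended whose weight column projects to
    *every* layer, giving each layer a learnable bias (the constant rate is
    supplied by the stimulus; see :func:`nla.synthetic.add_bias_channel`).
    """
    sizes = list(sizes)
    n_in = sizes[0] + (1 if bias else 0)
    layer_sizes = tuple(sizes[1:])
    n = sum(layer_sizes)
    W_in = np.zeros((n, n_in))
    W_net = np.zeros((n, n))
    mask_in = np.zeros_like(W_in, dtype=bool)
    mask_net = np.zeros_like(W_net, dtype=bool)
    edges = np.concatenate([[0], np.cumsum(layer_sizes)])
    sls = [slice(int(a), int(b)) for a, b in zip(edges[:-1], edges[1:])]
    W_in[sls[0]] = init_weights(rng, (layer_sizes[0], n_in), weight_sd, weight_clip)
    mask_in[sls[0]] = True
    if bias:
        W_in[:, -1] = init_weights(rng, (n,), weight_sd, weight_clip)
        mask_in[:, -1] = True
    for i in range(1, len(layer_sizes)):
        W_net[sls[i], sls[i - 1]] = init_weights(
            rng, (layer_sizes[i], layer_sizes[i - 1]), weight_sd, weight_clip
        )
        mask_net[sls[i], sls[i - 1]] = True
    out = np.arange(edges[-2], edges[-1])
    return NetworkParams(W_in, W_net, tau, out, layer_sizes, mask_in, mask_net)


def make_recurrent_params(
    rng: np.random.Generator,
    n: int,
    n_in: int,
    n_out: int,
    tau: float = 10.0,
    weight_sd: float = 0.1,
    weight_clip: float = 0.3,
) -> NetworkParams:
    """Build an all-to-all recurrent network (no self-connections).

    The first ``n_out`` network neurons are the outputs.
    """
    W_in = init_weights(rng, (n, n_in), weight_sd, weight_clip)
    W_net = init_weights(rng, (n, n), weight_sd, weight_clip)
    np.fill_diagonal(W_net, 0.0)
    mask_net = ~np.eye(n, dtype=bool)
    out = np.arange(n_out)
    return NetworkParams(W_in, W_net, tau, out, None,
                         np.ones_like(W_in, dtype=bool), mask_net)
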