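"""Pyramidal–interneuron microcircuit that learns to represent dendritic errors.

In a layered network the top-down feedback ``B_l u_{l+1}`` arriving in the
apical dendrites of layer-l pyramidal neurons is laterally "explained away"
by an interneuron population of the same layer.  Interneuron voltages are a
convex combination of lateral drive and top-down nudging,

    u^I_l = (1 − β^I) W^IP_l r̄_l + β^I B^IP_l u_{l+1} ,

and what the interneurons cannot cancel remains as the apical error

    ē^A_l = B_l u_{l+1} − W^PI_l u^I_l .

Both lateral weight families descend their own mismatch energies,

    dW^IP/dt = η^IP (u^I − W^IP r̄) r̄ᵀ ,
    dW^PI/dt = η^PI (B u_{l+1} − W^PI u^I) u^Iᵀ ,

which drives the lateral loop ``W^PI W^IP`` into alignment with the vertical
loop ``B W_{l+1}``.  After alignment the apical voltages equal the
B-backpropagated errors ``B_l ē_{l+1}``, so a network using only the
microcircuit (fixed random feedback, no weight transport) performs the same
credit assignment as the idealised transpose dynamics.

Interneurons have a linear transfer function and their voltage is assigned
algebraically each step (their own time constant is absorbed into the
pyramidal dynamics).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .network import (
    Activation,
    NetworkParams,
    NetworkState,
    StimulusTrace,
    _check_finite,
    _spd_solve,
    init_weights,
    iterate_samples,
    mismatch_error,
)

__all__ = [
    "MicrocircuitParams",
    "InterneuronState",
    "interneuron_voltage",
    "apical_error_microcircuit",
    "microcircuit_updates",
    "loop_alignment_angle",
    "make_microcircuit",
    "train_microcircuit",
    "MicrocircuitLog",
]


@dataclass
class MicrocircuitParams:
    """Lateral interneuron circuit for each hidden layer of a layered network.

    Lists are indexed by hidden layer (0 = first network layer); entry l
    couples layer l to layer l+1.  ``B[l]`` and ``B_IP[l]`` are fixed random
    backprojections; ``W_IP[l]``/``W_PI[l]`` are plastic.  ``beta_I`` is the
    interneuron nudging strength in [0, 1).
    """

    W_IP: list[np.ndarray]
    W_PI: list[np.ndarray]
    B: list[np.ndarray]
    B_IP: list[np.ndarray]
    beta_I: float = 0.0
    eta_IP: float = 1e-3
    eta_PI: float = 1e-3

    def __post_init__(self) -> None:
        if not (0.0 <= self.beta_I < 1.0):
            raise ValueError("beta_I must lie in [0, 1)")
        for l, (wip, wpi, b, bip) in enumerate(zip(self.W_IP, self.W_PI, self.B, self.B_IP)):
            n_i, n_l = wip.shape
            if wpi.shape != (n_l, n_i):
                raise ValueError(f"layer {l}: W_PI shape must transpose W_IP's")
            n_next = b.shape[1]
            if b.shape[0] != n_l or bip.shape != (n_i, n_next):
                raise ValueError(f"layer {l}: feedback matrix shapes are inconsistent")
            if n_i < min(n_l, n_next):
                warnings.warn(
                    f"layer {l}: {n_i} interneurons < min(n_l, n_l+1) = "
                    f"{min(n_l, n_next)}; exact loop alignment is impossible",
                    RuntimeWarning,
                )

    @property
    def n_hidden_layers(self) -> int:
        return len(self.W_IP)

    def copy(self) -> "MicrocircuitParams":
        return MicrocircuitParams(
            [w.copy() for w in self.W_IP], [w.copy() for w in self.W_PI],
            [b.copy() for b in self.B], [b.copy() for b in self.B_IP],
            self.beta_I, self.eta_IP, self.eta_PI,
        )


@dataclass
class InterneuronState:
    """Per-hidden-layer interneuron voltage vectors."""

    u_I: list[np.ndarray]

    @classmethod
    def zeros(cls, mc: MicrocircuitParams) -> "InterneuronState":
        return cls([np.zeros(w.shape[0]) for w in mc.W_IP])


def interneuron_voltage(
    mc: MicrocircuitParams, layer: int, r_bar_l: np.ndarray, u_next: np.ndarray
) -> np.ndarray:
    """Convex combination ``(1 − β^I) W^IP r̄_l + β^I B^IP u_{l+1}``."""
    return (1.0 - mc.beta_I) * (mc.W_IP[layer] @ r_bar_l) + mc.beta_I * (mc.B_IP[layer] @ u_next)


def apical_error_microcircuit(
    mc: MicrocircuitParams, layer: int, u_next: np.ndarray, u_I_l: np.ndarray
) -> np.ndarray:
    """Apical voltage ``ē^A_l = B_l u_{l+1} − W^PI_l u^I_l``.

    The somatic error it induces is ``ρ'(u_l) ∘ ē^A_l`` (modulated by the
    postsynaptic rate derivative).
    """
    return mc.B[layer] @ u_next - mc.W_PI[layer] @ u_I_l


def microcircuit_updates(
    mc: MicrocircuitParams,
    layer: int,
    r_bar_l: np.ndarray,
    u_I_l: np.ndarray,
    u_next: np.ndarray,
) -> tuple[np.ndarray, np.ndarray]:
    """Gradient updates ``(dW^IP/dt, dW^PI/dt)`` for one hidden layer.

    Each is gradient descent on its own mismatch energy:
    ``E^IP = ½‖u^I − W^IP r̄‖²`` and ``E^PI = ½‖B u_{l+1} − W^PI u^I‖²``.
    """
    d_ip = mc.eta_IP * np.outer(u_I_l - mc.W_IP[layer] @ r_bar_l, r_bar_l)
    d_pi = mc.eta_PI * np.outer(mc.B[layer] @ u_next - mc.W_PI[layer] @ u_I_l, u_I_l)
    return d_ip, d_pi


def loop_alignment_angle(
    W_PI: np.ndarray, W_IP: np.ndarray, B: np.ndarray, W_next: np.ndarray
) -> float:
    """Frobenius angle (degrees) between the lateral loop ``W^PI W^IP`` and
    the vertical loop ``B W_{l+1}``.

    Independent random matrices sit near 90°; loop alignment drives the angle
    toward 0°.
    """
    A = W_PI @ W_IP
    Bm = B @ W_next
    na, nb = np.linalg.norm(A), np.linalg.norm(Bm)
    if na == 0.0 or nb == 0.0:
        raise ValueError("alignment angle undefined for a zero-norm loop matrix")
    c = float(np.sum(A * Bm) / (na * nb))
    return float(np.degrees(np.arccos(np.clip(c, -1.0, 1.0))))


def make_microcircuit(
    rng: np.random.Generator,
    params: NetworkParams,
    n_interneurons: list[int],
    beta_I: float = 0.0,
    eta_IP: float = 1e-3,
    eta_PI: float = 1e-3,
    lateral_sd: float = 0.01,
    lateral_clip: float = 0.03,
    feedback_sd: float = 0.05,
    feedback_clip: float = 0.15,
) -> MicrocircuitParams:
    """Random microcircuit for a layered network.

    Lateral weights start small (N(0, 0.01²) clipped at ±0.03); the fixed
    feedback matrices B and B^IP use the wider 5·N(0, 0.01²) clipped at ±0.15.
    """
    sizes = params.layer_sizes
    assert sizes is not None
    W_IP, W_PI, B, B_IP = [], [], [], []
    for l in range(len(sizes) - 1):
        n_l, n_next, n_i = sizes[l], sizes[l + 1], n_interneurons[l]
        W_IP.append(init_weights(rng, (n_i, n_l), lateral_sd, lateral_clip))
        W_PI.append(init_weights(rng, (n_l, n_i), lateral_sd, lateral_clip))
        B.append(init_weights(rng, (n_l, n_next), feedback_sd, feedback_clip))
        B_IP.append(init_weights(rng, (n_i, n_next), feedback_sd, feedback_clip))
    return MicrocircuitParams(W_IP, W_PI, B, B_IP, beta_I, eta_IP, eta_PI)


# ---------------------------------------------------------------------------
# microcircuit network dynamics (Algorithm-2 loop)
# ---------------------------------------------------------------------------


def _mc_error(
    params: NetworkParams,
    mc: MicrocircuitParams,
    u: np.ndarray,
    u_I: list[np.ndarray],
    beta: float,
    e_star: np.ndarray,
) -> np.ndarray:
    """Network-wide error vector: apical microcircuit errors on hidden layers,
    target nudging on the output layer (whose B and W^PI rows are zero)."""
    sls = params.layer_slices()
    e = beta * e_star
    for l in range(len(sls) - 1):
        e[sls[l]] += apical_error_microcircuit(mc, l, u[sls[l + 1]], u_I[l])
    return e


def _mc_error_jacobian(
    params: NetworkParams,
    mc: MicrocircuitParams,
    act: Activation,
    u: np.ndarray,
    beta: float,
    nudge_mask: np.ndarray,
) -> np.ndarray:
    """State-Jacobian of the microcircuit error, treating u^I as the algebraic
    function of the current voltages that the end-of-step assignment realises."""
    n = params.n
    sls = params.layer_slices()
    _, rp = act(u)
    J = np.zeros((n, n))
    for l in range(len(sls) - 1):
        sl, sn = sls[l], sls[l + 1]
        J[sl, sl] -= (1.0 - mc.beta_I) * (mc.W_PI[l] @ mc.W_IP[l]) * rp[sl][None, :]
        J[sl, sn] += mc.B[l] - mc.beta_I * (mc.W_PI[l] @ mc.B_IP[l])
    if beta:
        m = np.zeros(n)
        m[params.output_indices] = nudge_mask.astype(float)
        J -= beta * np.diag(m)
    return J


@dataclass
class MicrocircuitLog:
    """Diagnostics logged during microcircuit training."""

    t: np.ndarray
    angles: np.ndarray        # (steps, hidden layers)
    E_IP: np.ndarray
    E_PI: np.ndarray
    C: np.ndarray


def train_microcircuit(
    params: NetworkParams,
    act: Activation,
    mc: MicrocircuitParams,
    stim: StimulusTrace,
    eta_forward: float = 0.0,
    integrator: str = "explicit",
    warmup_tau: float = 10.0,
    record_every: int = 200,
    plastic_lateral: bool = True,
) -> tuple[NetworkParams, MicrocircuitParams, MicrocircuitLog]:
    """Run the joint pyramidal/interneuron loop over a stimulus stream.

    Per time step: compute low-pass rates; weight derivatives for the forward
    weights (if ``eta_forward`` > 0) and both lateral families; the
    microcircuit error ``ē = B u − W^PI u^I + β ē*`` (output rows of B and
    W^PI structurally zero); one Euler step of the voltages (implicit or
    explicit, with the Hessian built from the microcircuit error Jacobian);
    Euler updates of all plastic weights; finally the algebraic interneuron
    voltage assignment.

    Returns trained copies of the network and microcircuit parameters plus an
    alignment/energy log.
    """
    p = params.copy()
    m = mc.copy()
    sls = p.layer_slices()
    n_hid = m.n_hidden_layers
    state = NetworkState.zeros(p.n)
    u_I = InterneuronState.zeros(m).u_I
    dt = stim.dt
    tau = p.tau
    n_in = p.n_in
    logs: dict[str, list] = {"t": [], "angles": [], "E_IP": [], "E_PI": [], "C": []}
    for k, sample in iterate_samples(stim, tau, warmup_tau):
        u = state.u
        r_net, rp = act(u)
        r_bar = np.concatenate([sample.r_bar_in, r_net])
        # weight derivatives from the pre-step state
        dW_in = dW_net = None
        if eta_forward:
            e_mm = mismatch_error(p, u, r_bar)
            dW_in = eta_forward * np.outer(e_mm, r_bar[:n_in]) * p.mask_in
            dW_net = eta_forward * np.outer(e_mm, r_bar[n_in:]) * p.mask_net
        d_laterals = []
        if plastic_lateral:
            for l in range(n_hid):
                d_laterals.append(
                    microcircuit_updates(m, l, r_bar[n_in:][sls[l]], u_I[l], u[sls[l + 1]])
                )
        # errors and voltage derivative
        e_star = np.zeros(p.n)
        if sample.u_star.size:
            e_star[p.output_indices] = np.where(
                sample.nudge_mask, sample.u_star - u[p.output_indices], 0.0
            )
        e_bar = _mc_error(p, m, u, u_I, sample.beta, e_star)
        J = _mc_error_jacobian(p, m, act, u, sample.beta, sample.nudge_mask)
        r_bar_in_dot = (sample.r_in - sample.r_bar_in) / tau
        e_bar_dt = np.zeros(p.n)
        if sample.beta and sample.u_star.size:
            e_bar_dt[p.output_indices] += sample.beta * np.where(
                sample.nudge_mask, sample.u_star_dot, 0.0
            )
        if integrator == "implicit":
            r_prosp = r_net + tau * rp * state.u_dot_prev
            drive = p.W_in @ sample.r_in + p.W_net @ r_prosp
            e_dot = J @ state.u_dot_prev + e_bar_dt
            u_dot = (-u + drive + e_bar + tau * e_dot) / tau
        else:
            f = mismatch_error(p, u, r_bar) - e_bar
            H = np.eye(p.n) - p.W_net * rp[None, :] - J
            df_dt = -(p.W_in @ r_bar_in_dot) - e_bar_dt
            u_dot = _spd_solve(tau * H, -f - tau * df_dt)
        u_new = u + dt * u_dot
        _check_finite(u_new, k, "voltage (microcircuit step)")
        # Euler weight updates (skipped during warm-up)
        if k >= 0:
            if eta_forward:
                p.W_in += dt * dW_in
                p.W_net += dt * dW_net
            for l, (d_ip, d_pi) in enumerate(d_laterals):
                m.W_IP[l] += dt * d_ip
                m.W_PI[l] += dt * d_pi
        state = NetworkState(u_new, u_dot, state.t + dt)
        # algebraic interneuron assignment from the updated state
        r_new, _ = act(u_new)
        for l in range(n_hid):
            u_I[l] = interneuron_voltage(m, l, r_new[sls[l]], u_new[sls[l + 1]])
        if k >= 0 and k % record_every == 0:
            logs["t"].append(k * dt)
            logs["angles"].append([
                loop_alignment_angle(m.W_PI[l], m.W_IP[l], m.B[l],
                                     p.W_net[sls[l + 1], sls[l]])
                for l in range(n_hid)
            ])
            e_ip = sum(
                0.5 * float(np.sum((u_I[l] - m.W_IP[l] @ r_new[sls[l]]) ** 2))
                for l in range(n_hid)
            )
            e_pi = sum(
                0.5 * float(np.sum(
                    (m.B[l] @ u_new[sls[l + 1]] - m.W_PI[l] @ u_I[l]) ** 2
                ))
                for l in range(n_hid)
            )
            logs["E_IP"].append(e_ip)
            logs["E_PI"].append(e_pi)
            if sample.u_star.size:
                err = np.where(sample.nudge_mask,
                               sample.u_star - u_new[p.output_indices], 0.0)
                logs["C"].append(0.5 * float(err @ err))
            else:
                logs["C"].append(0.0)
    return p, m, MicrocircuitLog(
        np.asarray(logs["t"]), np.asarray(logs["angles"]),
        np.asarray(logs["E_IP"]), np.asarray(logs["E_PI"]), np.asarray(logs["C"]),
    )
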