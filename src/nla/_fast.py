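"""Compiled inner loops for training-scale simulations.

Numerically identical re-implementations of the explicit-integrator step
(and the no-lookahead ablation step) with interleaved plasticity, compiled
with numba for the long pattern-task runs.  The reference implementations in
:mod:`nla.network` / :mod:`nla.plasticity` remain the specification; a unit
test pins the two paths against each other.

Only the configuration the training experiments use is supported here:
explicit (or ablation) stepping, continuous plasticity at a constant rate,
all outputs nudged.
"""

from __future__ import annotations

import numpy as np
from numba import njit

__all__ = ["train_explicit_fast", "run_explicit_fast"]

ACT_LOGISTIC = 0
ACT_HARD_SIGMOID = 1
ACT_THRESHOLD_LINEAR = 2
ACT_LINEAR = 3

_ACT_CODES = {
    "logistic": ACT_LOGISTIC,
    "hard_sigmoid": ACT_HARD_SIGMOID,
    "threshold_linear": ACT_THRESHOLD_LINEAR,
    "linear": ACT_LINEAR,
}


@njit(cache=True)
def _act(code, u, r, rp):
    n = u.shape[0]
    if code == 0:
        for i in range(n):
            v = 1.0 / (1.0 + np.exp(-u[i]))
            r[i] = v
            rp[i] = v * (1.0 - v)
    elif code == 1:
        for i in range(n):
            if u[i] <= 0.0:
                r[i] = 0.0
                rp[i] = 0.0
            elif u[i] >= 1.0:
                r[i] = 1.0
                rp[i] = 0.0
            else:
                r[i] = u[i]
                rp[i] = 1.0
    elif code == 2:
        for i in range(n):
            if u[i] > 0.0:
                r[i] = u[i]
                rp[i] = 1.0
            else:
                r[i] = 0.0
                rp[i] = 0.0
    else:
        for i in range(n):
            r[i] = u[i]
            rp[i] = 1.0


@njit(cache=True)
def _loop(code, W_in, W_net, mask_in, mask_net, out_idx, tau, dt, beta,
          r_in_seq, u_star_seq, n_warm, eta, plastic, ablation, curvature,
          u_log):
    n = W_net.shape[0]
    m = W_in.shape[1]
    n_steps = r_in_seq.shape[0]
    n_out = u_star_seq.shape[1]
    u = np.zeros(n)
    r = np.empty(n)
    rp = np.empty(n)
    r_bar_in = r_in_seq[0].copy()
    a = np.exp(-dt / tau)
    eye = np.eye(n)
    for k in range(-n_warm, n_steps):
        kk = k if k >= 0 else 0
        r_in = r_in_seq[kk]
        if k >= 0 and u_log.shape[0] > 0:
            for i in range(n):
                u_log[k, i] = u[i]
        _act(code, u, r, rp)
        # mismatch error e_mm = u − W_in r̄_in − W_net r
        e_mm = u - W_in @ r_bar_in - W_net @ r
        # plasticity from the pre-step state (weights updated before stepping,
        # matching the reference trainer)
        if plastic and k >= 0:
            scale = eta * dt
            for i in range(n):
                e = e_mm[i] * scale
                if e != 0.0:
                    for j in range(m):
                        if mask_in[i, j]:
                            W_in[i, j] += e * r_bar_in[j]
                    for j in range(n):
                        if mask_net[i, j]:
                            W_net[i, j] += e * r[j]
            e_mm = u - W_in @ r_bar_in - W_net @ r
        backproj = W_net.T @ e_mm
        # errors
        e_bar = rp * backproj
        if beta > 0.0 and n_out > 0:
            for o in range(n_out):
                e_bar[out_idx[o]] += beta * (u_star_seq[kk, o] - u[out_idx[o]])
        r_bar_in_dot = (r_in - r_bar_in) / tau
        drive_dot = W_in @ r_bar_in_dot
        e_dt = -rp * (W_net.T @ drive_dot)
        if beta > 0.0 and n_out > 0 and k > 0:
            for o in range(n_out):
                e_dt[out_idx[o]] += beta * (u_star_seq[k, o] - u_star_seq[k - 1, o]) / dt
        if ablation:
            u_dot = (-u + W_in @ r_bar_in + W_net @ r + e_bar) / tau
        else:
            f = e_mm - e_bar
            inner = eye - W_net * rp.reshape(1, n)
            J = rp.reshape(n, 1) * (W_net.T @ inner)
            if beta > 0.0 and n_out > 0:
                for o in range(n_out):
                    J[out_idx[o], out_idx[o]] -= beta
            if curvature and code == 0:
                for i in range(n):
                    v = 1.0 / (1.0 + np.exp(-u[i]))
                    J[i, i] += v * (1.0 - v) * (1.0 - 2.0 * v) * backproj[i]
            H = eye - W_net * rp.reshape(1, n) - J
            rhs = -f - tau * (-drive_dot - e_dt)
            u_dot = np.linalg.solve(tau * H, rhs)
        u = u + dt * u_dot
        r_bar_in = a * r_bar_in + (1.0 - a) * r_in
    return u


def _prepare(params, act, stim):
    code = _ACT_CODES[act.kind]
    u_star = stim.u_star if stim.u_star.size else np.zeros((stim.n_steps, 0))
    if stim.u_star.size and not np.all(stim.nudge_mask):
        raise ValueError("fast path supports fully nudged outputs only")
    return code, np.ascontiguousarray(stim.r_in), np.ascontiguousarray(u_star)


def train_explicit_fast(params, act, stim, eta, warmup_tau=10.0,
                        ablation=False, include_curvature=False):
    """Compiled equivalent of ``train_online`` (explicit stepper, constant η).

    Returns trained parameters (a copy); the input is not modified.
    """
    p = params.copy()
    code, r_in_seq, u_star_seq = _prepare(p, act, stim)
    n_warm = int(np.ceil(warmup_tau * p.tau / stim.dt))
    _loop(code, p.W_in, p.W_net, p.mask_in, p.mask_net,
          p.output_indices.astype(np.int64), p.tau, stim.dt, float(stim.beta),
          r_in_seq, u_star_seq, n_warm, float(eta), True, ablation,
          include_curvature, np.zeros((0, 0)))
    return p


def run_explicit_fast(params, act, stim, warmup_tau=10.0, ablation=False,
                      include_curvature=False):
    """Compiled forward simulation; returns the voltage trajectory (n_steps, n)."""
    p = params.copy()
    code, r_in_seq, u_star_seq = _prepare(p, act, stim)
    n_warm = int(np.ceil(warmup_tau * p.tau / stim.dt))
    u_log = np.zeros((stim.n_steps, p.n))
    _loop(code, p.W_in, p.W_net, p.mask_in, p.mask_net,
          p.output_indices.astype(np.int64), p.tau, stim.dt, float(stim.beta),
          r_in_seq, u_star_seq, n_warm, 0.0, False, ablation,
          include_curvature, u_log)
    return u_log
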