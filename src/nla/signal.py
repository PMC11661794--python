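"""Temporal operator algebra: exponential low-pass filtering and linear lookahead.

The network theory rests on a pair of mutually inverse single-time-constant
operators.  The low-pass filter ``x̄`` of a signal ``x`` obeys

    τ dx̄/dt = −x̄ + x ,

and the lookahead operator is its inverse,

    (1 + τ d/dt) x̄ = x .

A firing rate of the form ``r = ρ(u) + τ dρ(u)/dt`` is the lookahead of the
instantaneous rate ``ρ(u)``: it linearly extrapolates activity one membrane
time constant into the future, which is what lets voltage signals propagate
through layers of leaky neurons without accumulating integration delays.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.signal import lfilter

__all__ = [
    "Series",
    "low_pass",
    "lookahead",
    "phase_advance_analytic",
    "fit_sinusoid",
    "measure_phase_lead",
    "read_series",
    "write_series",
]


@dataclass(frozen=True)
class Series:
    """A uniformly sampled real-valued time series.

    Parameters
    ----------
    values : array of shape (n,) or (n, k)
        Sample values; the first axis is time.
    dt : float
        Sampling step in milliseconds, strictly positive.
    t0 : float
        Time of the first sample in milliseconds.
    """

    values: np.ndarray
    dt: float
    t0: float = 0.0

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", v)
        if self.dt <= 0:
            raise ValueError(f"dt must be positive, got {self.dt}")
        if v.shape[0] < 1:
            raise ValueError("Series must contain at least one sample")
        if not np.all(np.isfinite(v)):
            raise ValueError("Series values must be finite")

    @property
    def n(self) -> int:
        return self.values.shape[0]

    @property
    def t(self) -> np.ndarray:
        """Sample times in ms."""
        return self.t0 + self.dt * np.arange(self.n)

    def with_values(self, values: np.ndarray) -> "Series":
        return Series(values, self.dt, self.t0)


def low_pass(x: Series, tau: float) -> Series:
    """Exponential low-pass filter with time constant ``tau`` (ms).

    Integrates ``τ dx̄/dt = −x̄ + x`` with the exact exponential update

        x̄[k] = x̄[k−1]·exp(−dt/τ) + x[k−1]·(1 − exp(−dt/τ)) ,

    which is unconditionally stable and exact for piecewise-constant input
    held over each step.  The filter is initialised at ``x̄[0] = x[0]``; for
    signals whose history matters, prepend a warm-up window of several τ.
    """
    if tau <= 0:
        raise ValueError(f"tau must be positive, got {tau}")
    v = x.values
    a = float(np.exp(-x.dt / tau))
    b = 1.0 - a
    # recursion x̄[k] = a x̄[k−1] + b x[k−1] as an IIR filter; zi = x[0] sets x̄[0] = x[0]
    zi = np.asarray(v[0], dtype=float)[None] if v.ndim == 1 else v[0][None, :]
    out, _ = lfilter([0.0, b], [1.0, -a], v, axis=0, zi=zi)
    return x.with_values(out)


def lookahead(x: Series, tau: float) -> Series:
    """Linear lookahead ``x + τ ẋ`` with a causal backward-difference derivative.

    The derivative at step k is ``(x[k] − x[k−1])/dt``; the first sample has no
    past and copies the second sample's derivative (callers that care about
    the boundary should prepend a warm-up window).
    """
    if tau <= 0:
        raise ValueError(f"tau must be positive, got {tau}")
    if x.n < 2:
        raise ValueError("lookahead needs at least 2 samples to form a derivative")
    v = x.values
    dv = np.empty_like(v)
    dv[1:] = (v[1:] - v[:-1]) / x.dt
    dv[0] = dv[1]
    return x.with_values(v + tau * dv)


def phase_advance_analytic(freq: float, tau: float) -> float:
    """Phase (radians) by which ``ρ(u) + τ dρ(u)/dt`` leads ``ρ(u)``.

    For a sinusoid of frequency ``freq`` (Hz) passed through the lookahead
    operator with time constant ``tau`` (ms), the lead is ``arctan(2π f τ)``
    in the linear regime.  Equivalently it is the phase lag that the low-pass
    filter would impose, so the two cancel.
    """
    if freq < 0:
        raise ValueError("freq must be non-negative")
    if tau <= 0:
        raise ValueError("tau must be positive")
    return float(np.arctan(2.0 * np.pi * freq * 1e-3 * tau))


def fit_sinusoid(x: Series, freq: float) -> tuple[float, float, float]:
    """Least-squares fit of ``offset + A sin(2π f t + φ)`` to a series.

    Returns ``(amplitude, phase, offset)`` with phase in radians.  The fit is
    linear in the basis ``{sin, cos, 1}`` and therefore exact in the noise-free
    case regardless of the number of cycles covered.
    """
    w = 2.0 * np.pi * freq * 1e-3  # rad per ms
    t = x.t
    basis = np.column_stack([np.sin(w * t), np.cos(w * t), np.ones_like(t)])
    coef, *_ = np.linalg.lstsq(basis, x.values, rcond=None)
    a, b, c = coef
    return float(np.hypot(a, b)), float(np.arctan2(b, a)), float(c)


def measure_phase_lead(y: Series, x: Series, freq: float) -> float:
    """Measured phase (radians) by which sinusoidal ``y`` leads ``x``.

    Both series are fit with :func:`fit_sinusoid` at the given frequency and
    the phase difference is wrapped to (−π, π].
    """
    _, ph_y, _ = fit_sinusoid(y, freq)
    _, ph_x, _ = fit_sinusoid(x, freq)
    d = ph_y - ph_x
    return float((d + np.pi) % (2.0 * np.pi) - np.pi)


def write_series(path, x: Series) -> None:
    """Write a series as two-column delimited text (time_ms, value...)."""
    cols = np.column_stack([x.t, np.atleast_2d(x.values.T).T])
    np.savetxt(path, cols, delimiter="\t", header="time_ms\tvalue", comments="")


def read_series(path) -> Series:
    """Read a series written by :func:`write_series`."""
    data = np.loadtxt(path, delimiter="\t", skiprows=1)
    data = np.atleast_2d(data)
    t = data[:, 0]
    if len(t) < 2:
        raise ValueError("need at least two samples to infer dt")
    dt = float(t[1] - t[0])
    values = data[:, 1] if data.shape[1] == 2 else data[:, 1:]
    return Series(values, dt=dt, t0=float(t[0]))
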