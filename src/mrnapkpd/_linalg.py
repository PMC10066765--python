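"""Closed-form propagation of linear compartmental systems.

The disposition + effect-compartment + protein-turnover system is linear and
time-invariant, with dosing entering as impulses (IV bolus) or piecewise-
constant inputs (IV infusion).  The trajectory is therefore a superposition
of matrix-exponential responses.  This module evaluates that superposition
via one eigendecomposition per parameter set, which is orders of magnitude
cheaper than repeated ODE solves and is exact up to floating-point error —
the property the likelihood machinery leans on.

A piecewise ``expm`` fallback handles the (measure-zero) defective case.
"""

from __future__ import annotations

import numpy as np
from scipy.linalg import expm

__all__ = ["linear_trajectory"]

# eigenvalues closer to zero than this are treated as exactly zero when
# integrating the step response (limit (e^{lt}-1)/l -> t)
_LAM_TINY = 1e-12


def _phi(lam: np.ndarray, tau: np.ndarray) -> np.ndarray:
    """Elementwise integral of e^{lam*s} over [0, tau], zero for tau <= 0."""
    tau = np.asarray(tau, dtype=float)
    out = np.zeros((tau.size, lam.size), dtype=complex)
    pos = tau > 0
    if np.any(pos):
        tl = np.outer(tau[pos], lam)
        small = np.abs(lam) < _LAM_TINY
        vals = np.empty_like(tl)
        if np.any(~small):
            vals[:, ~small] = np.expm1(tl[:, ~small]) / lam[~small]
        if np.any(small):
            vals[:, small] = tau[pos, None]
        out[pos] = vals
    return out


def linear_trajectory(
    A: np.ndarray,
    x0: np.ndarray,
    doses,
    times: np.ndarray,
    input_index: int = 0,
) -> np.ndarray:
    """States of x' = A x + u(t) e_in at ``times``.

    ``doses`` is an iterable of objects with attributes ``time``, ``amount``
    and ``duration`` (0 = bolus).  An observation falling exactly on a bolus
    time sees the post-dose state.  Returns (n_times, n_states).
    """
    A = np.asarray(A, dtype=float)
    x0 = np.asarray(x0, dtype=float)
    times = np.asarray(times, dtype=float)
    lam, V = np.linalg.eig(A)
    try:
        Vinv = np.linalg.inv(V)
    except np.linalg.LinAlgError:
        return _trajectory_expm(A, x0, doses, times, input_index)
    # defective/ill-conditioned eigenbasis -> piecewise expm (infinity-norm
    # condition estimate; cheap compared to an SVD)
    if np.abs(V).sum(axis=1).max() * np.abs(Vinv).sum(axis=1).max() > 1e10:
        return _trajectory_expm(A, x0, doses, times, input_index)

    out = np.zeros((times.size, A.shape[0]), dtype=complex)
    if np.any(x0 != 0.0):
        c0 = Vinv @ x0.astype(complex)
        out += np.exp(np.outer(times, lam)) * c0 @ V.T
    cin = Vinv[:, input_index]
    for d in doses:
        if d.duration == 0.0:
            tau = times - d.time
            mask = tau >= 0.0
            if np.any(mask):
                out[mask] += (
                    np.exp(np.outer(tau[mask], lam)) * (cin * d.amount)
                ) @ V.T
        else:
            rate = d.amount / d.duration
            contrib = _phi(lam, times - d.time) - _phi(lam, times - d.time - d.duration)
            out += contrib * (cin * rate) @ V.T
    return out.real


def _trajectory_expm(A, x0, doses, times, input_index):
    """Piecewise matrix-exponential propagation (augmented-matrix quadrature
    for constant-rate infusion segments)."""
    n = A.shape[0]
    e_in = np.zeros(n)
    e_in[input_index] = 1.0
    boluses = sorted((d for d in doses if d.duration == 0.0), key=lambda d: d.time)
    infusions = [d for d in doses if d.duration > 0.0]

    breaks = {0.0}
    breaks.update(d.time for d in doses)
    breaks.update(d.time + d.duration for d in infusions)
    breaks.update(times.tolist())
    grid = np.array(sorted(b for b in breaks if b >= 0.0))

    def rate_at(t):
        r = 0.0
        for d in infusions:
            if d.time <= t < d.time + d.duration:
                r += d.amount / d.duration
        return r

    Aug = np.zeros((n + 1, n + 1))
    Aug[:n, :n] = A
    state = x0.astype(float).copy()
    t_prev = grid[0]
    for d in boluses:
        if d.time <= t_prev:
            state[input_index] += d.amount
    out = np.zeros((times.size, n))
    out[times <= t_prev] = state  # times before start (t<0 not supported anyway)
    for t_next in grid[1:]:
        dt = t_next - t_prev
        if dt > 0:
            r = rate_at((t_prev + t_next) / 2.0)
            Aug[:n, n] = r * e_in
            M = expm(Aug * dt)
            state = M[:n, :n] @ state + M[:n, n]
        for d in boluses:
            if t_prev < d.time <= t_next:
                state[input_index] += d.amount
        sel = np.isclose(times, t_next)
        out[sel] = state
        t_prev = t_next
    return out
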