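"""Adaptive Dormand-Prince 5(4) integrator compiled with numba.

The transplant competition system mixes fast mature-cell turnover (~7/week)
with slow HSC expansion; the stiffness ratio is mild enough for an explicit
embedded Runge-Kutta pair, and a compiled fixed right-hand side makes the
thousands of solves inside the hierarchical fit affordable.  The scipy LSODA
path in :mod:`hemaflux.model` serves as the implicit-capable cross-check.
"""

from __future__ import annotations

import numpy as np
from numba import njit

# Dormand-Prince 5(4) Butcher tableau
_C = np.array([0.0, 1 / 5, 3 / 10, 4 / 5, 8 / 9, 1.0, 1.0])
_A = np.array(
    [
        [0.0, 0.0, 0.0, 0.0, 0.0, 0.0],
        [1 / 5, 0.0, 0.0, 0.0, 0.0, 0.0],
        [3 / 40, 9 / 40, 0.0, 0.0, 0.0, 0.0],
        [44 / 45, -56 / 15, 32 / 9, 0.0, 0.0, 0.0],
        [19372 / 6561, -25360 / 2187, 64448 / 6561, -212 / 729, 0.0, 0.0],
        [9017 / 3168, -355 / 33, 46732 / 5247, 49 / 176, -5103 / 18656, 0.0],
    ]
)
_B5 = np.array([35 / 384, 0.0, 500 / 1113, 125 / 192, -2187 / 6784, 11 / 84, 0.0])
_B4 = np.array(
    [5179 / 57600, 0.0, 7571 / 16695, 393 / 640, -92097 / 339200, 187 / 2100, 1 / 40]
)

# state layout: 3 origins (D, C, R) x 12 components
# 0 L, 1 S, 2-5 Y[N,E,P,B], 6-8 Z[N,E,P], 9 EB1, 10 EB2, 11 ZB
NSTATE = 36
NCOMP = 12
# theta layout: per origin (15 entries):
#   rL, rS, pLS, pL[N,E,P,B], pS[N,E,P,B], delta[N,E,P,B]
# shared tail (9 entries): d[N,E,P,B], alpha[N,E,P,B], KS
NTHETA = 3 * 15 + 9


@njit(cache=True)
def rhs(t: float, y: np.ndarray, theta: np.ndarray, out: np.ndarray) -> None:
    KS = theta[53]
    sumL = y[0] + y[12] + y[24]
    sumS = y[1] + y[13] + y[25]
    for j in range(3):
        b = NCOMP * j
        p = 15 * j
        L = y[b + 0]
        S = y[b + 1]
        out[b + 0] = theta[p + 0] * (1.0 - sumL) * L
        out[b + 1] = theta[p + 1] * (1.0 - sumS / KS) * S + theta[p + 2] * L
        for i in range(4):
            d_i = theta[45 + i]
            out[b + 2 + i] = theta[p + 3 + i] * L + theta[p + 7 + i] * S - d_i * y[b + 2 + i]
        for i in range(3):
            out[b + 6 + i] = (
                theta[49 + i] * theta[45 + i] * y[b + 2 + i] - theta[p + 11 + i] * y[b + 6 + i]
            )
        dB = theta[48]
        aB = theta[52]
        out[b + 9] = aB * dB * y[b + 5] - dB * y[b + 9]
        out[b + 10] = dB * y[b + 9] - dB * y[b + 10]
        out[b + 11] = dB * y[b + 10] - theta[p + 14] * y[b + 11]


@njit(cache=True)
def integrate_batch(
    thetas: np.ndarray,
    y0s: np.ndarray,
    t_eval: np.ndarray,
    rtol: float,
    atol: float,
):
    """Integrate a batch of parameter sets over one shared output grid.

    Used for finite-difference gradients and population-level sweeps, where
    per-call overhead would otherwise dominate.  Returns ``(ys, statuses)``
    with ``ys`` shaped (batch, n_out, NSTATE).
    """
    nb = thetas.shape[0]
    n_out = t_eval.shape[0]
    out = np.empty((nb, n_out, NSTATE))
    statuses = np.zeros(nb, dtype=np.int64)
    for b in range(nb):
        ys, status, _, _ = integrate(thetas[b], y0s[b], t_eval, rtol, atol)
        out[b] = ys
        statuses[b] = status
    return out, statuses


@njit(cache=True)
def integrate(
    theta: np.ndarray,
    y0: np.ndarray,
    t_eval: np.ndarray,
    rtol: float,
    atol: float,
):
    """Integrate from t=0, returning states at ``t_eval`` (sorted, >= 0).

    Returns ``(ys, status, nsteps, nreject)`` with status 0 on success,
    1 if the step size underflowed, 2 on a negativity violation beyond
    solver tolerance (tiny negatives are floored to zero).
    """
    n_out = t_eval.shape[0]
    ys = np.empty((n_out, NSTATE))
    y = y0.copy()
    k = np.empty((7, NSTATE))
    ytmp = np.empty(NSTATE)
    y5 = np.empty(NSTATE)
    y4 = np.empty(NSTATE)
    t = 0.0
    h = 1e-3
    nsteps = 0
    nreject = 0
    status = 0
    iout = 0
    # emit any t_eval == 0 immediately
    while iout < n_out and t_eval[iout] <= 0.0:
        ys[iout] = y
        iout += 1
    while iout < n_out:
        target = t_eval[iout]
        while t < target:
            if h > target - t:
                h = target - t
            if h < 1e-14:
                status = 1
                return ys, status, nsteps, nreject
            rhs(t, y, theta, k[0])
            for s in range(1, 7):
                for m in range(NSTATE):
                    acc = 0.0
                    for q in range(s):
                        if s < 6:
                            acc += _A[s][q] * k[q][m]
                        else:
                            acc += _B5[q] * k[q][m]
                    ytmp[m] = y[m] + h * acc
                rhs(t + _C[s] * h, ytmp, theta, k[s])
            err = 0.0
            ymax = 0.0
            for m in range(NSTATE):
                acc5 = 0.0
                acc4 = 0.0
                for q in range(7):
                    acc5 += _B5[q] * k[q][m]
                    acc4 += _B4[q] * k[q][m]
                y5[m] = y[m] + h * acc5
                y4[m] = y[m] + h * acc4
                sc = atol + rtol * max(abs(y[m]), abs(y5[m]))
                e = (y5[m] - y4[m]) / sc
                err += e * e
                if abs(y5[m]) > ymax:
                    ymax = abs(y5[m])
            err = np.sqrt(err / NSTATE)
            nsteps += 1
            if nsteps > 10_000_000:
                status = 1
                return ys, status, nsteps, nreject
            if err <= 1.0:
                t += h
                floor = -(atol + rtol * ymax)
                for m in range(NSTATE):
                    v = y5[m]
                    if v < 0.0:
                        if v < floor and v < -1e-9:
                            status = 2
                        v = 0.0
                    y[m] = v
                fac = 5.0 if err == 0.0 else min(5.0, max(0.2, 0.9 * err ** -0.2))
                h *= fac
            else:
                nreject += 1
                h *= max(0.2, 0.9 * err ** -0.2)
        ys[iout] = y
        iout += 1
    return ys, status, nsteps, nreject
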