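"""Compiled hot loops for the annealing objective evaluations.

The annealer evaluates the regularized squared-error objective for all
restart chains at every iteration; with a dense grid of ~130 points and 128
chains that is the entire cost of a fit. These kernels run the forward-Euler
recursion and the penalty terms in nopython mode. They are numerically
equivalent to the pure-numpy path in ``model.py`` (same order of
operations per chain), which the tests cross-check.
"""

from __future__ import annotations

import numpy as np
from numba import njit


@njit(cache=True)
def _sigmoid(x: float) -> float:
    if x >= 0.0:
        return 1.0 / (1.0 + np.exp(-x))
    e = np.exp(x)
    return e / (1.0 + e)


@njit(cache=True)
def _penalty(x: float, omega: float) -> float:
    if x <= omega:
        return 0.0
    r = x / omega - 1.0
    return r * r


@njit(cache=True)
def model_objectives(
    params: np.ndarray,  # (R, 3+m): k1, k2, b, w_1..w_m
    y: np.ndarray,  # (m, T) regulator values on the dense grid
    target: np.ndarray,  # (T,)
    dt: float,
    z0: float,
    c: float,
    k1_bound: float,
    steepness_bound: float,
    rho_bound: float,
    maxabs_y: np.ndarray,  # (m,) per-regulator max |y|
) -> np.ndarray:
    R = params.shape[0]
    m, T = y.shape
    out = np.empty(R)
    for r in range(R):
        k1 = params[r, 0]
        k2 = params[r, 1]
        b = params[r, 2]
        decay = 1.0 - k2 * dt
        z = z0
        d0 = z - target[0]
        err = d0 * d0
        min_abs_rho = np.inf
        synth_prev = 0.0
        for i in range(T):
            rho = b
            for j in range(m):
                rho += params[r, 3 + j] * y[j, i]
            a = abs(rho)
            if a < min_abs_rho:
                min_abs_rho = a
            synth = k1 * _sigmoid(rho)
            if i > 0:
                z = z * decay + dt * synth_prev
                if z < 0.0:
                    z = 0.0
                d = z - target[i]
                err += d * d
            synth_prev = synth
        reg = _penalty(k1, k1_bound)
        for j in range(m):
            reg += _penalty(abs(params[r, 3 + j]) * maxabs_y[j], steepness_bound)
        reg += _penalty(min_abs_rho, rho_bound)
        out[r] = err + c * reg
    return out


@njit(cache=True)
def csynth_objectives(
    params: np.ndarray,  # (R, 2): k1, k2
    t: np.ndarray,  # (T,) times relative to t_1
    target: np.ndarray,
    z0: float,
) -> np.ndarray:
    R = params.shape[0]
    T = t.shape[0]
    out = np.empty(R)
    for r in range(R):
        k1 = params[r, 0]
        k2 = params[r, 1]
        zs = k1 / k2
        amp = z0 - zs
        err = 0.0
        for i in range(T):
            d = zs + amp * np.exp(-k2 * t[i]) - target[i]
            err += d * d
        out[r] = err
    return out
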