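"""The regulation kinetics model.

Transcript level z of a target gene controlled by regulators y_1..y_m evolves
as

    dz/dt = k1 * f(rho(t)) - k2 * z,      rho(t) = sum_j w_j y_j(t) + b

where f is the logistic sigmoid, k1 the maximal synthesis rate, k2 the
first-order decay rate, w_j regulator weights and b the bias. The baseline
"constant synthesis" model drops the regulators:

    dz/dt = k1 - k2 * z

which has the closed form z(t) = k1/k2 + (z0 - k1/k2) exp(-k2 (t - t0)).

Fitting minimises the squared prediction error on a dense grid plus a
regularization term that pushes parameters into biologically interpretable
ranges: k1 below the target's maximal expression (maximal transcript level
cannot be reached in under a unit of time starting from zero), bounded
steepness of the regulatory response (max_t |w_j y_j(t)| < 10), and a
regulatory input that approaches the sigmoid's steep region
(min_t |rho(t)| < 0.5). Each bound is enforced softly through a one-sided
quadratic penalty.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.special import expit

from .smoothing import DenseGrid

#: bound on the steepness of the regulatory response, max_t |w_j y_j(t)|
STEEPNESS_BOUND = 10.0
#: the regulatory input must come within this distance of zero at some time
RHO_PROXIMITY_BOUND = 0.5


@dataclass(frozen=True)
class RegulationParams:
    """Parameter vector of the full model: k1, k2, b and one weight per regulator."""

    k1: float
    k2: float
    b: float
    w: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "w", np.atleast_1d(np.asarray(self.w, dtype=float)))
        if not (self.k1 > 0 and self.k2 > 0):
            raise ValueError("k1 and k2 must be positive")
        if not np.all(np.isfinite([self.k1, self.k2, self.b])) or not np.all(
            np.isfinite(self.w)
        ):
            raise ValueError("non-finite parameter")

    @property
    def m(self) -> int:
        return int(self.w.size)

    def as_array(self) -> np.ndarray:
        return np.concatenate([[self.k1, self.k2, self.b], self.w])


@dataclass(frozen=True)
class ConstantSynthesisParams:
    """Zero-regulator baseline: constant synthesis k1 balanced by decay k2."""

    k1: float
    k2: float

    def __post_init__(self) -> None:
        if not (self.k1 > 0 and self.k2 > 0):
            raise ValueError("k1 and k2 must be positive")

    @property
    def steady_state(self) -> float:
        return self.k1 / self.k2


@dataclass(frozen=True)
class RegularizationSpec:
    """Regularization weight c and the three soft bounds.

    ``k1_bound`` is the maximal (smoothed) expression of the target gene and
    is filled in per target at fit time when left as None.
    """

    c: float = 1.0
    steepness_bound: float = STEEPNESS_BOUND
    rho_proximity_bound: float = RHO_PROXIMITY_BOUND
    k1_bound: float | None = None

    def __post_init__(self) -> None:
        if self.c < 0:
            raise ValueError("c must be non-negative")
        if self.steepness_bound <= 0 or self.rho_proximity_bound <= 0:
            raise ValueError("bounds must be positive")
        if self.k1_bound is not None and self.k1_bound <= 0:
            raise ValueError("k1 bound must be positive")

    def with_k1_bound(self, bound: float) -> "RegularizationSpec":
        return RegularizationSpec(
            self.c, self.steepness_bound, self.rho_proximity_bound, bound
        )


def default_c(n_dense: int) -> float:
    """Default regularization weight: one tenth of the dense point count."""
    return max(1.0, float(round(n_dense / 10)))


def sigmoid(x):
    """Logistic soft-threshold f(x) = 1/(1+e^-x); stable for large |x|."""
    return expit(x)


def regulatory_input(w: np.ndarray, b: float, regulator_values) -> np.ndarray:
    """rho = sum_j w_j y_j + b; *regulator_values* is (m,) or (m, T)."""
    w = np.atleast_1d(np.asarray(w, dtype=float))
    y = np.asarray(regulator_values, dtype=float)
    if y.size == 0 and w.size == 0:
        return np.asarray(b, dtype=float)
    # 1-D input is a vector of per-regulator values at one time
    y2 = y[:, None] if y.ndim == 1 else y
    if y2.shape[0] != w.size:
        raise ValueError(f"{w.size} weights but {y2.shape[0]} regulator profiles")
    out = w @ y2 + b
    return out if y.ndim > 1 else np.squeeze(out)[()]


def integrate_model(
    params: RegulationParams,
    regulators: np.ndarray,
    z0: float,
    dense: DenseGrid,
) -> np.ndarray:
    """Forward-Euler solution of the regulation ODE on a dense grid.

    *regulators* is an (m, resolution) matrix of regulator values sampled on
    the same grid. The state is clipped at 0 after every step: transcript
    levels cannot go negative, and extreme trial parameters during annealing
    must not produce runaway negative states.
    """
    if z0 < 0:
        raise ValueError("initial value must be non-negative")
    y = np.atleast_2d(np.asarray(regulators, dtype=float))
    if params.m != y.shape[0]:
        raise ValueError(f"{params.m} weights but {y.shape[0]} regulator rows")
    if y.shape[1] != dense.resolution:
        raise ValueError("regulators not sampled on the dense grid")
    dt = dense.step
    if params.k2 * dt >= 2.0:
        raise ValueError(
            f"Euler step {dt:g} unstable for decay rate {params.k2:g} (k2*dt >= 2)"
        )
    synth = params.k1 * sigmoid(regulatory_input(params.w, params.b, y))
    z = np.empty(dense.resolution)
    z[0] = z0
    decay = 1.0 - params.k2 * dt
    for i in range(dense.resolution - 1):
        z[i + 1] = max(z[i] * decay + dt * synth[i], 0.0)
    return z


def integrate_constant_synthesis(
    params: ConstantSynthesisParams, z0: float, dense: DenseGrid
) -> np.ndarray:
    """Closed-form trajectory of the constant-synthesis model on a dense grid."""
    if z0 < 0:
        raise ValueError("initial value must be non-negative")
    zs = params.steady_state
    t = dense.times
    return zs + (z0 - zs) * np.exp(-params.k2 * (t - t[0]))


def penalty(x: float, omega: float) -> float:
    """One-sided quadratic penalty: 0 below the bound, ((x/omega)-1)^2 above."""
    if omega <= 0:
        raise ValueError("bound must be positive")
    if x <= omega:
        return 0.0
    return (x / omega - 1.0) ** 2


def regularization(
    params: RegulationParams,
    regulators: np.ndarray,
    target_max: float,
    spec: RegularizationSpec,
) -> float:
    """r(beta): weighted sum of the three soft-bound penalties.

    *target_max* is the maximal (smoothed) expression of the target, used as
    the bound on k1.
    """
    y = np.atleast_2d(np.asarray(regulators, dtype=float))
    k1_bound = spec.k1_bound if spec.k1_bound is not None else target_max
    total = penalty(params.k1, k1_bound)
    for j in range(params.m):
        steep = float(np.max(np.abs(params.w[j] * y[j])))
        total += penalty(steep, spec.steepness_bound)
    rho = regulatory_input(params.w, params.b, y)
    total += penalty(float(np.min(np.abs(rho))), spec.rho_proximity_bound)
    return spec.c * total


def objective(
    params: RegulationParams,
    target_dense: np.ndarray,
    regulators_dense: np.ndarray,
    dense: DenseGrid,
    spec: RegularizationSpec,
    z0: float | None = None,
) -> float:
    """Regularized squared error of the model trajectory against the target.

    The error is summed over the dense grid of the smoothed target; the
    initial condition defaults to the target's value at the first time point
    so that the fit depends only on the parameters.
    """
    target = np.asarray(target_dense, dtype=float)
    if target.shape != (dense.resolution,):
        raise ValueError("target not sampled on the dense grid")
    if z0 is None:
        z0 = float(target[0])
    pred = integrate_model(params, regulators_dense, z0, dense)
    sse = float(np.sum((pred - target) ** 2))
    return sse + regularization(params, regulators_dense, float(np.max(target)), spec)
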