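"""B-spline smoothing of noisy expression profiles.

Each profile is fitted by ordinary least squares on a B-spline basis with a
user-chosen number of degrees of freedom (basis functions), then resampled on
a dense equally spaced grid so that the kinetic model can be integrated
accurately with a plain Euler scheme. Smoothing trades away high-frequency
signal (oscillations near the sampling interval are suppressed) for
robustness against measurement noise; df controls that trade-off. Missing
measurements are simply left out of the regression, which also interpolates
them.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.interpolate import BSpline

from .io import TimeGrid

#: default spline order (order = polynomial degree + 1; 3 means quadratic)
DEFAULT_ORDER = 3

#: default number of dense evaluation points
DEFAULT_RESOLUTION = 100


@dataclass(frozen=True)
class DenseGrid:
    """Equally spaced evaluation grid spanning a profile's time domain."""

    start: float
    stop: float
    resolution: int

    def __post_init__(self) -> None:
        if self.resolution < 2:
            raise ValueError("resolution must be at least 2")
        if not self.stop > self.start:
            raise ValueError("empty time domain")

    @property
    def times(self) -> np.ndarray:
        return np.linspace(self.start, self.stop, self.resolution)

    @property
    def step(self) -> float:
        return (self.stop - self.start) / (self.resolution - 1)

    @classmethod
    def for_grid(cls, grid: TimeGrid, resolution: int | None = None) -> "DenseGrid":
        if resolution is None:
            resolution = max(DEFAULT_RESOLUTION, 10 * grid.n)
        if resolution < grid.n:
            raise ValueError("dense resolution below the number of measurements")
        t0, t1 = grid.span
        return cls(t0, t1, resolution)


def default_df(n: int) -> int:
    """Degrees of freedom for smoothing: half the number of measurements.

    Uses round-half-up (13 points -> 7) and clamps to [3, n].
    """
    if n < 6:
        raise ValueError("need at least 6 time points for the default df rule")
    df = int(np.floor(n / 2 + 0.5))
    return min(max(df, 3), n)


def bspline_basis(
    times: np.ndarray, domain: tuple[float, float], df: int, order: int = DEFAULT_ORDER
) -> tuple[np.ndarray, np.ndarray, int]:
    """Design matrix of *df* B-spline basis functions on *domain*.

    Knots are equally spaced over the domain with fully clamped ends. The
    order is lowered when df is too small to support it (df >= order is
    required). Returns (design matrix, full knot vector, degree).
    """
    if df < 3:
        raise ValueError("df must be at least 3")
    order = min(order, df)
    degree = order - 1
    t0, t1 = domain
    n_interior = df - order
    interior = np.linspace(t0, t1, n_interior + 2)[1:-1]
    knots = np.concatenate([np.full(order, t0), interior, np.full(order, t1)])
    x = np.clip(np.asarray(times, dtype=float), t0, t1)
    design = BSpline.design_matrix(x, knots, degree, extrapolate=False).toarray()
    return design, knots, degree


@dataclass
class SmoothedProfile:
    """A continuous least-squares spline representation of one gene's profile."""

    gene_id: str
    knots: np.ndarray
    degree: int
    coefficients: np.ndarray
    time_domain: tuple[float, float]

    @property
    def df(self) -> int:
        return int(self.coefficients.size)

    def __call__(self, times: np.ndarray) -> np.ndarray:
        """Evaluate the spline (unclipped) inside the time domain."""
        t = np.asarray(times, dtype=float)
        lo, hi = self.time_domain
        if np.any(t < lo - 1e-12) or np.any(t > hi + 1e-12):
            raise ValueError(
                f"evaluation outside time domain [{lo}, {hi}] requested"
            )
        spl = BSpline(self.knots, self.coefficients, self.degree, extrapolate=False)
        return np.nan_to_num(spl(np.clip(t, lo, hi)))

    def dense_grid(self, resolution: int | None = None) -> DenseGrid:
        lo, hi = self.time_domain
        if resolution is None:
            resolution = DEFAULT_RESOLUTION
        return DenseGrid(lo, hi, resolution)


def smooth_profile(
    raw_values: np.ndarray,
    grid: TimeGrid,
    df: int | None = None,
    *,
    gene_id: str = "",
    order: int = DEFAULT_ORDER,
) -> SmoothedProfile:
    """Least-squares fit of a noisy profile on a B-spline basis.

    Missing (NaN) points are excluded from the regression; the fitted curve
    interpolates them. Requires at least *df* usable points.
    """
    y = np.asarray(raw_values, dtype=float)
    if y.shape != (grid.n,):
        raise ValueError(f"expected {grid.n} values, got {y.shape}")
    present = ~np.isnan(y)
    n_used = int(present.sum())
    if n_used == 0:
        raise ValueError(f"{gene_id or 'profile'}: all points missing")
    if df is None:
        df = default_df(grid.n)
    if df > n_used:
        raise ValueError(
            f"{gene_id or 'profile'}: df={df} exceeds {n_used} usable points"
        )
    design, knots, degree = bspline_basis(grid.times[present], grid.span, df, order)
    coef, *_ = np.linalg.lstsq(design, y[present], rcond=None)
    return SmoothedProfile(gene_id, knots, degree, coef, grid.span)


def resample(profile: SmoothedProfile, dense: DenseGrid) -> np.ndarray:
    """Evaluate a smoothed profile on a dense grid, clipped at 0 from below.

    Transcript levels are non-negative, so negative spline excursions are
    clipped before any model use.
    """
    lo, hi = profile.time_domain
    if dense.start < lo - 1e-12 or dense.stop > hi + 1e-12:
        raise ValueError("dense grid extends beyond the profile's time domain")
    return np.clip(profile(dense.times), 0.0, None)
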