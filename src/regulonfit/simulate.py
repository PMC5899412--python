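"""Synthetic datasets with known ground truth.

Emulates a bacterial sigma-factor induction experiment: one regulator with a
pulse-shaped expression profile (sharp induction followed by decay, as seen
for stress sigma factors), a set of target genes whose transcript levels are
driven by the regulation ODE with per-target kinetic parameters, plus decoy
genes that the screening steps must remove — flat profiles (no change) and
monotone saturating trajectories of the zero-regulator constant-synthesis
model. Optional Gaussian measurement noise is added on top, scaled to each
gene's signal level.

Ground truth is recorded per gene: the generating parameters and the label
the workflow is expected to assign. Comparisons against truth are made at
the profile level, not the parameter level — vastly different parameter
combinations can yield nearly identical trajectories, so the parameters
themselves are not identifiable.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io import CandidateNetwork, ExpressionSet, TimeGrid
from .model import (
    ConstantSynthesisParams,
    RegulationParams,
    integrate_constant_synthesis,
    integrate_model,
    sigmoid,
)
from .smoothing import DenseGrid


@dataclass(frozen=True)
class FixtureSpec:
    """Study conditions for one synthetic dataset.

    Defaults mirror a typical bacterial time course: 13 samples over 12 time
    units, 20 regulated targets, 5 flat decoys and 5 constant-synthesis
    decoys, noise-free unless a noise level is requested.
    """

    n_targets: int = 20
    n_constant: int = 5
    n_const_synth: int = 5
    n_points: int = 13
    t_max: float = 12.0
    noise_sd: float = 0.0
    seed: int = 0
    #: regulator pulse: base + amp * (t/tau) * exp(1 - t/tau), peaking at tau
    pulse_tau: float = 3.0
    pulse_amp: float = 1.0
    pulse_base: float = 0.1
    #: per-target parameter ranges (inside the regularized box); chosen so
    #: response timescales stay resolvable by the sampling design — features
    #: faster than ~2 sampling intervals cannot survive the smoothing step
    k1_range: tuple[float, float] = (1.0, 2.0)
    k2_range: tuple[float, float] = (0.2, 0.7)
    w_range: tuple[float, float] = (2.0, 5.0)
    repressor_fraction: float = 0.3
    #: generation grid fineness (points per time unit for the truth ODE)
    gen_points_per_unit: int = 80

    def __post_init__(self) -> None:
        if self.n_targets < 1 or self.n_points < 3:
            raise ValueError("need at least 1 target and 3 time points")
        if self.noise_sd < 0:
            raise ValueError("noise sd must be non-negative")


def pulse_profile(times: np.ndarray, spec: FixtureSpec) -> np.ndarray:
    """Sigma-factor-like induction pulse, peak value base + amp at t = tau."""
    s = np.asarray(times, dtype=float) / spec.pulse_tau
    return spec.pulse_base + spec.pulse_amp * s * np.exp(1.0 - s)


def _sample_target(rng: np.random.Generator, spec: FixtureSpec, y_dense, dense):
    """Draw kinetic parameters for one regulated target and integrate its truth."""
    k1 = rng.uniform(*spec.k1_range)
    k2 = rng.uniform(*spec.k2_range)
    w_mag = rng.uniform(*spec.w_range) / max(float(np.max(np.abs(y_dense))), 1e-12)
    sign = -1.0 if rng.random() < spec.repressor_fraction else 1.0
    w = sign * w_mag
    # bias puts the sigmoid's steep region inside the attained regulator range,
    # so the regulatory input crosses zero during the time course
    lo, hi = float(np.min(y_dense)), float(np.max(y_dense))
    q = lo + rng.uniform(0.25, 0.75) * (hi - lo)
    b = -w * q
    params = RegulationParams(k1, k2, b, np.array([w]))
    rho0 = w * float(y_dense[0]) + b
    z0 = max(k1 * float(sigmoid(rho0)) / k2, 0.02)
    truth = integrate_model(params, y_dense[None, :], z0, dense)
    return params, z0, truth


def make_fixture(
    spec: FixtureSpec,
) -> tuple[ExpressionSet, CandidateNetwork, pd.DataFrame]:
    """Generate (expression set, candidate network, ground-truth table).

    The network links the regulator to every other gene; the truth table
    records each gene's kind, generating parameters and the label the
    screening/fitting workflow should assign. Deterministic per seed.
    """
    rng = np.random.Generator(np.random.PCG64(spec.seed))
    times = np.linspace(0.0, spec.t_max, spec.n_points)
    grid = TimeGrid(times)
    resolution = int(spec.t_max * spec.gen_points_per_unit) + 1
    dense = DenseGrid(0.0, spec.t_max, resolution)
    # measurement times land exactly on the generation grid
    sample_idx = np.round(
        (times - times[0]) / dense.step
    ).astype(int)

    y_dense = pulse_profile(dense.times, spec)
    gene_ids = ["reg"]
    profiles = [y_dense[sample_idx]]
    truth_rows = [
        {"gene_id": "reg", "kind": "regulator", "expected_label": "",
         "k1": np.nan, "k2": np.nan, "b": np.nan, "w": np.nan, "z0": np.nan}
    ]

    for i in range(spec.n_targets):
        params, z0, traj = _sample_target(rng, spec, y_dense, dense)
        gid = f"tgt{i:02d}"
        gene_ids.append(gid)
        profiles.append(traj[sample_idx])
        truth_rows.append(
            {"gene_id": gid, "kind": "ode_target", "expected_label": "GOOD_FIT",
             "k1": params.k1, "k2": params.k2, "b": params.b,
             "w": float(params.w[0]), "z0": z0}
        )

    for i in range(spec.n_constant):
        level = rng.uniform(0.3, 2.5)
        gid = f"const{i}"
        gene_ids.append(gid)
        profiles.append(np.full(spec.n_points, level))
        truth_rows.append(
            {"gene_id": gid, "kind": "constant", "expected_label": "NO_CHANGE",
             "k1": np.nan, "k2": np.nan, "b": np.nan, "w": np.nan, "z0": level}
        )

    for i in range(spec.n_const_synth):
        k1 = rng.uniform(0.5, 2.0)
        k2 = rng.uniform(*spec.k2_range)
        params = ConstantSynthesisParams(k1, k2)
        zs = params.steady_state
        # start far from steady state so the trajectory visibly saturates
        offset = rng.uniform(1.0, 2.0)
        z0 = zs + offset if rng.random() < 0.5 else max(zs - offset, 0.01)
        traj = integrate_constant_synthesis(params, z0, dense)
        gid = f"csyn{i}"
        gene_ids.append(gid)
        profiles.append(traj[sample_idx])
        truth_rows.append(
            {"gene_id": gid, "kind": "const_synth",
             "expected_label": "CONSTANT_SYNTHESIS",
             "k1": k1, "k2": k2, "b": np.nan, "w": np.nan, "z0": z0}
        )

    values = np.vstack(profiles)
    if spec.noise_sd > 0:
        scale = spec.noise_sd * np.maximum(values.max(axis=1, keepdims=True), 1e-12)
        values = values + rng.standard_normal(values.shape) * scale
        values = np.clip(values, 0.0, None)

    dataset = ExpressionSet(gene_ids, values, grid)
    network = CandidateNetwork([("reg", g) for g in gene_ids if g != "reg"])
    truth = pd.DataFrame(truth_rows)
    return dataset, network, truth
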