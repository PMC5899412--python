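"""Gaussian-process random regulator profiles and false-positive estimation.

A candidate regulon is only credible if its targets are fitted markedly
better by the true regulator's profile than by arbitrary smooth curves. To
estimate the false-positive acceptance rate, random profiles with similar
magnitude and rate of change as the regulator are drawn from a zero-mean
Gaussian process with a squared-exponential kernel, transformed to be
positive, and substituted for the regulator; the fraction of targets still
accepted measures how easily the model is fooled.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.gaussian_process import GaussianProcessRegressor
from sklearn.gaussian_process.kernels import RBF, ConstantKernel

from .fitting import FitSettings, Label, _task_seed, evaluate_edges
from .io import CandidateNetwork, ExpressionSet
from .smoothing import DenseGrid, SmoothedProfile, resample


@dataclass(frozen=True)
class GPNullConfig:
    """Settings for drawing random regulator profiles.

    ``variance``/``lengthscale`` default to None, meaning they are matched
    to the reference regulator by maximising the GP marginal likelihood of
    its (centered) smoothed profile.
    """

    n_profiles: int = 50
    seed: int = 0
    variance: float | None = None
    lengthscale: float | None = None

    def __post_init__(self) -> None:
        if self.n_profiles < 1:
            raise ValueError("need at least one null profile")
        if self.variance is not None and self.variance <= 0:
            raise ValueError("kernel variance must be positive")
        if self.lengthscale is not None and self.lengthscale <= 0:
            raise ValueError("kernel lengthscale must be positive")


@dataclass
class NullSummary:
    """Acceptance proportions: the true regulator vs each random profile."""

    regulator_proportion: float
    null_proportions: np.ndarray
    n_targets_tested: int

    @property
    def mean_null_proportion(self) -> float:
        return float(np.mean(self.null_proportions))


def match_gp_hyperparams(
    reference_dense: np.ndarray, dense: DenseGrid
) -> tuple[float, float]:
    """Maximum-marginal-likelihood (variance, lengthscale) for the reference.

    The reference profile is centered; a small noise floor keeps the kernel
    matrix well conditioned. Matching the hyperparameters to the regulator
    operationalises "similar magnitude and rate of change".
    """
    z = np.asarray(reference_dense, dtype=float)
    sd = float(np.std(z))
    if sd < 1e-12:
        raise ValueError("reference profile is constant; cannot match a GP to it")
    t = dense.times[:, None]
    span = dense.stop - dense.start
    # bounds keep the optimiser off the flat large-variance/long-lengthscale
    # ridge that smooth single-bump references induce; the sampler's
    # mean-matching rescale cancels the variance anyway
    kernel = ConstantKernel(sd**2, (1e-2 * sd**2, 1e4 * sd**2)) * RBF(
        span / 5, (span / 50, span * 2)
    )
    gpr = GaussianProcessRegressor(
        kernel=kernel,
        alpha=1e-6 * sd**2,
        normalize_y=False,
        n_restarts_optimizer=3,
        random_state=0,
    )
    gpr.fit(t, z - z.mean())
    k = gpr.kernel_
    variance = float(k.k1.constant_value)
    lengthscale = float(k.k2.length_scale)
    return variance, lengthscale


def _se_kernel_matrix(times: np.ndarray, variance: float, lengthscale: float):
    d2 = (times[:, None] - times[None, :]) ** 2
    return variance * np.exp(-0.5 * d2 / lengthscale**2)


def sample_null_profiles(
    config: GPNullConfig,
    dense: DenseGrid,
    reference_dense: np.ndarray,
) -> list[np.ndarray]:
    """Draw random regulator-like profiles on the dense grid.

    Draws come from GP(0, SE kernel); each is made positive by taking the
    absolute value and then linearly rescaled so its mean equals the
    reference profile's mean (keeping the magnitude comparable to the
    regulator while preserving the draw's rate of change). Deterministic
    per seed.
    """
    ref = np.asarray(reference_dense, dtype=float)
    if config.variance is None or config.lengthscale is None:
        variance, lengthscale = match_gp_hyperparams(ref, dense)
        if config.variance is not None:
            variance = config.variance
        if config.lengthscale is not None:
            lengthscale = config.lengthscale
    else:
        variance, lengthscale = config.variance, config.lengthscale

    K = _se_kernel_matrix(dense.times, variance, lengthscale)
    jitter = 1e-10 * variance
    for _ in range(6):
        try:
            L = np.linalg.cholesky(K + jitter * np.eye(len(K)))
            break
        except np.linalg.LinAlgError:
            jitter *= 100
    else:
        raise np.linalg.LinAlgError("kernel matrix not positive definite")

    ref_mean = max(float(np.mean(ref)), 1e-12)
    profiles = []
    for i in range(config.n_profiles):
        gen = np.random.Generator(
            np.random.PCG64(_task_seed(config.seed, "null_profile", i))
        )
        draw = np.abs(L @ gen.standard_normal(len(K)))
        mean = float(np.mean(draw))
        if mean < 1e-12:
            draw = np.full_like(draw, ref_mean)
        else:
            draw = draw * (ref_mean / mean)
        profiles.append(draw)
    return profiles


def null_test(
    dataset: ExpressionSet,
    regulon_edges: CandidateNetwork,
    regulator_id: str,
    config: GPNullConfig,
    settings: FitSettings | None = None,
) -> NullSummary:
    """Contrast acceptance by the true regulator against GP random profiles.

    Runs the edge evaluation once with the measured regulator profile and
    once per random profile substituted in its place. Proportions are over
    the targets that survive the no-change and constant-synthesis screens:
    acceptances with the true regulator are the method's true positives on a
    trusted regulon, acceptances of a nonsensical random profile are false
    positives.
    """
    bad = [e for e in regulon_edges.edges if e[0] != regulator_id]
    if bad:
        raise ValueError(f"edges with a different regulator: {bad[:3]}")
    settings = settings or FitSettings()
    dense, margin, classification, _ = settings.resolve(dataset)
    from .fitting import _GeneCache

    cache = _GeneCache(
        dataset,
        dense,
        settings.df,
        margin,
        classification,
        settings.annealing,
        settings.annealing.seed,
    )
    true_table = evaluate_edges(dataset, regulon_edges, settings, _cache=cache)
    tested = true_table[
        ~true_table["label"].isin([str(Label.NO_CHANGE), str(Label.CONSTANT_SYNTHESIS)])
    ]
    n_tested = len(tested)
    if n_tested == 0:
        raise ValueError("nothing to test: no targets survive the screens")
    reg_prop = float((tested["label"] == str(Label.GOOD_FIT)).mean())

    from .smoothing import smooth_profile

    prof = smooth_profile(
        dataset.row(regulator_id), dataset.grid, settings.df, gene_id=regulator_id
    )
    ref_dense = resample(prof, dense)
    nulls = sample_null_profiles(config, dense, ref_dense)

    surviving = CandidateNetwork(
        [tuple(e) for e in tested[["regulator", "target"]].itertuples(index=False)]
    )
    null_props = np.empty(len(nulls))
    for i, profile in enumerate(nulls):
        table = evaluate_edges(
            dataset,
            surviving,
            settings,
            regulator_override={regulator_id: profile},
            _cache=cache,
        )
        null_props[i] = float((table["label"] == str(Label.GOOD_FIT)).mean())
    return NullSummary(reg_prop, null_props, n_tested)


def summary_frame(summary: NullSummary, regulator_id: str) -> pd.DataFrame:
    rows = [
        {"profile": regulator_id, "kind": "regulator",
         "accepted_proportion": summary.regulator_proportion},
    ]
    for i, p in enumerate(summary.null_proportions):
        rows.append(
            {"profile": f"null_{i}", "kind": "random", "accepted_proportion": float(p)}
        )
    rows.append(
        {"profile": "mean_random", "kind": "summary",
         "accepted_proportion": summary.mean_null_proportion}
    )
    return pd.DataFrame(rows)
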