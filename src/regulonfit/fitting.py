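"""Model fitting by multi-restart simulated annealing, baseline screens and
classification.

Fitting pipeline for one regulator-target pair:

1. *No-change screen*: a gene whose smoothed profile never leaves the error
   band around its own mean carries no information and is excluded both as
   target and as regulator.
2. *Constant-synthesis screen*: a gene explained by the zero-regulator model
   dz/dt = k1 - k2 z could be "fitted" by any regulator with w = 0 and a
   large bias, so it is excluded as a target (but remains usable as a
   regulator).
3. *Annealed fit* of the full model with 128 restarts from random initial
   points; the best parameter vector over all restarts is kept.
4. *Classification*: the fit quality is the fraction of time points where
   the model trajectory lies inside the per-point error margin of the
   measured (smoothed) profile; a fit with quality above the threshold
   (default 0.8) is a good fit, i.e. a plausible regulation.

All randomness is driven by per-task seed sequences derived from one base
seed and the gene/edge names, so every stage is individually re-runnable
and bit-reproducible.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field, replace
from enum import Enum

import numpy as np
import pandas as pd

from .io import CandidateNetwork, ExpressionSet, RESULT_COLUMNS, empty_result_table
from .model import (
    ConstantSynthesisParams,
    RegulationParams,
    RegularizationSpec,
    default_c,
    integrate_constant_synthesis,
    integrate_model,
    regularization,
)
from .smoothing import DenseGrid, resample, smooth_profile


class Label(str, Enum):
    NO_CHANGE = "NO_CHANGE"
    CONSTANT_SYNTHESIS = "CONSTANT_SYNTHESIS"
    GOOD_FIT = "GOOD_FIT"
    NO_FIT = "NO_FIT"

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value


@dataclass(frozen=True)
class ErrorMarginSpec:
    """Per-timepoint tolerance band: max(e_minimal, e_absolute + z * e_relative)."""

    e_minimal: float = 0.0
    e_absolute: float = 0.0
    e_relative: float = 0.1

    def __post_init__(self) -> None:
        if self.e_minimal < 0 or self.e_absolute < 0 or self.e_relative < 0:
            raise ValueError("error margin components must be non-negative")
        if self.e_minimal == self.e_absolute == self.e_relative == 0:
            raise ValueError("at least one error margin component must be positive")

    @classmethod
    def default_for(cls, dataset_max: float) -> "ErrorMarginSpec":
        """Default band: 10% relative error with a floor of 2.5% of the
        dataset's maximal expression."""
        return cls(e_minimal=0.025 * dataset_max, e_absolute=0.0, e_relative=0.1)


@dataclass(frozen=True)
class ClassificationConfig:
    fit_quality_threshold: float = 0.8
    margin: ErrorMarginSpec = field(default_factory=ErrorMarginSpec)

    def __post_init__(self) -> None:
        if not 0 < self.fit_quality_threshold <= 1:
            raise ValueError("threshold must be in (0, 1]")


@dataclass(frozen=True)
class AnnealingConfig:
    """Simulated-annealing schedule. 128 restarts give highly replicable fits.

    Each restart runs an independent chain from a random initial point with
    geometric cooling; the initial temperature is the objective value of the
    chain's initial point. Proposal steps are Gaussian with per-parameter
    scales, shrinking with the square root of the relative temperature so
    that late iterations refine rather than explore.
    """

    restarts: int = 128
    iterations: int = 1000
    cooling: float = 0.95
    seed: int = 0
    min_step_fraction: float = 0.02
    #: Nelder-Mead refinement of the winning restart (deterministic); the
    #: annealing remains the primary search, the polish only sharpens the
    #: endpoint of the best chain
    polish: bool = True
    polish_maxiter: int = 600

    def __post_init__(self) -> None:
        if self.restarts < 1:
            raise ValueError("need at least one restart")
        if not 0 < self.cooling < 1:
            raise ValueError("cooling factor must be in (0, 1)")


@dataclass
class FitResult:
    params: RegulationParams | ConstantSynthesisParams | None
    predicted: np.ndarray | None
    residual_ss: float
    regularization_term: float
    fit_quality: float
    label: Label
    restarts_agreeing: int = 0
    note: str = ""


def error_margin(z_t, margin: ErrorMarginSpec):
    """Allowed deviation at expression level z: max(e_min, e_abs + z*e_rel)."""
    z = np.asarray(z_t, dtype=float)
    return np.maximum(margin.e_minimal, margin.e_absolute + z * margin.e_relative)


def fit_quality(predicted, measured, margin: ErrorMarginSpec) -> float:
    """Fraction of time points where the fit lies inside the error band."""
    pred = np.asarray(predicted, dtype=float)
    meas = np.asarray(measured, dtype=float)
    if pred.shape != meas.shape:
        raise ValueError("predicted and measured profiles on different grids")
    inside = np.abs(pred - meas) <= error_margin(meas, margin)
    return float(np.mean(inside))


def classify_no_change(smoothed_dense, margin: ErrorMarginSpec) -> bool:
    """True if the profile never leaves the error band around its own mean."""
    z = np.asarray(smoothed_dense, dtype=float)
    mean = float(np.mean(z))
    return bool(np.all(np.abs(z - mean) <= error_margin(mean, margin)))


def _task_seed(base_seed: int, *names: str | int) -> np.random.SeedSequence:
    """Stable per-task seed from the base seed and task names.

    Names are hashed with CRC32 so identical tasks get identical streams
    regardless of the order stages are run in.
    """
    words = [
        zlib.crc32(n.encode()) if isinstance(n, str) else int(n) & 0xFFFFFFFF
        for n in names
    ]
    return np.random.SeedSequence([int(base_seed) & 0x7FFFFFFF, *words])


def _anneal(
    eval_batch,
    init_lo: np.ndarray,
    init_hi: np.ndarray,
    scales: np.ndarray,
    positive: np.ndarray,
    upper: np.ndarray,
    config: AnnealingConfig,
    seed_seq: np.random.SeedSequence,
) -> tuple[np.ndarray, float, int, int]:
    """Vectorised multi-restart annealing.

    ``eval_batch`` maps an (R, p) parameter matrix to (R,) objective values.
    Each restart consumes its own pre-drawn random stream, so the best
    objective over the first k restarts does not depend on how many more
    restarts follow, and ties resolve to the lowest restart index.

    Returns (best parameter vector, best objective, best restart index,
    number of restarts agreeing with the best objective to within 0.1%).
    """
    R, p = config.restarts, init_lo.size
    iters = config.iterations
    children = seed_seq.spawn(R)
    init_u = np.empty((R, p))
    normals = np.empty((R, iters, p))
    unifs = np.empty((R, iters))
    for r, child in enumerate(children):
        gen = np.random.Generator(np.random.PCG64(child))
        init_u[r] = gen.random(p)
        normals[r] = gen.standard_normal((iters, p))
        unifs[r] = gen.random(iters)

    cur = init_lo + init_u * (init_hi - init_lo)
    cur_obj = eval_batch(cur)
    temp0 = np.maximum(cur_obj, 1e-300)
    temp = temp0.copy()
    best = cur.copy()
    best_obj = cur_obj.copy()
    min_frac = config.min_step_fraction
    for i in range(iters):
        # proposal scale tracks sqrt(T/T0): broad early, fine late
        step = scales * np.maximum(np.sqrt(temp / temp0), min_frac)[:, None]
        prop = cur + normals[:, i, :] * step
        prop[:, positive] = np.maximum(np.abs(prop[:, positive]), 1e-9)
        np.minimum(prop, upper, out=prop)
        prop_obj = eval_batch(prop)
        with np.errstate(over="ignore"):
            accept = prop_obj <= cur_obj
            worse = ~accept
            accept[worse] = unifs[worse, i] < np.exp(
                -(prop_obj[worse] - cur_obj[worse]) / temp[worse]
            )
        cur[accept] = prop[accept]
        cur_obj[accept] = prop_obj[accept]
        improved = prop_obj < best_obj
        best[improved] = prop[improved]
        best_obj[improved] = prop_obj[improved]
        temp *= config.cooling
    idx = int(np.argmin(best_obj))  # argmin takes the lowest index on ties
    winner_x, winner = best[idx], best_obj[idx]
    if config.polish:
        winner_x, winner = _polish(
            eval_batch, winner_x, float(winner), positive, upper, config
        )
    tol = 1e-3 * max(abs(winner), 1e-12)
    agreeing = int(np.sum(best_obj <= winner + tol))
    return winner_x, float(winner), idx, agreeing


def _polish(eval_batch, x0, f0, positive, upper, config):
    """Deterministic Nelder-Mead refinement of the best annealing endpoint."""
    from scipy.optimize import minimize

    def fun(x):
        x = x.copy()
        x[positive] = np.maximum(np.abs(x[positive]), 1e-9)
        np.minimum(x, upper, out=x)
        return float(eval_batch(x[None, :])[0])

    res = minimize(
        fun,
        x0,
        method="Nelder-Mead",
        options={"maxiter": config.polish_maxiter, "xatol": 1e-8, "fatol": 1e-10},
    )
    if res.fun < f0:
        x = res.x.copy()
        x[positive] = np.maximum(np.abs(x[positive]), 1e-9)
        np.minimum(x, upper, out=x)
        return x, float(res.fun)
    return x0, f0


def _model_objective_batch(
    target: np.ndarray,
    regulators: np.ndarray,
    dense: DenseGrid,
    spec: RegularizationSpec,
    z0: float,
):
    """Batch objective for the full model: squared error + regularization.

    Regulator values on the dense grid are non-negative (clipped splines),
    so max_t |w_j y_j(t)| factors as |w_j| * max_t y_j(t). Evaluation runs
    in a compiled kernel; the annealer calls this once per iteration for
    all restart chains.
    """
    from ._kernels import model_objectives

    y = np.ascontiguousarray(np.atleast_2d(regulators), dtype=float)
    target = np.ascontiguousarray(target, dtype=float)
    maxabs_y = np.max(np.abs(y), axis=1)
    k1_bound = spec.k1_bound if spec.k1_bound is not None else float(np.max(target))
    dt = dense.step

    def eval_batch(params: np.ndarray) -> np.ndarray:
        return model_objectives(
            np.ascontiguousarray(params),
            y,
            target,
            dt,
            z0,
            spec.c,
            k1_bound,
            spec.steepness_bound,
            spec.rho_proximity_bound,
            maxabs_y,
        )

    return eval_batch


def _const_synth_objective_batch(target: np.ndarray, dense: DenseGrid, z0: float):
    from ._kernels import csynth_objectives

    t = np.ascontiguousarray(dense.times - dense.times[0])
    target = np.ascontiguousarray(target, dtype=float)

    def eval_batch(params: np.ndarray) -> np.ndarray:
        return csynth_objectives(np.ascontiguousarray(params), t, target, z0)

    return eval_batch


def fit_constant_synthesis(
    target_dense: np.ndarray,
    dense: DenseGrid,
    classification: ClassificationConfig,
    config: AnnealingConfig,
    seed_seq: np.random.SeedSequence | None = None,
) -> FitResult:
    """Fit the zero-regulator baseline dz/dt = k1 - k2 z by annealing.

    The model's closed form makes each objective evaluation exact and cheap.
    The label is CONSTANT_SYNTHESIS when the fit quality reaches the
    threshold, meaning the gene is uninformative as a target.
    """
    target = np.asarray(target_dense, dtype=float)
    z0 = float(target[0])
    max_z = max(float(np.max(target)), 1e-12)
    dt = dense.step
    eval_batch = _const_synth_objective_batch(target, dense, z0)
    span = dense.stop - dense.start
    init_lo = np.array([1e-6, 0.01])
    init_hi = np.array([2.0 * max_z, 2.0])
    scales = np.array([0.1 * max_z, 0.1])
    positive = np.array([True, True])
    upper = np.array([np.inf, 1.9 / dt])
    if seed_seq is None:
        seed_seq = np.random.SeedSequence(config.seed)
    best, best_obj, _, agreeing = _anneal(
        eval_batch, init_lo, init_hi, scales, positive, upper, config, seed_seq
    )
    params = ConstantSynthesisParams(max(best[0], 1e-12), max(best[1], 1e-12))
    predicted = integrate_constant_synthesis(params, z0, dense)
    quality = fit_quality(predicted, target, classification.margin)
    label = (
        Label.CONSTANT_SYNTHESIS
        if quality >= classification.fit_quality_threshold
        else Label.NO_FIT
    )
    return FitResult(
        params=params,
        predicted=predicted,
        residual_ss=float(np.sum((predicted - target) ** 2)),
        regularization_term=0.0,
        fit_quality=quality,
        label=label,
        restarts_agreeing=agreeing,
    )


def anneal_fit(
    target_dense: np.ndarray,
    regulators_dense: np.ndarray,
    dense: DenseGrid,
    spec: RegularizationSpec,
    config: AnnealingConfig,
    classification: ClassificationConfig,
    seed_seq: np.random.SeedSequence | None = None,
) -> FitResult:
    """Fit the full regulation model to one target given regulator profiles.

    Runs ``config.restarts`` annealing chains from random initial points
    covering the regularized parameter box and keeps the minimum-objective
    parameter vector (ties go to the lowest restart index). Deterministic
    given the seed.
    """
    target = np.asarray(target_dense, dtype=float)
    y = np.atleast_2d(np.asarray(regulators_dense, dtype=float))
    m = y.shape[0]
    if m == 0:
        raise ValueError("no regulators: use the constant-synthesis path")
    if np.all(np.isnan(y)):
        raise ValueError("regulator profile entirely missing")
    z0 = float(target[0])
    max_z = max(float(np.max(target)), 1e-12)
    maxabs_y = np.maximum(np.max(np.abs(y), axis=1), 1e-12)
    dt = dense.step

    eval_batch = _model_objective_batch(target, y, dense, spec, z0)
    init_lo = np.concatenate([[1e-6, 0.01, -5.0], -5.0 / maxabs_y])
    init_hi = np.concatenate([[max_z, 2.0, 5.0], 5.0 / maxabs_y])
    scales = np.concatenate([[0.1 * max_z, 0.1, 0.5], 0.5 / maxabs_y])
    positive = np.array([True, True] + [False] * (1 + m))
    upper = np.array([np.inf, 1.9 / dt] + [np.inf] * (1 + m))
    if seed_seq is None:
        seed_seq = np.random.SeedSequence(config.seed)
    best, best_obj, _, agreeing = _anneal(
        eval_batch, init_lo, init_hi, scales, positive, upper, config, seed_seq
    )
    params = RegulationParams(
        max(best[0], 1e-12), max(best[1], 1e-12), best[2], best[3:]
    )
    predicted = integrate_model(params, y, z0, dense)
    quality = fit_quality(predicted, target, classification.margin)
    reg = regularization(params, y, max_z, spec)
    label = (
        Label.GOOD_FIT if quality >= classification.fit_quality_threshold else Label.NO_FIT
    )
    return FitResult(
        params=params,
        predicted=predicted,
        residual_ss=float(np.sum((predicted - target) ** 2)),
        regularization_term=reg,
        fit_quality=quality,
        label=label,
        restarts_agreeing=agreeing,
    )


@dataclass(frozen=True)
class FitSettings:
    """Bundle of everything evaluate_edges needs besides data.

    ``df`` None means half the number of time points; ``margin`` None means
    the dataset-scaled default band; ``c`` None means one tenth of the dense
    point count.
    """

    df: int | None = None
    resolution: int | None = None
    margin: ErrorMarginSpec | None = None
    fit_quality_threshold: float = 0.8
    c: float | None = None
    annealing: AnnealingConfig = field(default_factory=AnnealingConfig)

    def resolve(
        self, dataset: ExpressionSet
    ) -> tuple[DenseGrid, ErrorMarginSpec, ClassificationConfig, RegularizationSpec]:
        dense = DenseGrid.for_grid(dataset.grid, self.resolution)
        margin = self.margin
        if margin is None:
            margin = ErrorMarginSpec.default_for(float(np.nanmax(dataset.values)))
        classification = ClassificationConfig(self.fit_quality_threshold, margin)
        c = self.c if self.c is not None else default_c(dense.resolution)
        return dense, margin, classification, RegularizationSpec(c=c)


class _GeneCache:
    """Per-run cache of smoothed/densified profiles and screen outcomes."""

    def __init__(self, dataset, dense, df, margin, classification, annealing, seed):
        self.dataset = dataset
        self.dense = dense
        self.df = df
        self.margin = margin
        self.classification = classification
        self.annealing = annealing
        self.seed = seed
        self._dense_values: dict[str, np.ndarray] = {}
        self._no_change: dict[str, bool] = {}
        self._const_synth: dict[str, FitResult] = {}

    def dense_values(self, gene: str) -> np.ndarray:
        if gene not in self._dense_values:
            prof = smooth_profile(
                self.dataset.row(gene), self.dataset.grid, self.df, gene_id=gene
            )
            self._dense_values[gene] = resample(prof, self.dense)
        return self._dense_values[gene]

    def is_no_change(self, gene: str) -> bool:
        if gene not in self._no_change:
            self._no_change[gene] = classify_no_change(
                self.dense_values(gene), self.margin
            )
        return self._no_change[gene]

    def const_synth_fit(self, gene: str) -> FitResult:
        if gene not in self._const_synth:
            self._const_synth[gene] = fit_constant_synthesis(
                self.dense_values(gene),
                self.dense,
                self.classification,
                self.annealing,
                _task_seed(self.seed, "const_synth", gene),
            )
        return self._const_synth[gene]


def _result_row(regulator, target, fit: FitResult) -> dict:
    row = dict.fromkeys(RESULT_COLUMNS)
    row.update(
        regulator=regulator,
        target=target,
        label=str(fit.label),
        fit_quality=fit.fit_quality,
        residual_ss=fit.residual_ss,
        regularization=fit.regularization_term,
        note=fit.note,
        provenance="auto",
    )
    p = fit.params
    if isinstance(p, RegulationParams):
        row.update(k1=p.k1, k2=p.k2, b=p.b, w=";".join("%.6g" % x for x in p.w))
    elif isinstance(p, ConstantSynthesisParams):
        row.update(k1=p.k1, k2=p.k2)
    return row


def evaluate_edges(
    dataset: ExpressionSet,
    network: CandidateNetwork,
    settings: FitSettings | None = None,
    *,
    regulator_override: dict[str, np.ndarray] | None = None,
    _cache: "_GeneCache | None" = None,
) -> pd.DataFrame:
    """Run the screens and per-edge fits for every candidate regulation.

    Targets removed by the no-change or constant-synthesis screens are
    reported with those labels and not fitted. Edges whose regulator is
    itself a no-change gene are excluded too (a flat regulator carries no
    regulatory information). ``regulator_override`` maps regulator ids to
    dense profiles substituted in place of the measured ones (used by the
    random-profile null test).
    """
    settings = settings or FitSettings()
    dense, margin, classification, reg_spec = settings.resolve(dataset)
    network.resolve(dataset)
    seed = settings.annealing.seed
    cache = _cache or _GeneCache(
        dataset, dense, settings.df, margin, classification, settings.annealing, seed
    )
    rows: list[dict] = []
    for regulator, target in network.edges:
        override = regulator_override.get(regulator) if regulator_override else None
        if override is None and cache.is_no_change(regulator):
            fit = FitResult(
                params=None,
                predicted=None,
                residual_ss=np.nan,
                regularization_term=np.nan,
                fit_quality=np.nan,
                label=Label.NO_CHANGE,
                note="regulator shows no change",
            )
            rows.append(_result_row(regulator, target, fit))
            continue
        if cache.is_no_change(target):
            fit = FitResult(
                params=None,
                predicted=None,
                residual_ss=np.nan,
                regularization_term=np.nan,
                fit_quality=np.nan,
                label=Label.NO_CHANGE,
            )
            rows.append(_result_row(regulator, target, fit))
            continue
        cs = cache.const_synth_fit(target)
        if cs.label is Label.CONSTANT_SYNTHESIS:
            rows.append(_result_row(regulator, target, cs))
            continue
        target_dense = cache.dense_values(target)
        reg_dense = override if override is not None else cache.dense_values(regulator)
        spec = reg_spec.with_k1_bound(max(float(np.max(target_dense)), 1e-12))
        fit = anneal_fit(
            target_dense,
            reg_dense,
            dense,
            spec,
            settings.annealing,
            classification,
            _task_seed(seed, "edge", regulator, target),
        )
        rows.append(_result_row(regulator, target, fit))
    if not rows:
        return empty_result_table()
    return pd.DataFrame(rows, columns=RESULT_COLUMNS)


def apply_overrides(table: pd.DataFrame, overrides: pd.DataFrame) -> pd.DataFrame:
    """Replace labels per a manual-decision table; provenance becomes "manual".

    Raises on overrides naming edges absent from the result table.
    """
    valid = {str(l) for l in Label}
    out = table.copy()
    for _, row in overrides.iterrows():
        if row["new_label"] not in valid:
            raise ValueError(f"unknown label in overrides: {row['new_label']!r}")
        mask = (out["regulator"] == row["regulator"]) & (out["target"] == row["target"])
        if not mask.any():
            raise ValueError(
                f"override references unknown edge: "
                f"({row['regulator']}, {row['target']})"
            )
        out.loc[mask, "label"] = row["new_label"]
        out.loc[mask, "provenance"] = "manual"
    return out
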