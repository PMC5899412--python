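# Methods

This note documents the model, the numerical choices, the defaults and
their rationale, what the synthetic data generator does and does not
emulate, and the known limitations.

## Kinetic model and objective

Transcription of a target z under regulators y₁…y_m is modelled as

    dz/dt = k₁ f(ρ(t)) − k₂ z,   ρ(t) = Σⱼ wⱼ yⱼ(t) + b,   f(x) = 1/(1+e⁻ˣ),

a single-gene neural-network-style kinetic model: synthesis saturates at k₁
(expression units per time unit), decay is first order with rate k₂ (per
time unit), the weights wⱼ (per expression unit) set the strength and sign
of each regulatory input and the bias b (dimensionless) sets the basal
activation. Time units are taken exactly as given in the input header; no
rescaling is applied, and the k₁ bound's "unit time" means one unit of that
axis.

The fitted objective is the squared error between the model trajectory and
the smoothed target, summed over the dense evaluation grid, plus a
regularization term

    r(β) = c·[ γ(k₁, max_t z(t)) + Σⱼ γ(max_t |wⱼyⱼ(t)|, 10) + γ(min_t |ρ(t)|, 0.5) ],

with γ(x, ω) = 0 for x ≤ ω and ((x/ω)−1)² above. The three bounds encode,
respectively: maximal transcript level cannot be reached from zero in under
a unit of time; the regulatory response must not be a hard step; and the
regulatory input should pass near the sigmoid's steep region at some time
point — otherwise the sigmoid is effectively linear over the attained range
and (k₁, w, b) trade off freely. Summing the error on the dense grid
(rather than only at the N measurement times) matches the reason the
profiles are densified in the first place: accurate cheap integration and
comparison. "Maximal expression level" in the k₁ bound is the smoothed
maximum.

The default regularization weight is c = max(1, round(T/10)) where T is the
number of dense evaluation points — one tenth of the number of time points
after smoothing. The initial condition is always the smoothed target value
at the first time point, so a fit depends only on β.

## Smoothing

Each profile is fitted by ordinary least squares on a B-spline basis of
order 3 (quadratic; order = degree + 1) with df basis functions, knots
equally spaced over the time domain with fully clamped ends, and missing
points excluded from the regression (which also interpolates them). The
default df is round-half-up of N/2, clamped to [3, N]; for the typical
13-point series this gives df = 7. df is the sensitivity/specificity dial:
smaller df smooths more aggressively, accepting more regulations (true and
false alike).

Two caveats discovered while validating:

* Residual sum of squares is **not** monotone in df in general, because
  uniform-knot spline spaces are not nested as df increments; it is
  monotone along the dyadic chain df = 3, 4, 6, 10, … where the knot sets
  nest. The property tests assert the nested chain only.
* The least-squares spline can overshoot near the domain boundary when the
  profile has high curvature within the first knot interval; smoothed
  values are clipped at 0 from below before any model use, since transcript
  levels are non-negative.

The dense evaluation grid has max(100, 10·N) equally spaced points (130 for
N = 13), which makes the first-order Euler error negligible relative to the
default error bands for decay rates inside the regularized range.

## Integration

The full model is integrated by forward Euler on the dense grid with the
state clipped at 0 after each step; clipping prevents runaway negative
states at extreme trial parameters during annealing. Steps with k₂·Δt ≥ 2
(the linear stability limit) are rejected outright, and the annealer clamps
trial k₂ below 1.9/Δt. Forward Euler is first-order: at dense resolution
1000 over a 5-unit span the deviation from the closed form of the
saturated-activation model is ~9×10⁻⁴ for k₂ = 0.5, scaling linearly with
both step size and decay rate. The constant-synthesis baseline
dz/dt = k₁ − k₂z is evaluated by its closed form
z(t) = k₁/k₂ + (z₀ − k₁/k₂)e^(−k₂(t−t₁)) — exact and cheaper than Euler.

## Optimisation

Each fit runs 128 independent simulated-annealing chains (128 was chosen as
enough for highly replicable classifications, and the replicability check
confirms it on the synthetic data). Per chain: initial point drawn
uniformly from k₁ ∈ (0, max z), k₂ ∈ (0.01, 2), b ∈ (−5, 5),
wⱼ ∈ (−5, 5)/max|yⱼ| — a box covering the regularized region; 1000 Gaussian
proposal steps with per-parameter base scales (0.1·max z, 0.1, 0.5,
0.5/max|yⱼ|), reflected at 0 for k₁ and k₂; geometric cooling T ← 0.95·T
from an initial temperature equal to the chain's initial objective value.
Proposal scales shrink with √(T/T₀), floored at 2% of the base scale, so
early iterations explore and late iterations refine; with fixed scales the
chains plateau at a precision much coarser than the error bands. The
minimum-objective chain wins, ties resolving to the lowest restart index,
and its endpoint is refined by a deterministic Nelder–Mead polish (the
annealing remains the primary search; the polish is derivative-free and
only sharpens the winning endpoint).

Randomness: every task (per-gene constant-synthesis fit, per-edge model
fit, per-profile GP draw) derives its own seed sequence from the base seed
and the CRC32 of the gene/edge names, and each restart spawns an
independent child stream whose draws are fixed before the loop starts.
Consequences: identical config + seed gives byte-identical outputs; stages
rerun in isolation reproduce the end-to-end run; and the best objective
over the first k restarts does not depend on how many more restarts follow.
The objective evaluations run in compiled (numba) kernels, cross-checked in
the tests against the pure-numpy reference implementation.

## Screens and classification

The per-point error margin is max{e_min, e_abs + z(t)·e_rel}. Published
time-series data rarely quantifies uncertainty, so the margin is the user's
statement of expected error; the defaults are e_rel = 0.1, e_abs = 0 and
e_min = 2.5% of the dataset's maximal expression — a 10% relative band with
a floor that keeps near-zero expression levels from demanding impossible
precision. Fit quality is the fraction of dense grid points inside the
band, compared against the smoothed profile (the model is fitted to the
smoothed curve, so judging it against the raw points would mix smoothing
error into the score). The good-fit threshold is 0.8.

A gene is "no change" when its smoothed profile never leaves the band
around its own mean (boundary inclusive) — the band reuses the user's error
model rather than introducing a separate variance test. No-change genes are
excluded as regulators and targets; constant-synthesis genes only as
targets (their profiles still carry regulatory information when used as
inputs). Both screens run before any pair fitting, and results are cached
per gene, not per edge.

Multi-regulator fits (m > 1) are supported by the library but even modest
time series let an arbitrary regulator pair "explain" many genes, inflating
false positives; the CLI therefore fits pairwise only.

Human inspection is replaced by per-edge diagnostic plot files (regulator,
target with margin ribbon, fitted trajectory) and an overrides TSV
(regulator, target, new label) whose applications are marked
provenance = "manual" in the result table.

## Null profiles

Random regulator profiles are drawn from a zero-mean Gaussian process with
squared-exponential kernel. Hyperparameters are matched to the real
regulator by maximising the GP marginal likelihood of its centered smoothed
profile — this operationalises "similar magnitude and rate of change"
without manual tuning. Kernel bounds restrain the optimiser from the flat
large-variance/long-lengthscale ridge that smooth single-bump profiles
induce; the choice is harmless because draws are subsequently transformed:
absolute value (positivity, preserving the rate of change better than
exponentiation would) then a linear rescale to the reference profile's
mean. The rescale cancels the fitted variance, so effectively only the
lengthscale matters; calibration over 200 draws puts the mean per-draw
standard deviation within a factor 2 of the reference's. The defaults are
50 profiles for bacterial-style evaluations and 20 for the quicker
protocol used in the tests.

The null test refits every screened-surviving target once per random
profile substituted for the regulator. Acceptances under the true regulator
are the method's true positives on a trusted regulon; acceptances under a
nonsensical profile are false positives. Testing random profiles is
preferred over testing the regulon's complement, whose members may simply
be unannotated targets or coincidentally similar profiles.

## Synthetic data generator

The generator emulates a bacterial sigma-factor induction experiment: a
pulse-shaped regulator profile (base + amp·(t/τ)e^(1−t/τ), peaking at
τ = 3 time units), 13 samples over 12 time units, 20 targets integrated
from the full model with per-target parameters drawn from k₁ ∈ (1, 2),
k₂ ∈ (0.2, 0.7), |w| ∈ (2, 5) scaled by the regulator's maximum (30%
repressors), and a bias placed so the regulatory input crosses zero inside
the attained regulator range. The steepness and decay ranges keep response
timescales at or above roughly two sampling intervals — a deliberate
design constraint: the smoothing step provably cannot represent faster
features, so a fixture with near-step responses would measure sampling
adequacy, not fitter quality. Decoys: 5 constant profiles and 5
constant-synthesis trajectories started well away from their steady state.
Noise, when requested, is Gaussian with per-gene standard deviation equal
to a fraction of the gene's maximum, clipped at zero; the standard
evaluation fixture is noise-free.

What passing on this fixture does **not** show: robustness to measurement
noise structure (heteroscedastic, platform-specific), to replicate
averaging, to probe-level artifacts, to regulators acting in complexes
(which break the single-input model and visibly degrade performance on
eukaryotic data), or to dynamics faster than the sampling rate. Ground
truth is compared at the profile level only — β is not identifiable, since
vastly different parameter combinations can yield nearly identical
trajectories.

## Degenerate inputs and tie-breaks

Negative input expression is clipped to 0 with a warning. Duplicate network
edges are dropped with a warning; self-loops are rejected unless explicitly
allowed. SOFT files without a sample→time mapping get unit-spaced times in
column order, logged prominently. Equal annealing objectives resolve to the
lowest restart index. All-missing profiles, df exceeding usable points,
non-increasing header times, empty networks and overrides naming absent
edges are hard errors.

## Problem sizes used in the checks

The automated checks run the standard fixture (31 genes, 30 edges, 128
restarts), two full runs for replicability, one unregularized run, and a
20-profile null test — about three minutes on one CPU in total. Oracle
comparisons use dense resolution 1000 (Euler vs closed form) and 20 random
13-point profiles (spline vs normal equations).
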