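# Methods

## The problem

`coraldemog` estimates the demography of a size-structured, sessile
population — massive reef corals binned into diameter classes — from
irregular, sparse monitoring surveys, and projects its recovery under
density dependence, imported recruitment and recurrent pulse disturbance.
The setting it targets is a population observed in a handful of survey
years with uneven transect effort, for which a trajectory forecast is
nonetheless required.

## Stage classification

Colonies are grouped by planar diameter into an ordered set of size
classes. The default scheme has five bins: 0–5, 5–10, 10–20, 20–40 and
> 40 cm. Each class also carries a *representative diameter* used when
converting abundances into percent cover; the defaults are the bin
midpoints (2.5, 7.5, 15, 30 cm) and 50 cm for the open-ended top class.
Cover depends directly on these diameters, so they are an explicit,
configurable field of the scheme rather than a hidden constant.

## Preprocessing

Surveys from different years may use different numbers of transects.
Counts are first rescaled to a common reference effort (count ×
reference_transects / transects; e.g. a 3-transect year is doubled to
match 6-transect years). Because transects are not revisits of the same
colonies, absolute counts across years are not comparable even after
effort scaling; each annual vector is therefore converted to
*standardized proportional frequencies* — percent contributions summing
to 100. This discards the vector's magnitude but keeps its direction,
which is the quantity a transition-matrix fit actually uses (the
least-squares objective is scale-equivariant, and the package tests this
property explicitly).

Unsurveyed years inside the series are filled by regression imputation:
for each stratum and size class independently, an ordinary
least-squares line of value against year is fitted on a configurable
window of observed years and evaluated at the target years. Negative
fitted values are clipped to zero. The window is an explicit parameter
(default: the post-disturbance years only) because a mortality event is
a regime break — pre-event years would drag the line. Imputation runs
on proportional units, after effort scaling, matching the order of the
preprocessing chain; imputed rows are flagged and carry zero transects.

Small colonies are systematically under-detected on survey imagery
(roughly half of the 0–5 cm class is overlooked). The pipeline exposes a
single multiplicative correction hook for the smallest class
(`sc1_correction`, default 1.0 = off); no further detectability
modelling is attempted.

## Inverse estimation of the transition matrix

The population model is the linear stage-structured projection

    n(t+1) = M n(t),

where entry M[i, j] moves abundance from class j into class i over one
year. M is constrained by a *life-cycle graph*: stasis loops on the
diagonal, growth by exactly one class on the subdiagonal, shrinkage of
the largest class into the one below it (partial mortality), and
fertility entries in the first row from the two largest classes. The
default graph has 12 free parameters for five classes.

Given annual vectors n(0)…n(T), the matrix is estimated by constrained
least squares over the free arc parameters θ:

    minimize   Σ_t ‖n(t+1) − M(θ) n(t)‖²
    subject to θ ≥ 0,  and per column: stasis + growth + shrinkage ≤ 1.

Survival entries are probabilities, hence the column bound; fertility
entries are per-capita recruit contributions and are only required
nonnegative. This is a convex quadratic program. Implementation: the
system is normalized by the Frobenius norm of the design matrix (making
the estimate exactly equivariant under rescaling of the input vectors);
the unconstrained least-squares solution is accepted when feasible;
otherwise a trust-region interior-point method solves the QP and an
exact KKT re-solve on the identified active set recovers the optimum to
machine precision (interior iterates stop strictly inside the feasible
set, so activity is detected over a swept tolerance and the best
feasible candidate kept). The reported objective allows any alternative
backend to be validated; the test suite checks it against an
independently coded accelerated projected-gradient minimizer.

An *identifiability check* precedes every fit: T transitions of a
k-class series give kT equations; the fit refuses to run with fewer
equations than free parameters unless an explicit ridge penalty λ‖θ‖²
is supplied, in which case the minimum-norm solution is returned
(default λ = 0).

When is the inverse problem well-conditioned? The information in the
series lives in its *transient*: once a trajectory has collapsed onto
the dominant eigenvector, successive vectors are proportional and the
design matrix is nearly rank-one per row block. Estimation accuracy is
therefore much better for series started far from the stable stage
distribution — e.g. the small-class-dominated vectors that follow a
mass-mortality event, which is precisely the recovery regime this
method addresses. The recovery tests use such post-disturbance starting
vectors; with 5 % multiplicative observation noise and 10 transitions
the median relative error of nonzero entries is about 10 %, against
roughly 19 % from a near-equilibrium start.

## Hindcast verification

The fit window excludes the first vector n(0). Verification projects
forward from n(0) with the estimated matrix plus a deterministic
recruit sequence added to the smallest class after each matrix product
(default [5, 0, 0, 3, 0] over the first five steps), and compares the
predictions with the observed (and imputed) vectors by a pooled R²:
1 − SSE/SST over all class × year cells, with SST about the grand mean
of observed cells — a single R² per stratum, not a per-class average.

## Forward projection with density dependence

A fitted linear model grows exponentially; corals are limited by space.
For forecasting, M is split into a survival matrix S (stasis diagonal,
growth subdiagonal, shrinkage superdiagonal) and a fecundity matrix R
(first-row entries), S + R = M exactly, and a Ricker inhibition factor

    g_j = exp(−b_j n_j)

caps growth at high abundance. Defaults: b = 0.001 on the three largest
classes, zero on the two smallest. Each class is inhibited by its own
abundance (configurable in principle to total abundance; per-class is
the default because the coefficients are declared per class).

Where the factors act is genuinely ambiguous in this model family, so
the placement is a three-mode enum, recorded in all output metadata:

- `fertility_only` — only the first-row fecundity entries are damped;
- `inflow` (default) — row i of S + R is scaled by g_i, damping all
  additions into crowded classes; chosen as default because it yields a
  bounded equilibrium dominated by the large classes, the behaviour
  expected of a recovering massive-coral stand;
- `outflow` — column j scaled by g_j.

The population is treated as demographically *open*: each step adds to
the smallest class a Gaussian imported-recruitment draw with mean 25
and variance 25 (σ = 5), truncated at zero — negative recruitment is
impossible — plus any remaining deterministic recruit-sequence entry.
Draws are real-valued, not rounded, because the model state is a
continuous standardized abundance. One step of the forecast is

    n(t+1) = G(n(t)) ∘ (S + R) · n(t) + e₁ · max(0, N(25, 25)) + υ(t),

with ∘ the mode-dependent application of the factors. With b = 0 and a
purely deterministic recruitment spec this reduces bitwise to the
linear projection — a tested invariant, as is convergence of the
per-step growth factor to the dominant eigenvalue of S + R when
recruitment is removed. Eigen-analysis is otherwise deliberately not a
headline output: in an open population the dominant eigenvalue no
longer determines the rate of increase.

## Cover conversion and stabilization time

Abundance vectors convert to percent cover by summing per-class circle
areas: class j contributes 100 · n_j · π (d_j / 200)² / A with d_j the
representative diameter in cm and A the reference area in m² (default
300 m², six 50 × 1 m transects). Stabilization time is the first step t
at which cover stays within ± rel_tol of its local mean over a trailing
window [t, t + window].

## Pulse disturbances and ensembles

Disturbance events recur at uniform random intervals (default 10–20
years; waiting times are continuous uniform, cumulated, rounded to
whole years with a minimum spacing of one year) and kill a uniform
random fraction (default 0–100 %) of colonies in *every* size class —
no size selectivity by default. A disturbance is applied at the start
of its year, before that year's growth and recruitment; the order is a
convention and is recorded in output metadata.

Ensembles run many seeded realizations (default 500) and report the
mean cover trajectory with 5/50/95 % quantile bands; the ensemble mean
staying positive at the horizon is the persistence indicator. Seeding:
the master seed spawns two independent child streams per realization
(recruitment draws; disturbance schedule and kill fractions), so a
null-disturbance regime reproduces the undisturbed run bitwise under
matched seeds — a tested invariant — and any realization can be rerun
in isolation.

The recruitment sweep reruns the ensemble (without disturbance) over a
set of imported-recruitment means, averages total cover over the last
20 steps and across replicates, and fits an ordinary least-squares line
of long-run cover against recruitment mean. In an open population with
Ricker-damped demography the relationship is close to linear with
positive slope (line R² above 0.95 in the shipped configuration).

## Synthetic data: what it emulates and what it does not

The generator draws a ground-truth matrix on the life-cycle graph
(per-column total survival in 0.7–1.0 × cap, split by a stasis-weighted
Dirichlet — weights 4 stasis / 2 growth / 1 shrinkage — because a
massive coral growing ~1 cm yr⁻¹ against 5–20 cm bin widths persists
far more often than it advances a class; fertility uniform in
0.05–0.3, i.e. weak local recruitment), projects a known trajectory,
and degrades it like a real video-transect survey: effort scaling per
year (default 3 transects in the first post-disturbance year, 6
thereafter), missing survey years (default two), binomial thinning of
the smallest class at detection probability 0.5 (a deterministic mode
exists for exact tests), optional Poisson count noise, and rounding to
whole colonies.

It does *not* emulate: spatial structure or transect placement,
multi-species interaction, size-dependent disturbance mortality,
observer variability beyond the SC1 thinning, or temporal variation in
the true transition rates. Passing recovery tests therefore show that
the estimator works when the population really follows a fixed
transition matrix with stationary observation error — they do not show
robustness to regime shifts or non-stationary detectability.

## Numerical choices

- QP: constraint violation ≤ 1e−8 on entry to the matrix object
  (survival column sums are checked at 1e−9); objective recovered to
  machine precision by the KKT polish; deterministic for a fixed
  configuration.
- Proportional vectors sum to 100 within 1e−9 and the operation is
  idempotent at that tolerance; an all-zero vector raises an error
  rather than yielding NaN.
- Degenerate inputs: an all-zero source series, mismatched dimensions,
  zero transects, nonpositive reference area and out-of-range kill
  fractions all raise explicit errors.
- All CSV readers parse floats in round-trip mode so that
  write-then-read is lossless.
- Counts are real-valued internally; rounding to whole colonies happens
  only in survey emulation output.

## Problem sizes in the shipped tests and acceptance script

Recovery statistics use 100 seeded replicates of 10-transition series;
the QP cross-check uses 20 random 3-class instances; disturbance
persistence uses 500-realization ensembles over a 100-year horizon
(three master seeds in the test suite); the recruitment sweep uses
means {0, 10, 25, 50} with 100 replicates each. These sizes give stable
Monte-Carlo summaries (the ensemble-mean standard error is well under
the effects being checked) while keeping a full run in the order of a
minute.

## Known limitations

- The linear imputation model is adequate only for short gaps inside a
  monotone regeneration phase; it will misbehave across regime breaks,
  which is why the window is explicit.
- Relative (proportional) units mean absolute abundance is never
  predicted — only composition and derived cover over the reference
  area.
- The per-area normalization of recruitment (recruits per m² versus
  recruits per transect set) is exposed as configuration rather than
  fixed; published per-area recruit densities cannot be reproduced from
  the per-step Gaussian alone without choosing that convention.
- Shrinkage is modelled only from the top class into the one below;
  bleaching-style shrinkage cascades across several classes are outside
  the default graph (though the structure type admits per-class
  shrinkage arcs one step down).
- Disturbance mortality is deterministic multiplication of abundances;
  a binomial survivor draw would add demographic stochasticity at low
  abundance and is a possible extension.
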