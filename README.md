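# coraldemog

Stage-structured demography for reef corals observed through sparse,
irregular monitoring surveys. The package estimates a size-class
transition matrix from a short series of annual size-frequency vectors,
verifies it by hindcast, and projects population and percent-cover
trajectories over a century under density dependence, stochastic imported
recruitment and recurrent pulse disturbance.

It is written for reef ecologists and conservation modellers who have the
kind of data real monitoring programmes produce — a few survey years,
uneven transect effort, gaps, under-detected recruits — and who still
need a defensible trajectory forecast.

## The model

Colonies are binned into diameter classes (default SC1: 0–5 cm … SC5:
> 40 cm). Annual dynamics follow a Leslie-type projection

    n(t+1) = M n(t) + υ(t),

where M is constrained by a life-cycle graph — stasis loops, growth by
one class, shrinkage of SC5 into SC4, fertility into SC1 from SC4/SC5 —
and υ adds recruits to the smallest class. M is *inversely* estimated
from the observed vectors by constrained least squares (Wood's method):

    min Σ_t ‖n(t+1) − M n(t)‖²   s.t.  M ≥ 0 on allowed arcs,
                                       column survival sums ≤ 1,

a convex QP solved to machine precision. For forecasting, M = S + R is
split into survival and fecundity, growth is damped by Ricker factors
exp(−b_j n_j) (default b = 0.001 on SC3–SC5), and the population is
treated as demographically open: each year SC1 receives a zero-truncated
Gaussian draw N(25, 25) of imported recruits. Disturbance scenarios kill
a uniform-random fraction of all classes at uniform-random 10–20-year
intervals; ensembles of seeded realizations summarize persistence via
the mean cover trajectory. See `docs/methods.md` for the full account.

## Worked example

Generate a known truth, degrade it into a survey-like table, and run the
whole chain — effort standardization, proportional scaling, imputation,
inverse fit, hindcast, disturbed forecast:

```python
import numpy as np
import coraldemog as cd

structure = cd.LifeCycleStructure.default_graph()
scheme = cd.SizeClassScheme()

truth_matrix = cd.generate_true_matrix(structure, survival_cap=0.95, seed=42)
truth = cd.GroundTruth(matrix=truth_matrix,
                       initial_vector=np.array([60., 30., 20., 10., 5.]),
                       recruitment=cd.RecruitmentSpec.deterministic((5, 0, 0, 3, 0)))
series = cd.simulate_series(truth, 4)
obs = cd.ObservationModel()   # 3 transects in 2010, 6 later; 2011/12 missing
survey = cd.emulate_survey(series, obs, scheme, seed=42, years=range(2010, 2015))

std = cd.standardize_effort(survey, reference_transects=6)
prop = cd.to_proportional_frame(std)
imp = cd.impute_missing_years(
    prop, cd.ImputationConfig(target_years=(2011, 2012),
                              window_years=(2010, 2013, 2014)))

vectors, years = cd.series_vectors(imp, "2m")
report = cd.solve_wood(vectors[1:], structure)   # hold out t = 0
print(f"fit: {report.equations} equations, {report.unknowns} parameters, "
      f"RSS = {report.rss:.2f}")
pred = cd.project_linear(report.matrix, vectors[0], 4,
                         cd.RecruitmentSpec.deterministic((5, 0, 0, 3, 0)))
fit = cd.hindcast_fit(pred[1:], vectors[1:])
print(f"hindcast R^2 = {fit.r_squared:.3f}")

fc = cd.ForecastConfig(decomp=cd.decompose(report.matrix),
                       dd=cd.DensityDependence(),
                       n0=vectors[0], recruitment=cd.RecruitmentSpec(),
                       scheme=scheme, horizon=100)
ens = cd.run_ensemble(fc, cd.DisturbanceRegime(), realizations=500, master_seed=7)
print(f"mean cover at year 100 = {ens.mean_cover[-1]:.2f}% "
      f"(persistent: {ens.persistent})")
```

Output:

```
fit: 15 equations, 12 parameters, RSS = 53.96
hindcast R^2 = 0.958
mean cover at year 100 = 0.24% (persistent: True)
```

Reading it: four annual vectors give 15 equations for the 12 free arcs
of the life-cycle graph, so the fit is (barely) overdetermined; the
residual sum of squares is in squared proportional units. The hindcast
R² pools all class × year cells — 0.958 means the matrix solved from
t = 1…4, projected from the held-out t = 0 vector with the recruit
sequence [5, 0, 0, 3, 0], explains ~96 % of the observed variation.
The ensemble mean cover staying positive at year 100 under random
10–20-year disturbances killing 0–100 % of colonies is the persistence
verdict; its magnitude is relative (the initial vector is a
proportional composition over a 300 m² reference area), so the sign and
trend carry the message, not the absolute percentage.

The same chain is available from the shell:

```bash
coraldemog simulate-data --out survey.csv --seed 42
coraldemog impute --survey survey.csv --out prepped.csv --window 2010-2017 --targets 2011,2012
coraldemog solve --survey prepped.csv --stratum 2m --out matrix.csv
coraldemog forecast --matrix matrix.csv --survey prepped.csv --stratum 2m \
    --recruit-mean 25 --recruit-var 25 --steps 100 --seed 7 --out traj.csv
coraldemog run --config run.yaml    # full pipeline with manifest
```

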