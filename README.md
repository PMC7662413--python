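# mortsurv

Bayesian spatio-temporal surveillance of small-area mortality and life
expectancy.

`mortsurv` is for epidemiologists and public-health analysts who monitor
mortality across administrative areas and want to answer two questions:
how is life expectancy evolving across levels of socioeconomic
deprivation, and which individual areas show **unexplained** excess
mortality — higher than their age structure, deprivation level, location
and calendar year would predict? The second question matters because an
area flagged after accounting for deprivation points to local,
potentially actionable causes rather than poverty alone.

## The model

Death counts by area *i*, age group *j* and year *t* (sexes analysed
separately) are modelled as

```
y_ijt ~ Poisson(λ_ijt · Pop_ijt)
log λ_ijt = a0 + α_j + γ_i + ζ_t + φ_d(i) + ω_it + δ_ij + κ_jt + ν_d(i)t
```

where *d(i)* is the deprivation decile of area *i* (1 = most deprived).
Smoothness is encoded through the priors: first-order random walks (RW1)
on the age, year and decile main effects α, ζ, φ and on the time profiles
of the age–time (κ) and decile–time (ν) interactions; an intrinsic
conditional autoregressive (ICAR) prior on the spatial effect γ, whose
precision structure is the adjacency-graph Laplacian; exchangeable normal
priors on the unstructured space–age (δ) and space–time (ω) interactions;
a vague normal prior on a0 and Gamma(1, 0.01) hyperpriors on all eight
precisions. Inference is Metropolis-within-Gibbs MCMC with conjugate
precision updates and vectorized single-site Metropolis moves, with
sum-to-zero constraints maintained by mean transfers that leave the
likelihood invariant (see `docs/methods.md`).

Two downstream products are computed from the posterior draws:

- **Life expectancy.** Each draw's age-specific rates are pushed through a
  Chiang-style abridged life table (q_j = n_j m_j / (1 + n_j (1−a_j) m_j),
  open interval closed as L = l/m) to give e0 per area-year and, with
  population-weighted rate pooling, per decile-year, summarized as
  posterior means with 95% credible intervals; period gaps are reported
  in days (×365.25).
- **Detection.** The exceedance probability p_it = P(ω_it > 0 | data) is
  the fraction of draws with positive space–time interaction. An
  area-year is flagged when p_it strictly exceeds 0.95 within the
  detection window (default 2012–2018). ω is the natural surveillance
  target: it absorbs exactly the mortality that the structured terms —
  including deprivation — cannot explain.

Because registry extracts cannot be redistributed, the package ships a
first-class synthetic-data generator that draws every component from its
prior on a lattice geography, assigns spatially smooth deprivation
deciles, and can inject known area-year anomalies — so the whole pipeline
is testable end to end with ground truth.

## Worked example

```python
import mortsurv as ms

spec = ms.SimulationSpec(anomalies=[(42, 6, 0.3)], seed=7)  # desk-scale default
data, truth = ms.simulate_dataset(spec)
graph = ms.make_lattice_graph(spec.rows, spec.cols)

config = ms.ModelConfig(n_chains=2, burn_in=400, n_iter=500, seed=5)
samples = ms.fit(data, graph, config)

report = ms.convergence_report(samples).set_index("parameter")
print(f"draws: {samples.n_draws}, R-hat(a0): {report.loc['a0','rhat']:.3f}")

lt = ms.AbridgedLifeTableConfig.from_age_groups(data.age_groups)
e0 = ms.decile_year_e0(samples, data, lt)
for d in (1, 10):
    row = e0[(e0.decile == d) & (e0.year == 2018)].iloc[0]
    print(f"decile {d:2d}, 2018: e0 = {row.e0_mean:.2f} "
          f"[{row.e0_low:.2f}, {row.e0_high:.2f}] years")

det = ms.detect_from_samples(samples)  # threshold 0.95, window 2012-2018
print(det.flagged_table().head(3).to_string(index=False))
```

Output (about 5 seconds on one CPU):

```
draws: 1000, R-hat(a0): 1.002
decile  1, 2018: e0 = 77.68 [76.11, 79.25] years
decile 10, 2018: e0 = 140.86 [136.84, 145.30] years
area  decile  year  exceedance_probability
A017       5  2012                   0.990
A042       1  2015                   1.000
A049       6  2015                   0.954
```

The injected anomaly — a +0.3 log-rate shift in area 42 in 2015 — is
flagged with exceedance probability 1.000; the remaining flags are cells
whose (randomly drawn) true ω happens to be confidently positive, at a
rate consistent with the measured false-flag rate of about 1–2% under a
null simulation. The e0 values are internally coherent but not comparable
to real populations: the synthetic age effect is a random-walk draw on a
10-group grid, not an observed old-age mortality schedule, so survival in
the open-ended age interval dominates. Interval estimates, coverage and
detection behave as they would on real data; the absolute e0 level does
not (see `docs/methods.md`).

A command-line interface mirrors the library: `mortsurv simulate | fit |
lifetable | detect | report | run | fixtures`, with a single YAML config
driving the full `run` pipeline and a JSON manifest (seeds, SHA-256
digests, per-stage status) written per run.

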