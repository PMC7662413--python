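# Methods

## Model

Deaths are Poisson counts on a dense (area, age group, year) grid for one
sex, with exposure in person-years:

    y_ijt ~ Poisson(λ_ijt · Pop_ijt)
    log λ_ijt = a0 + α_j + γ_i + ζ_t + φ_d(i) + ω_it + δ_ij + κ_jt + ν_d(i)t

Deprivation enters through a decile label per area, d(i) ∈ {1..10}; the
decile subscript is therefore a deterministic function of the area and
the data are stored per (i, j, t). Cells with zero population are kept in
the tensors but contribute zero log-likelihood; a cell with deaths but no
population is rejected at load time.

Priors encode smoothness where rates are known to vary slowly:

| component | meaning | prior |
|---|---|---|
| α_j | age main effect | RW1, precision τ_α |
| ζ_t | year main effect | RW1, τ_ζ |
| φ_d | decile main effect | RW1 across deciles, τ_φ |
| γ_i | spatial main effect | intrinsic CAR (graph Laplacian), τ_γ |
| κ_jt | age–time interaction | RW1 over t per age group, shared τ_κ |
| ν_dt | decile–time interaction | RW1 over t per decile, shared τ_ν |
| ω_it | space–time interaction | exchangeable normal, τ_ω |
| δ_ij | space–age interaction | exchangeable normal, τ_δ |
| a0 | intercept | normal(0, 10⁶) |
| all τ | precisions | Gamma(shape 1, rate 0.01) |

The RW1-on-interactions choice is resolved as a random walk **over time**
within each age group (κ) and each decile (ν): time is the shared index
of both terms and smooth temporal divergence from the main effects is
what the interactions exist to capture. The CAR prior is the intrinsic
(improper) variant with a sum-to-zero constraint, the standard choice in
disease mapping; the detection statistic reads ω, not γ, so a proper-CAR
alternative would change little downstream. The Gamma(1, 0.01)
hyperpriors are the weakly-informative conjugate default of the disease
mapping literature and are configurable.

### Identifiability constraints

Intrinsic priors and the presence of every main effect leave flat
directions; the minimal centering set used here is: Σα = Σγ = Σζ = Σφ = 0;
ω and δ centered jointly (grand mean zero); κ and ν doubly centered (row
means over t and column means over their first index both zero). After
every MCMC sweep each component is re-centered and the removed means are
transferred up the hierarchy — interaction row/column means into the
matching main effects, main-effect means into a0 — so that the linear
predictor, and hence the likelihood, is *exactly* unchanged by the
operation. For the improper RW1/ICAR components the transfer moves along
directions of zero prior curvature; for the exchangeable components the
grand mean is weakly pinned by the prior and the transferred quantity is
O((nτ)^-1/2), negligible at the sizes used. Uncentered variants would
redistribute mass between main effects and interactions without changing
fitted rates.

### Sampler

Metropolis-within-Gibbs:

- **Precisions:** conjugate Gamma full conditionals,
  τ ~ Gamma(a + k/2, b + q/2) with q the component's quadratic form and k
  the dimension of its constrained support (n−1 for RW1 length n, I−c for
  ICAR with c components, (J−1)(T−1) for doubly-centered RW1 matrices,
  n−1 for grand-mean-centered exchangeable fields).
- **Gaussian fields:** vectorized single-site random-walk Metropolis.
  Because each data cell (i, j, t) involves exactly one element of each
  field, the likelihood factorizes over field elements; elements that are
  also prior-independent are proposed and accepted simultaneously. For
  exchangeable fields that is the whole field at once; for RW1-structured
  components an odd/even schedule over the walk index; for the ICAR field
  a greedy graph coloring. Acceptance uses the exact local change
  ΔlogL = Y·d − M·(e^d − 1) with Y and M the death-count and
  Poisson-mean totals over the element's cells, plus the single-site
  prior change 2d(Sx) + S_kk d² under structure matrix S.
- **Adaptation:** one step size per field, Robbins–Monro toward 0.44
  acceptance, frozen after burn-in so the stationary distribution is
  untouched.
- The running Poisson-mean tensor is updated multiplicatively on accepted
  moves and recomputed from scratch every 200 sweeps to stop round-off
  drift. Chains are seeded via `SeedSequence.spawn`, so fits are bitwise
  reproducible for a given seed and chain count.

Convergence is reported as split-chain rank-normalized R-hat and bulk
ESS (via ArviZ) for a0, every precision, and each field's cross-element
standard deviation — the field *mean* is pinned to zero by the
constraints and carries no information, so the spread is the natural
scalar summary. Rows with R-hat > 1.1 are flagged.

## Life tables

e0 uses the Chiang abridged construction on the dataset's age grid:
q_j = n_j m_j / (1 + n_j (1−a_j) m_j) for closed intervals (a_j = 0.5,
infant group a = 0.1), q = 1 in the open-ended interval, person-years
L_j = n_j l_j (1 − (1−a_j) q_j) — the algebraically identical, numerically
stable form of n_j(l_{j+1} + a_j d_j) — and L = l/m for the open interval.
Where a very large rate would push q past 1 it is clamped and L reverts to
the defining identity L = d/m, which keeps e0 continuous and strictly
decreasing in every rate. Rates are floored at 1e-10 to guard the open
interval division; a_j and the interval widths are configurable.
e0 is computed per posterior draw (per area-year from the draw's rates;
per decile-year from population-weighted pooled member rates) and
summarized afterwards, so credible intervals propagate the full joint
posterior. Period gaps use paired two-year means (default {2012, 2013} vs
{2017, 2018}) differenced within draw and converted to days at 365.25.

## Detection

p_it = (number of draws with ω_it > 0)/S, strict inequality (a draw at
exactly zero does not count). Flagging requires p_it > threshold
(strictly — a probability of exactly 0.95 at the default threshold is not
flagged) and the calendar year inside the window. The default window
2012–2018 targets the period of stalled life-expectancy improvement but
is a configurable analysis choice, keyed by calendar-year label rather
than index. No multiplicity adjustment is applied to the exceedance
probabilities. A sensitivity comparison runs detection under two fits of
the same data that differ only in the decile assignment (e.g. two
vintages of a deprivation index) and classifies each area-year as
both / only-A / only-B / neither.

## Synthetic data

The generator draws every component from the prior the model assumes:
α, ζ, φ via cumulative-sum RW1 draws re-centered to zero; γ by exact
ICAR sampling through the eigendecomposition of the lattice Laplacian
(feasible to a few hundred areas; disconnected graphs are refused); κ
and ν as independent per-row RW1s over time, column-centered; ω and δ
i.i.d. normal, grand-mean centered. Anomalies are additive shifts on ω
applied *after* centering, so the detection target carries exactly the
injected signal. Deciles are assigned by ranking a sampled ICAR surface
and cutting into equal-count groups (sizes differ by at most one),
giving the spatial clustering real deprivation shows. Populations are a
deterministic peaked age-weight vector times a per-area scale with ±20%
uniform jitter.

Desk-scale defaults (the conditions every simulation-based test uses):
10×10 lattice, 10 age groups, 10 years ending 2018, 10 deciles, ≈10⁴
person-years per area-age cell, a0 = log 0.01, and precisions τ_α = 2,
τ_ζ = 100, τ_φ = 25, τ_γ = 25, τ_ω = τ_δ = 2000, τ_κ = τ_ν = 400. These
give a strong age gradient, a ≈0.6 log-scale deprivation range (mortality
ratio ≈1.8 most-to-least deprived), spatial variation ≈0.2, a visible
year trend, and small unstructured interactions (sd ≈0.02) so that an
injected +0.3 shift is an order of magnitude above background — the
regime in which exceedance surveillance is meant to operate. No published
hyperparameter values exist for the fitted precisions; these are this
package's choices.

**What the generator does not emulate:** real geography and contiguity
(a lattice stands in for administrative boundaries), migration,
a realistic old-age mortality schedule (the age effect is a random-walk
draw, so absolute e0 levels on synthetic data are grid- and
draw-dependent and can far exceed human values), within-area deprivation
heterogeneity, and decile reassignment over time. Passing tests
therefore demonstrate correct inference and detection *given the model's
assumptions*, not robustness to their violation.

## Numerical and design choices

- Graph file format: the 1-based "N / node degree neighbors" plain-text
  dialect, symmetric-or-error.
- Age labels serialized "0-0", "1-4", …, "90+"; grids must start at
  [0, 1), be contiguous, and end open-ended.
- MCMC defaults: 2 chains, 500 burn-in, 500 kept, thinning 1; at least
  100 kept draws per chain are required. Test and acceptance runs use
  single chains of 400 + 600 at desk scale — a fit takes ~1 s — and 20
  seeded replicates for coverage/operating-characteristic estimates.
- A dataset with a single area is rejected (the spatial prior is
  undefined on one node), as is a disconnected adjacency graph.
- Divergence is reported explicitly: non-finite Poisson means abort the
  chain, as does total rejection of every intercept proposal.
- e0 summaries use equal-tailed 2.5/97.5% quantiles across draws.

## Known limitations

- Single-site Metropolis mixes slowly for strongly correlated
  high-dimensional blocks; the per-field spread summaries can show
  R-hat > 1.1 on short chains even when scalar targets (a0, precisions,
  ω cells) have converged. Longer chains or multiple chains resolve this.
- The exchangeable-field centering is exact only up to the O((nτ)^-1/2)
  prior term discussed above.
- The false-flag rate under a null simulation is prior-dependent (≈1–2%
  at the defaults) and is asserted in tests only as an upper bound (<5%).
- Detection looks for unusually *high* mortality only; low-mortality
  outliers (ω < 0) are out of scope, as are cause-specific analyses.
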