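# Methods

## The model

`huffgap` implements a Huff-type (gravity) spatial-interaction model of
facility choice, adjusted so that attraction variables observed for only a
subset of facilities can still be used. The expected admissions from demand
area *i* to facility *j* are

```
V_ij = AA_ij / Σ_j AA_ij × V_i

AA_ij = [ (1 − B_j) + BM · B_j · Π_f Á_f[j]^γ́_f ] · Π_f A_f[j]^γ_f · exp(−D_ij · DF)
```

* `A_f` — attraction variables observed for **every** facility (here: bed
  counts), with exponents `γ_f`;
* `Á_f` — attraction variables observed only where the binary availability
  flag `B_j = 1` (here: a reputation score), with exponents `γ́_f` (the
  reputation exponent is the *effect size* α);
* `D_ij` — great-circle distance in km (haversine, Earth radius 6371 km),
  with exponential decay rate `DF ≥ 0` per km;
* `BM ∈ (0, 1]` — the *benchmark* parameter. Facilities without reputation
  data get a bracket of 1; facilities with data get `BM · Π Á^γ́`. Since the
  partial variables are positive and utility-increasing, any observed value
  would otherwise advantage the observed group; `BM` scales their utility
  down so both groups compete on a level field. Implicitly the unobserved
  facilities are treated as having an average value of the partial variable,
  without that average ever being specified.

The fraction is the Huff market-share rule: utility of *j* relative to the
summed utility of all alternatives for area *i*. Shares are multiplied by
the area market size `V_i` to give expected volumes; facility totals are
`Σ_i V_ij`.

Assumptions: multiplicative power utility in positive attraction variables,
exponential distance decay on great-circle (not network) distance,
independent multinomial choice within each area, and a single fixed
availability partition (gaps are structural, not random per observation).

### Numerical notes

Utilities are computed in log space and shares via a log-sum-exp
normalization, so extreme exponents proposed during global optimization
cannot overflow; stored numerators are the literal `AA_ij`. Partial-variable
entries where `B_j = 0` may hold placeholders but can never influence the
result (the bracket is exactly 1 there; property-tested). With homogeneous
availability (all zeros or all ones) `BM` multiplies one entire group and
cancels in the shares; it is therefore pinned at 1 instead of being left as
a flat objective direction.

## Estimation

The model is not linearizable in its parameters, so it is fitted without
transformation by simulated annealing (`scipy.optimize.dual_annealing`)
over box bounds, with an L-BFGS-B local refinement (max 100 iterations) per
annealing round; the bound-feasible parameter vector with the lowest
objective ever evaluated is returned. The objective is the mean squared
error between observed and predicted facility-level totals (mean rather
than sum — the minimizer is identical, the scale is per-facility).
Non-finite proposals are rejected. Fits are deterministic given the
configured seed.

Defaults: 2000 annealing iterations per fit; desk-scale studies use 200,
which on the synthetic markets below reaches the same optimum as 2000 in
every spot check. Bounds: `γ, γ́ ∈ [0, 3]`, `DF ∈ [0, 1]` per km,
`BM ∈ [1e-4, 1]` — wide margins around realistic hospital-market values
(size exponent near 0.92, decay well below 1/km). Annealing starts at the
bound midpoints for reproducibility.

The *control model* drops every partial variable (availability zeroed,
`BM = 1`): the classic size-only gravity model one is forced into when
incomplete variables are discarded.

## Synthetic markets

The generator emulates a regional hospital market (the scale is modelled on
Flanders: ~89 campuses serving ~9000 statistical sectors, with total yearly
admissions in the hundreds of thousands), since real geography and
admission records are not shipped:

| parameter | default | rationale |
|---|---|---|
| extent | lat 50.7–51.5, lon 2.6–5.9 | pairwise distances ~0–240 km, Flanders-like |
| facilities × areas | 30 × 1000 | desk scale; full scale is a config choice |
| bed counts | lognormal, median 300, σ=0.6, floor 30 | realistic inter-hospital size ratios |
| market sizes | lognormal shares of 600,000 total | facility-level multinomial noise ≈ 1%, matching the accuracy floor at full availability |
| reputation | Normal(10, 2.8), floor 0.01 | stated score distribution; floor keeps the power utility defined (hits ~2·10⁻⁴ of draws) |
| size exponent | 0.92 | realistic value for hospital markets |
| true decay | 0.15 per km | plausible catchment sizes; never stated in the source conditions, configurable |

Demand is one multinomial draw per area: `V_i` admissions over the
facilities with the model's choice probabilities as weights, so per-area
totals are conserved exactly. The *truth* always has reputation for every
facility; incomplete availability is applied afterwards to what the
estimator sees.

What the generator does **not** emulate: real spatial clustering of
facilities and population, network travel times, localized (area-specific)
reputation, correlation between size and reputation, and non-gravity choice
behaviour. Passing tests therefore show that the estimator recovers the
data-generating process *when the gravity structure holds*, not that real
admission flows follow it.

## The simulation study

`run_grid` sweeps effect sizes (default 0.1–1.3, step 0.2) × availability
fractions (0.05–1.00, step 0.05) × 5 runs = 700 fits, plus one control fit
per (effect size, run). Noise between cells is limited with common random
numbers: geography, bed counts and reputation are drawn once per study; the
demand realization is shared by every availability level within one
(effect size, run); availability masks are nested in p (drawn once per run
as a priority order). Seeds derive from the base seed and the
(effect-size, run) indices only — never from p.

Evaluation metrics: facility-level MAPE (zero-volume facilities excluded
with a warning), split into the in-group (`B_j = 1`) and out-group; the
Breusch–Pagan test (F form: squared effect-size errors regressed on p) for
whether estimation-error variance scales with availability; and right-tailed
Student-t upper bounds, `mean + t_{0.95, n−1}·sd/√n`, over replicate runs
(t = 2.13 at n = 5). The headline improvement statistic is
`100 · (control − in-group MAPE) / control` at 25% availability, averaged
over effect sizes.

## Design choices where the design was open

* **MSE over facilities, not (i, j) cells** — the error is defined at the
  facility level; area-level fitting would weight the objective toward the
  many small areas.
* **Rounding of the in-group count** — `round(p·J)` half-up; nested masks by
  default so availability sweeps are comparable.
* **Replicates** — 5 per cell (configurable).
* **Single annealing run per fit** — no restarts; the seed is the only
  source of optimizer randomness.
* **No closed-form BM(α)** — although the fitted benchmark is tightly,
  monotonically coupled to the effect size, BM is kept as a free parameter
  whenever availability is mixed.

## Known limitations

* At desk scale the in-group is small (8 facilities at p = 0.25, 2 at
  p = 0.05), so the two in-group-specific parameters (α, BM) can nearly
  interpolate the in-group totals; in-group MAPE at low p is therefore
  optimistic relative to larger markets, while out-group and control
  accuracy are scale-stable.
* No uncertainty quantification per fit (no standard errors); replicate
  spread over seeded runs is the only variability measure.
* Exponential decay only; no power-law kernel, no additive utilities.
* Single partial variable exercised by the harness (the core model accepts
  any number).
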