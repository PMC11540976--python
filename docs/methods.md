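# Methods

This note documents the models, defaults and design choices behind the
pipeline, and what the synthetic experiments do and do not establish.

## Study design being emulated

A staggered-adoption policy evaluation on an aggregate panel: 151
townships observed over six two-year windows (P2007 … P2018, labelled by
first calendar year), with the policy adopted at the village level over
2015–2019.  The estimation panel uses P2013 (pre-policy base), P2016 and
P2018; the three earlier windows serve pre-trend diagnostics.  2015, the
pilot year, belongs to no calendar window but pilot enrollees count
toward cumulative enrollment from P2016 on.

## Exposure

Township exposure in window t is `enrolled villages / villages > 0.5`
evaluated with exact rational arithmetic (a township at exactly 50% is
unexposed).  Enrollment is cumulative and the policy permanent, so
exposure is absorbing and each township has a single adoption cohort —
the structure the group-time DiD estimator requires.  The 70/30
sensitivity definition classifies `>70%` as exposed and `<30%` as
unexposed and drops townships whose **final (2019)** fraction lies in
[0.30, 0.70]; the per-period alternative was rejected because exclusion
must define a single analysis set.

## Rates

Direct standardisation: `rate = 10^5 · Σ_s w_s · events_s / pop_s` with
reference weights `w_s` renormalised over the subgroup's strata.
Populations are window denominators (mean yearly population), so rates
are events per 100 000 persons per two-year window.

- Age bands: the main analysis uses {35–64, 65+} × sex, collapsed from
  the fine bands {35–49, 50–64, 65–79, 80+} × sex used in sensitivity
  analyses.  The fine bands are the generator's native strata.
- The packaged reference weights (21/15.5/10/3.5% per sex across the
  four bands) are a synthetic stand-in for the 2010 reference
  population, which is not published; only relative weights matter for
  the estimators.
- Natural logs throughout, so `(exp(coef) − 1)·100` is the percent
  change in incidence.
- Zero-rate cells (possible in sparse sex–age subgroups) receive a
  continuity floor of 0.5 pseudo-events over the cell's population
  before logging, with a warning; `floor_events=None` turns this into an
  error.
- November pooling (heating-season alignment) maps the window labelled
  `Py` to Nov 1 (y−1) – Oct 31 (y+1).  Read literally as "start in
  November of the first year" the windows would leave a gap after the
  excluded pilot year and overrun the final year of data; the
  implemented windows keep the policy-anniversary alignment that
  motivates the sensitivity analysis.  Monthly input is required.

## Spatial smoothing (BYM)

Per window and subgroup: `O_i ~ Poisson(E_i exp(θ_i))`,
`θ_i = α + u_i + v_i`, with `E_i` the internally standardised expected
count (pooled stratum rates × stratum populations).  `u` is intrinsic
CAR on the adjacency graph with a sum-to-zero constraint re-imposed
every sweep (the subtracted mean folds into α); `v` is iid normal.
Hyperpriors are half-normal(1) on both random-effect SDs — weakly
informative on the log-rate scale, where township relative risks rarely
exceed ±50% — and N(0, 10²) on α.

Sampler: random-walk Metropolis within Gibbs.  Graph colouring makes
all conditionally independent `u_i` update in one vectorised step;
`v` updates fully in parallel; SDs move on the log scale.  Per-site
step sizes adapt toward 44% acceptance during burn-in only, so the
post-burn-in chain is a fixed Markov kernel.  Defaults: 2 chains × 6000
iterations after 2000 burn-in, thinned by 2 → 6000 retained draws.
Split-R̂ and effective sample size (via arviz) are attached for α, the
SDs and a few θ components; R̂ > 1.1 flags `converged: False` with a
warning rather than failing — the exported θ components mix much faster
than the weakly identified variance split between `u` and `v`.

Exported draws are `θ_i + log(reference rate)`: the smoothed relative
risk mapped onto the incidence scale (indirect standardisation).  In
the generator this coincides with direct standardisation because
stratum rates are proportional across townships; with strongly
non-proportional age-specific risks the two scales can diverge, which is
a known limit of any single-θ spatial summary.

A bypass mode supplies draw banks without MCMC: stratum counts are
re-drawn Poisson around the observed counts and re-standardised
(`resample=True`), or repeated verbatim (`resample=False`, zero-variance
draws that collapse the propagation to the deterministic single-run
analysis).  The bypass is used by the replicate-heavy validation
experiments; the BYM model is validated separately.

## Difference-in-differences

For cohort g at window t ≥ g with outcome change
`ΔY_i = Y_{i,t} − Y_{i,P2013}`:

- unadjusted: `ATT(g,t) = mean_T ΔY − mean_C ΔY`;
- adjusted (doubly robust): with logistic propensity `p̂(X)` for
  membership in g versus the control set and linear outcome regression
  `m̂(X)` of ΔY on X fitted among controls,
  `ATT = mean_T[ΔY − m̂] − Σ_C w_i [ΔY_i − m̂_i]`, weights
  `w_i ∝ p̂_i/(1 − p̂_i)` normalised over controls.  Consistency needs
  only one of the two nuisance models correct; both are fitted on
  standardised covariates (an affine reparameterisation) for numerical
  stability at n ≈ 150.

Controls default to the never-exposed cohort (stable across t);
`not_yet` is available.  Anticipation is set to zero windows.
Propensities are trimmed to [0.001, 0.999] with a logged count;
coefficients beyond ±50 on standardised covariates are treated as
complete separation and raise.

Inference is influence-function based: each estimator stores per-township
ψ with mean exactly zero and `SE = sd(ψ)/√n`.  The two arms of ψ carry
HC2-style factors `√(m/(m−1))` per group so that, in the unweighted
case, the variance reduces to the unbiased Welch form — without this the
17-township cohort's variance is visibly underestimated and the joint
test over-rejects.  ψ omits the first-stage estimation-effect terms of
the propensity and outcome models; per-run analytic SEs are what the
draw-level propagation consumes, and the calibration experiments below
check the resulting error rates directly.

Aggregation: event-time effects θ(e) weight ATT(g,t) by cohort size
within each e (e = 0: "<2 years", e = 1: "2–4 years"); the overall ATT
weights θ(e) by the number of treated townships contributing to each e.
Influence functions combine linearly on the union township set, each
component rescaled by `n_union/n_component` so every aggregate satisfies
`est − truth ≈ mean(ψ)` on the union sample.  The joint equality test is
a Wald statistic on contrasts against the ψ covariance, reported as F
with (k−1, n−k) reference — the degrees of freedom are a reporting
convention, not an exact distributional result.  Heterogeneity between
subgroups uses `z = (ATT_A − ATT_B)/√(SE_A² + SE_B² − 2Ĉov)` with the
covariance from paired ψ on the shared panel (assumed zero, with a
logged caveat, when influence functions are unavailable).

## Propagation and impact

`run_over_draws` re-runs the full DiD once per draw of the outcome
panel.  Reported point = median of per-draw points; reported CI =
(median of lowers, median of uppers).  The median point rule is a
package choice — the alternative (a single full-data run) coincides with
it for symmetric draw distributions, and skew/kurtosis of the bound
distributions are recorded so that symmetry can be checked.  Isolated
draw failures are skipped and counted; more than 1% aborts.

Events avoided uses two counterfactual forms with ATT proportion
`a = pct/100`:

- already-exposed townships (counts observed **with** the policy):
  `avoided = E·(1/(1+a) − 1)` (divide form);
- hypothetically exposing unexposed townships (counts observed
  **without** the policy): `avoided = −E·a` (multiply form).

Only this pairing is self-consistent, since the observed counts sit on
opposite sides of the policy in the two scenarios.  CI bounds map
through the same formula; final counts round half away from zero.

Pre-trend diagnostics: placebo DiD pretending adoption at P2011 (base
P2009) per eventual cohort versus never-exposed, plus a Wald comparison
of per-township OLS time slopes over the four pre-policy windows.

## Synthetic-data generator

The generator is the package's study stand-in, with defaults fixed at
the design being emulated:

| parameter | default | rationale |
|---|---|---|
| townships | 151 on a 12×13 rook lattice | eligible-township count; sparse connected adjacency |
| villages per township | uniform 5–40 | ~2500 villages citywide |
| cohort fractions | 75/151, 17/151, 59/151 | adoption counts by 2017 and 2019 |
| stratum baselines | 40–2300 per 10⁵ per window | steep age gradient, male excess; township standardised rates in the few-hundred range |
| period effects | −0.20 … +0.12 | mild secular drift, base window 0 |
| spatial / unstructured SD | 0.15 / 0.10 | moderate clustering of township risks |
| treatment effects τ | ln 0.934, ln 0.90 | −6.6% after <2 years, −10% after 2–4 years of exposure |
| population per township | uniform 8 000–30 000 (35+) | ~5.7 M eligible population |

Counts are Poisson with
`log λ_its = log N_its + baseline_s + α_t + β′(X_i − X̄) + δ z_i t + u_i + v_i + τ_{e(i,t)}`,
`u` drawn from the ICAR distribution on the lattice (eigenbasis of the
graph Laplacian, sum-to-zero), `v` iid normal.  Covariate effects are
centred so baselines stay interpretable.  Each two-year intensity is
split evenly across its calendar years (and optionally months).  One
RNG seeded from `config.seed` drives geography, covariates, cohort
assignment, rollout, random effects and counts in that fixed order, so a
configuration is a reproducible dataset.

Village enrollment years are uniform conditional on the cohort's
threshold-crossing constraint — the within-township rollout law is
unknown, so the least-informative law is used; the exposure module
recovers every planted cohort exactly (round-trip test).

Confounding is off by default (cohort counts exact, assignment random).
`assignment_confounding` switches ever-adoption to a Bernoulli draw with
logit-linear probability in the standardised confounder (intercept
solved so the mean matches the configured adopter share; the 2016/2018
split is confounder-independent, keeping each treated-vs-never
propensity exactly in the logit family), and `trend_confounding` makes
the confounder tilt the secular slope — together they bias unadjusted
contrasts while leaving the doubly robust estimand identified.

What the generator does **not** emulate: real Beijing geography,
migration, within-period seasonality, time-varying covariates,
non-proportional age-specific policy effects, and exposure
misclassification from partial-window enrollment.  Passing recovery
tests therefore demonstrate estimator correctness under the assumed
design, not robustness to these real-data features.

## Validation experiments (problem sizes)

All replicate seeds are spawned from fixed SeedSequences.

- Oracle equivalence: unadjusted ATT equals the four-cell-means DiD to
  1e−10 on 50 random panels.
- Parameter recovery: 200 replicate studies at full size; mean adjusted
  dynamic/overall ATTs within ±2 MC-SE of planted truth.
- Double robustness: 200 replicates per arm on a two-cohort confounded
  design; each single-misspecified arm recovers truth, no adjustment is
  biased by ~+0.04 to +0.08 on the log scale.
- Calibration: joint equality test rejection rate over 1000 null
  replicates within [0.03, 0.07]; placebo pre-trend CIs cover zero in
  ≥90% of 200 replicates.
- BYM: posterior mean rates within 1% of direct rates when populations
  are in the millions; 95% credible-interval coverage within 95 ± 3% on
  302 cells of self-generated data, using a reduced sampler (2 chains,
  2000–3000 iterations).
- Propagation: zero-variance draw banks reproduce the deterministic
  single-run analysis exactly; medians of known per-draw outputs are
  exact.

## Known limitations

- The spatial model is independent per window; space-time interaction
  smoothing is out of scope, so temporal smoothing of township
  trajectories is absent.
- Influence-function SEs ignore first-stage estimation effects; the
  joint F reference degrees of freedom are conventional.
- The sensitivity-battery CLI covers threshold, pooling, age-band,
  exclusion and covariate-set variants one at a time; crossed variants
  are left to the user.
- Outlier exclusion is by explicit township id list (the original
  outliers were identified visually, which is not reproducible code).
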