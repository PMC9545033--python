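# Methods

## Data model and fitness proxy

A technical measurement is one population-size estimate with coordinates
(treatment, replicate, week, assessment day, technical index). Population
sizes are extrapolated from droplet counts as
`mean(counts) × suspension_volume / droplet_volume`; the suspension volume is
a free metadata parameter (`suspension_volume_ul`), since only the droplet
volume (5 µL) is fixed by the assay. When a table supplies both droplet
counts and a population size, they must agree within 0.5 individuals.
Model fitting uses natural-log population sizes; selection responses are
reported on the raw scale (differences of population sizes, magnitudes
~10⁴), with a `scale` flag exposing both everywhere. Replicate means pool
all assessment days and technical measurements with equal weight per
measurement. Zero population sizes have no log and are dropped from
log-scale analyses with a logged warning.

## Synthetic generator

Log sizes follow

```
log N(t,r,w,d,k) = mu0 + beta_trt[t] + 1{w=15}(beta_week + beta_int[t] + b_resp[t,r])
                   + b_rep[t,r] + b_day[t,r,w,d] + e[t,r,w,d,k]
```

with independent normal components: `b_rep ~ N(0, sigma_replicate²)` (baseline
replicate intercept), `b_resp ~ N(0, sigma_response²)` (replicate-specific
selection-response deviation — the generative "chance" component),
`b_day ~ N(0, sigma_day²)` and residual `e ~ N(0, sigma_error²)`. Splitting
the replicate effect into a baseline intercept and a response deviation lets
week-0 spread and response spread be controlled independently; the raw scale
is lognormal because the analysis models log counts. Draws use sub-streams
seeded deterministically from (seed, treatment, replicate, week, day), so
tables are bit-reproducible and order-independent.

**Calibration (invented).** All default values are design choices of this
package, not estimates from any dataset: `mu0 = 7.4` (≈1600 individuals at
week 0), `beta_week = 2.2`, treatment offsets (0, −1.3, +0.8) and
interactions (0, +0.9, −0.9) — round numbers giving an order-of-magnitude
fitness gain with treatment differences of plausible size —
`sigma_replicate = 0.5`, `sigma_day = 0.4`, `sigma_error = 0.5`, and
`sigma_response` rising with bottleneck strength (0.2 / 0.35 / 0.6), encoding
the expectation that drift contributes more after a bottleneck. The
paper-like presets use five replicates, three technical measurements per day,
one week-0 assessment day per replicate, and week-15 day counts (3,3,3,2,2)
for "no" and (2,2,2,1,1) for "moderate"/"strong" (108 and 8 balanced day
combinations).

The generator emulates the assay's statistical structure only: no genetics,
no selfing or drift dynamics, no observer effects, and variance components
are homogeneous within treatment. Passing tests therefore demonstrate
correctness of the statistical machinery under the assumed hierarchical
lognormal model, not robustness to features of real data that violate it
(heteroscedastic days, counting biases, contamination events).

## Component statistics

Levene's test (center = mean) and Brown–Forsythe (center = median, the
default, for robustness; both exposed because reproductions may need either)
compute a one-way ANOVA F on |y − center| with (k−1, N−k) df. Kruskal–Wallis
uses average ranks, the tie correction `1 − Σ(t³−t)/(N³−N)`, and a chi-square
p-value on k−1 df — the conventional choice at these group sizes, and the OH
permutation null does not depend on it. Spearman's ρ is the Pearson
correlation of average ranks. All three are implemented directly (scipy
supplies only distribution functions) so the permutation engine can share
their exact definitions; scipy's implementations serve as independent
cross-checks in the tests.

## Ordered Heterogeneity test

Statistic: `r_s × P_c`, where `P_c = 1 − p` of the heterogeneity kernel and
`r_s` is the Spearman correlation between the observed group summaries and
the predicted ranks. The observed summary is the group's mean within-group
rank (Kruskal–Wallis kernel) or its mean absolute deviation from the group
center (Levene kernel) — the natural pairing with each kernel; published
analyses do not state their summary, which is one reason exact reproduction
of archived values is not guaranteed. Tied predicted ranks (composite
alternatives such as "two treatments equal, one lower") are handled by
average ranks with no special-casing. The test is one-sided: large positive
statistics support the predicted order.

Significance uses random reassignment of observations to groups, preserving
group sizes: `p = (1 + #{permuted ≥ observed}) / (B + 1)` with B ≥ 100, or
exact enumeration of all `N!/Πn_j!` labelled assignments when requested.
Permutation was chosen over published critical-value tables because it is
exact in distribution, self-contained, and verifiable against the exhaustive
mode. Inside the vectorised null engine a permutation whose group summaries
are all tied contributes `r_s = 0` (no ordering evidence); the scalar
`spearman_rho` raises on such degenerate input instead. Comparisons against
the observed statistic use a 1e-12 tolerance to absorb round-off.

## Mixed model

`log N ~ week * treatment` (reference cell: week 0, "no" bottleneck) with
random intercepts for replicate and for assessment day nested within
replicate × week — day labels are distinct per cell because a day belongs to
one replicate's assay. Numerical REML optimisation is delegated to
statsmodels' MixedLM (L-BFGS with tightened gradient tolerances, Powell
fallback); the module owns the parameterisation, the cell-mean contrast
algebra, and the Tukey adjustment. For exactly noise-free data the REML
likelihood is degenerate, so the fit falls back to OLS with zero variance
components (also available explicitly as `method="ols"`).

Least-squares-means contrasts are `L·β` with SE `√(L Σ Lᵀ)`; the Tukey
adjustment evaluates the studentized-range tail at `q = |t|√2` with the
number of means set to the full 2 × n_treatments grid, matching pairwise
comparison of all cell means. Degrees of freedom use the residual method
(N − rank X), declared in the output; mixed-model df approximations differ
across software, so df values are a benchmark, not a contract. R² is
reported as Nakagawa marginal and conditional R² (fixed-effect variance over
total, without/with random components); published "R²/predicted R²" values
for such models are method-dependent and no equality is promised.

## Variance partitioning

For one treatment, a balanced subset (one day per replicate × week cell,
n technical measurements per cell) is scored by the nested ANOVA

```
SS_selection = b·n Σᵢ (ȳᵢ·· − ȳ···)²          df = a − 1        (a = 2 weeks)
SS_chance    = n Σᵢⱼ (ȳᵢⱼ· − ȳᵢ··)²           df = a(b − 1)
SS_error     = Σᵢⱼₖ (yᵢⱼₖ − ȳᵢⱼ·)²            df = ab(n − 1)
```

i.e. replicates are treated as nested within week (each week × replicate
cell its own level), which realises "variance among replicates" as the
chance stratum. Under this decomposition
`E[MS_error] = σ_e²`, `E[MS_chance] = σ_e² + n(σ_rep² + σ_day² + ½σ_resp²)`
(the response deviation enters only the week-15 half) and `E[MS_selection]`
adds the fixed week contrast. Proportions are mean squares over their sum —
not variance-component estimates — which deliberately conflates stratum
sample sizes; this follows the analysis being reproduced and is reported as
such. The partition defaults to the log scale (consistent with the mixed
model), with raw available for sensitivity; proportions are invariant to
positive scaling on the raw scale and to additive shifts on either.

Subset enumeration is the exhaustive Cartesian product over cells in
lexicographic order, with an optional seeded uniform cap (`max_subsets`) for
designs too large to enumerate. Degenerate subsets (zero total variance) are
skipped, counted and warned about. Week-0 cells with a single day simply
contribute one choice, so designs where only week 15 varied reproduce the
printed products (108 and 8) exactly.

## Pipeline

One top-level seed is split per stage through `SeedSequence((seed, stage))`
(all derived seeds < 2³¹ and recorded in the manifest); reruns with the same
config are byte-identical, and `report --manifest` regenerates every
artifact from the manifest alone. Logging is one structured line per stage
with row/subset counts.

## Problem sizes and numerical choices

Default analyses run the full design (132 measurements, 108 + 8 + 8 balanced
subsets, B = 10,000 permutations). The calibration studies in the test suite
and acceptance script use 200 simulated tables for mixed-model recovery,
2,000 (tests) or 1,000 (script) null datasets at B = 999 for OH type-I error,
and 100 common-random-number pairs for the chance-proportion contrast —
sizes at which Monte-Carlo error is small relative to the margins being
checked. Exhaustive OH enumeration is capped at 2 × 10⁶ assignments;
beyond that, permutation mode is required.

## Known limitations

- The OH group summary, Levene centering, and mixed-model df method used in
  published analyses of the archived dataset are unrecorded; reproduction of
  archived values may require trying both centers and summaries, and exact
  agreement is not guaranteed (`load_archived_experiment` gates these
  benchmarks on a separately downloaded archive).
- MS proportions are not variance components; with few replicates the chance
  stratum pools baseline replicate heterogeneity, day effects and response
  variance, so moderate changes in the generative chance SD shift the
  partition distribution but need not reorder every paired draw.
- The chi-square approximation for Kruskal–Wallis is inaccurate for very
  small samples; within the OH test this only affects the statistic's
  monotone transform, not the permutation p-value's validity.
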