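# evorepeat

Statistical pipeline for quantifying the **repeatability of fitness evolution**
in replicated experimental-evolution studies with population bottlenecks.

The target design is a fitness assay on evolving populations (e.g. obligately
outcrossing *Caenorhabditis elegans* adapting to a novel bacterial food):
three bottleneck treatments ("no", "moderate", "strong") × five replicate
populations × two time points (week 0 ancestral, week 15 evolved), with one to
three fitness-assessment days per replicate and three technical measurements
per day. The fitness proxy is the population size reached after one week of
growth, extrapolated from worm counts in 5 µL droplets.

The package answers two questions about such data:

1. **Did fitness change, and differently across treatments?** A linear mixed
   model on log population size,

   `log N ~ week * treatment + (1 | replicate) + (1 | assessment day)`,

   fitted by REML, with Tukey-adjusted pairwise comparisons of the
   week × treatment cell means.

2. **How repeatable was the change?** Two complementary measures:
   - **Ordered Heterogeneity (OH) tests** on the per-replicate selection
     response ΔN = N̄(week 15) − N̄(week 0). The OH statistic is
     *r*ₛ*P*꜀ — the Spearman correlation between observed group summaries and
     a predicted treatment ordering, times the complement of a nondirectional
     heterogeneity test's p-value (Kruskal–Wallis for ordered means, Levene /
     Brown–Forsythe for ordered variances). Significance comes from a
     permutation null (group labels reassigned), with exhaustive enumeration
     on small problems.
   - **Variance partitioning** into *selection* (between weeks), *chance*
     (among replicates within week) and *measurement error* (within
     replicate), as relative proportions of nested-ANOVA mean squares.
     Because day counts are unbalanced, the partition is computed on **every
     balanced subsample** obtained by choosing one assessment day per
     replicate × week cell (e.g. 3·3·3·2·2 = 108 combinations) and reported
     as a distribution.

A synthetic-data generator (`DesignSpec`, `generate_experiment`) reproduces
the full hierarchical structure — lognormal measurements with fixed
week/treatment effects and random replicate, replicate-response ("chance"),
assessment-day and residual components — so every stage is testable with
known ground truth.

## Worked example

```python
from evorepeat import (
    paper_like_experiment_spec, generate_experiment, fit_lmm, pairwise_contrasts,
    selection_response, oh_test_suite, BENCHMARK_HYPOTHESES, partition_distribution,
)

spec = paper_like_experiment_spec(seed=1)   # 3 treatments x 5 replicates
table = generate_experiment(spec)           # 132 technical measurements

fit = fit_lmm(table)
w = fit.fixed_effects["week15"]
print(f"week-15 effect: {w['estimate']:.2f} +/- {w['SE']:.2f} log units")
for c in pairwise_contrasts(fit, "within_treatment_between_weeks"):
    print(f"{c.label}: {c.estimate:.2f} (Tukey p = {c.adjusted_p:.3g})")

responses = selection_response(table)
oh = oh_test_suite(responses, BENCHMARK_HYPOTHESES["means"], target="means",
                   n_permutations=10_000, seed=2)
for r in oh:
    print(f"{r.hypothesis}: rsPc = {r.statistic:.3f}, P = {r.p_value:.3f}")

for trt in ("no", "strong"):
    d = partition_distribution(table, trt)
    m = d.summary()
    print(f"{trt}: {d.n_subsets} subsets, median selection/chance/error = "
          f"{m['selection']['median']:.3f}/{m['chance']['median']:.3f}/{m['error']['median']:.3f}")
```

Output:

```
week-15 effect: 1.83 +/- 0.31 log units
no bottleneck (week 0 - 15): -1.83 (Tukey p = 4.85e-07)
moderate bottleneck (week 0 - 15): -3.46 (Tukey p = 0)
strong bottleneck (week 0 - 15): -0.56 (Tukey p = 0.561)
response_decreases_with_bottleneck: rsPc = 0.387, P = 0.185
no_bottleneck_exceeds_bottlenecked: rsPc = 0.335, P = 0.215
no: 108 subsets, median selection/chance/error = 0.934/0.058/0.007
strong: 8 subsets, median selection/chance/error = 0.224/0.754/0.022
```

Read: every treatment gained fitness by week 15 (negative week 0 − 15
contrasts on the log scale; the strong-bottleneck gain is not significant in
this synthetic draw). Neither ordered-means hypothesis is supported
(*r*ₛ*P*꜀ small, permutation P > 0.18). The variance partition shows the
generator's built-in pattern: with a strong bottleneck most fitness variance
is attributable to chance (drift) rather than selection — the median chance
proportion rises from 0.06 to 0.75.

The same stages are available from a shell:

```bash
evorepeat simulate --scenario all --seed 1 --out sim.csv
evorepeat fit sim.csv --out-json fit.json
evorepeat oh-test sim.csv --target means --seed 2 --out oh.json
evorepeat partition sim.csv --treatment strong
evorepeat run-all --synthetic --seed 1 --outdir out/
```

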