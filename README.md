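# genoverlap

Toolkit for dissecting *why* two traits co-occur — shared genes, shared
environment, or causation — built around the smoking–caffeine association
and usable for any pair of binary/consumption traits with the same data
shapes.  It implements three complementary analyses end-to-end, each with a
matched synthetic-data generator so every estimator can be validated by
simulation at realistic sample sizes:

1. **Bivariate liability-threshold twin modelling** (`genoverlap.twin_model`)
   — maximum-likelihood ACE/AE Cholesky models for two binary traits
   measured on MZ/DZ twin pairs, with sex-specific age-moderated
   thresholds, a nested constraint-testing cascade, profile/bootstrap
   confidence intervals, and the decomposition of the phenotypic liability
   covariance into genetic and environmental shares.  For traits 1 and 2
   with variance shares A₁, A₂, E₁, E₂ and component correlations r_A,
   r_E, the genetic share of the covariance is
   r_A√(A₁A₂) / (r_A√(A₁A₂) + r_E√(E₁E₂)).
2. **Cross-trait LD-score regression** (`genoverlap.ldsc`) — h² and genetic
   correlation from GWAS summary statistics via the moment model
   E[z₁z₂] = √(N₁N₂)·ρ_g·l_j/M + intercept, with two-step weighting,
   block-jackknife standard errors, allele-orientation alignment, and the
   cessation→persistence sign recode.
3. **Bidirectional Mendelian randomization** (`genoverlap.mr`) — weighted
   allele scores from published GWAS effect sizes (8 coffee SNPs; rs1051730
   for smoking heaviness), instrument and confounder checks, stratified
   causal tests with cluster-robust inference, and an analytic IV power
   calculator with a simulation cross-check.

The orthant-probability engine behind the twin likelihood reduces each
pair's 4-D integral to a 2-D Gauss–Hermite quadrature by conditioning on
the shared familial factor, with a vectorized Genz bivariate-normal CDF
underneath; a full ~4 400-pair maximum-likelihood fit takes a few seconds.
See `docs/methods.md` for the models, assumptions and numerical choices.

## Worked example

```python
import numpy as np
from genoverlap import *

# --- twins: simulate at a known truth and refit --------------------------
params, thresholds, design = default_twin_truth("coffee")   # A 0.76/0.53, rA 0.47, rE 0.30
records = simulate_twin_sample(params, thresholds, design, rng=np.random.default_rng(1))
fit = fit_model(TwinData.from_records(records), model="AE", seed=1)
s = correlations_from_params(fit.params)
print(f"A shares {s.A1:.3f}/{s.A2:.3f}  rA {s.rA:.3f}  rE {s.rE:.3f}  overlap_A {s.overlap_A:.3f}")
# A shares 0.792/0.552  rA 0.419  rE 0.309  overlap_A 0.746

# --- LD-score regression on synthetic summary statistics ------------------
t1, t2 = simulate_sumstats_pair(SumstatsSimSpec(seed=1))    # rg_true 0.44, M 50 000
fit = cross_trait_rg(t1, t2)
print(f"rg {fit.rg:.3f} (SE {fit.se_rg:.3f})  h2 {fit.details['h2_1']:.3f}/{fit.details['h2_2']:.3f}")
# rg 0.449 (SE 0.012)  h2 0.301/0.303

# --- MR: first-stage instrument check -------------------------------------
cohort = simulate_mr_cohort(MRSimSpec(n_individuals=12_000, seed=1))  # set-point 86.7 mg/day
r = instrument_check(cohort)["score_on_caffeine"]
print(f"caffeine score -> mg/day: {r.beta:.1f} [{r.ci_low:.1f}, {r.ci_high:.1f}]")
# caffeine score -> mg/day: 97.2 [79.5, 114.8]

print(f"power: {mr_power(PowerSpec(n=12_319, alpha=0.05, r2_xz=0.01, beta_xy=0.25)):.3f}")
# power: 0.792
```

Each block recovers its generating truth: a single twin sample of ~4 400
pairs estimates the genetic correlation with a sampling SE of ≈0.04 (hence
0.419 for a truth of 0.47 here; the 20-replicate mean lands within ±0.01),
the LD-score regression recovers rg = 0.44 to ≈0.01 at M = 50 000, and the
score's 86.7 mg/day first-stage set-point sits inside its confidence
interval.

A command-line interface mirrors the library
(`genoverlap simulate-twins | fit-twin | simulate-sumstats | ldsc-rg |
simulate-cohort | mr-test | mr-power | run-all`); every randomized
subcommand takes `--seed` and echoes it into its output header.

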