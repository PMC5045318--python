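# Methods

`genoverlap` implements three complementary statistical views of why two
traits — in the motivating application, current smoking and heavy caffeine
(coffee) use — co-occur: shared genes, shared environment, or causation.
Each analysis stage is paired with a synthetic-data generator that produces
data with exactly the statistical structure the estimator assumes, so every
estimator can be validated by simulation-and-refit at realistic sample
sizes.

## 1. Bivariate liability-threshold twin model

### Model

Each binary trait is the indicator of a latent standard-normal liability
exceeding a cutpoint.  For a twin pair, the two liabilities per twin
decompose into additive-genetic (A), common-environment (C) and
unique-environment (E) components through a bivariate Cholesky
parameterization.  Co-twins correlate 1 (MZ) or 0.5 (DZ) on A, 1 on C, and
0 on E.  The derived quantities reported are the standardized variance
shares per trait (A, C, E), the component correlations

    r_X = cov_X(1,2) / sqrt(var_X(1) * var_X(2)),   X in {A, C, E},

and the decomposition of the phenotypic liability covariance into component
shares r_X·sqrt(X1·X2) / Σ_Y r_Y·sqrt(Y1·Y2), which sum to one.  (A
published formula for the genetic correlation in this model family is
typographically ambiguous about the grouping of its denominator; the
standard covariance-over-root-variance-product definition above is what is
implemented.)

Thresholds are sex-specific with a single linear age moderator per
trait × sex acting on an ordinal age-band score 0–5 (bands <20, 20–24,
25–34, 35–44, 45–54, ≥55 years).  Age acts only on thresholds, never on
variance components.

### Likelihood

The data enter as pooled counts of the 16 joint response patterns per
zygosity group × age band (complete pairs) and of the 4 patterns of the
observed twin (incomplete pairs), so each distinct orthant probability is
evaluated once per deviance evaluation.  Opposite-sex pairs are stored
male-first, which is valid because all supported correlation structures are
birth-order symmetric.

Pattern probabilities are *not* computed as generic 4-D integrals.  Any
birth-order-symmetric pair structure can be written as y_twin = u + e_twin
with a shared bivariate factor u and independent within-twin residuals;
conditioning on u makes the twins independent, so the 16 pattern
probabilities reduce to a 2-D Gauss–Hermite quadrature (24 nodes per
dimension) over products of bivariate-normal rectangle probabilities.  The
16 probabilities of a cell come out of a single pass and sum to one by
construction; against a 10^6-draw Monte-Carlo oracle and scipy's
Genz–Bretz integrator they agree to ~1e-6 or better.  The bivariate normal
CDF itself is a vectorized implementation of Genz's BVND algorithm
(Drezner–Wesolowsky quadrature for |rho| < 0.925, tail-series expansion
beyond), accurate to ~1e-14 against scipy.  A generic rectangle integrator
(`orthant_probability`, scipy Genz–Bretz with a fixed internal seed and
absolute tolerance 1e-7) is retained as the independent cross-check and for
structures outside the exchangeable family.

### Fitting

Free structural parameters are the variance shares and component
correlations (A1, C1, A2, C2, rA, rC, rE); Cholesky loadings are derived
from them, which keeps every implied covariance positive semi-definite and
makes the reported quantities directly profilable.  Equality constraints
(dropping C, fixing an overlap correlation at zero, equating thresholds
across sex, dropping the age moderator) are imposed by fixing entries of
this vector.  A component correlation is only a free parameter when both
traits carry that component.

Optimization is L-BFGS-B with finite-difference gradients inside box
bounds (shares in [0, 0.97], correlations in [-0.97, 0.97], E share kept
>= 0.02 by a smooth rescaling penalty), started from a moment-based guess
(probit regression of band prevalences for thresholds).  Jittered restarts
are used until a start converges, and every solution is "polished" by
restarting the optimizer from its own solution until the deviance is flat;
the polish step is what guarantees the nesting property
minus2LL(submodel) >= minus2LL(supermodel) to ~1e-6 in practice.  The
saturated model uses an internal parameterization — cross-twin
within-trait correlations plus two correlation-like fractions of the
admissible ranges for the cross-trait cells — that makes every candidate
point feasible, avoiding likelihood cliffs.

Model comparison uses likelihood-ratio chi-square tests (difference in
deviance, df = difference in free-parameter count); a constraint is
retained when p >= 0.05.  `model_selection_sequence` applies an ordered
cascade of constraints, skipping rejected steps; a step may be marked
`mandatory` (the ACE baseline) so submodels are always defined relative to
it, with its own test still reported.  Degrees of freedom are reported as
(number of observed binary responses) − (free parameters), matching the
convention of SEM software for threshold models.

Confidence intervals: profile likelihood by default (bound where the
profiled deviance rises by the chi-square(1) critical value, found by
Brent's method with warm-started constrained refits; box-edge hits are
flagged as one-sided), or a multinomial bootstrap of the pattern counts
(200 resamples by default) as fallback.

### Continuous-caffeine sensitivity variant

`twin_continuous` keeps smoking binary but observes trait 2 on its raw
scale via caffeine = mu_sex-free location + age slope × band + scale ×
liability.  The pair likelihood is closed-form: a bivariate normal density
for the two continuous observations times the conditional bivariate
rectangle probability of the two binary responses.  This variant exists as
a robustness option; real caffeine intake is right-skewed, which the
Gaussian measurement model does not capture, and no published reference
values are attached to it.

## 2. Cross-trait LD-score regression

Under a polygenic model, E[z_j^2] = 1 + N h² l_j / M and
E[z_1j z_2j] = sqrt(N1 N2) ρ_g l_j / M + ρ Ns / sqrt(N1 N2), where l_j is
SNP j's LD score, M the SNP count and Ns the overlapping sample size.
Heritability and genetic covariance are the slopes of weighted regressions
of z² and z1·z2 on l_j; confounding and sample overlap move the intercept,
not the slope.  The genetic correlation is rg = ρ_g / sqrt(h²_1 h²_2).

Weighting is two-step: an unweighted pilot fit supplies the variance terms,
then one weighted refit with w_j = 1/(l_j (1 + N h²_0 l_j/M)²)
(univariate) and w_j = 1/(l_j (v1 v2 + c²)) with c the pilot mean product
(bivariate).  The intercept is free by default.  Standard errors come from
a 200-block delete-one jackknife over SNPs in table order; for rg the full
pipeline (both univariate slopes and the cross slope) is re-estimated per
block from precomputed sufficient statistics.  rg values outside [-1, 1]
are flagged, never clipped; a non-positive estimated heritability makes rg
undefined rather than silently produced.  A trait coded as cessation
(0 = current, 1 = former) is converted to persistence by negating the
correlation.

Tables are merged on SNP id with allele-orientation checking: swapped
allele pairs flip the second Z's sign, incompatible pairs are dropped.
The estimate is exactly symmetric in its two arguments and invariant under
joint allele-label/Z-sign flips of any SNP subset.

## 3. Bidirectional Mendelian randomization

Instruments: an 8-SNP weighted allele score for caffeine use (weights =
published per-allele effects from the Cornelis et al. coffee GWAS
meta-analysis; score = Σ β_k × dosage_k) and the rs1051730 dosage for
smoking heaviness (TAG consortium).  A 2-SNP metabolism-only score (AHR +
CYP1A1) is available as a pleiotropy-sensitivity preset.  Missing dosages
are mean-imputed per SNP with a logged count.

Tests: (i) instrument checks — score on caffeine mg/day, SNP dosage on
cigarettes/day among current smokers; (ii) smoking → caffeine — SNP dosage
on total and coffee-only caffeine within current/former/never strata,
never smokers serving as the negative control because the SNP can act only
through smoking heaviness; (iii) caffeine → smoking — score on
cigarettes/day (linear, current smokers) and on initiation, current
smoking and persistence (logistic; persistence is undefined for never
smokers, who are excluded from that model only); (iv) confounder checks —
each instrument against education and social class, flagged at p < 0.05.
All models adjust for age, sex and cohort and use one-way cluster-robust
(sandwich) covariance by family id; singleton clusters are allowed.
Binary outcomes use logistic regression — the convention adopted here,
since linear-probability modelling is the main defensible alternative.

High-use dichotomization: high iff value > mean + 1 SD within the
individual's sex group (a value exactly at the cutoff is low).

Power: for a continuous outcome the IV Wald test has non-centrality
NCP = n r²_xz (β_xy σ_x/σ_y)² and power
Φ(−z_{1−α/2} + √NCP) + Φ(−z_{1−α/2} − √NCP); the inverse (smallest
detectable effect at target power) uses the standard z_{1−α/2} + z_{power}
approximation.  The formula is validated against a 2000-replicate
simulated IV analysis on a grid of (n, β) to within ±0.03.

## Synthetic-data generators

All generators are bit-reproducible from their seeds and emulate exactly
the structure the estimators assume — no more.  What passing recovery
tests show is that each estimator is consistent and approximately unbiased
*under its own model*; they do not probe misspecification such as
assortative mating, non-normal liabilities, real LD structure, or skewed
consumption scales.

Twin generator: factor scores drawn with the A/C/E cross-twin correlation
pattern, combined through the Cholesky loadings, binarized at sex- and
age-specific cutpoints.  Defaults emulate a large Dutch twin cohort: age
mix (11.6, 30.1, 22.3, 18.2, 7.0, 10.8)% across the six bands; complete
pairs ~1700 MZ + ~2700 DZ (coffee variant) or ~1300 MZ + ~2100 DZ (total
caffeine), split across MZM/MZF/DZM/DZF/DOS proportionally to the cohort's
group sizes.  Target prevalences: current smoking 28% (men) / 23% (women);
high coffee 19%/15% (≈17% overall); high total caffeine 16%/14% (≈15%);
threshold age slopes +0.04 (smoking declines with age) and −0.06 (caffeine
use rises).  The published study does not print per-band prevalences, so
these moderation values are declared defaults, not reproductions.

Summary-statistics generator: LD scores from a shifted gamma law (shape 2,
scale 30, shift 1 — right-skewed, positive, mean ≈ 61); per-SNP Z pairs
jointly normal with the first two moments of the LD-score model at
N1 = 46 481, N2 = 91 462, h² = 0.3 per trait and configurable rg and
sample overlap.  A parameter combination implying a non-PSD per-SNP
covariance is rejected with the offending values named.

MR cohort generator: dosages Binomial(2, RAF) with published risk-allele
frequencies; smoking status multinomial (50% never / 25% former / 25%
current — pooled frequencies are not published, so these are declared);
structural equations give each instrument its own-exposure effect
(defaults at the published first-stage set-points, 86.7 mg/day per unit
score and 0.6 cigarettes/day per risk allele), optional cross-trait causal
effects (smoking → caffeine acts through realized cigarettes/day among
current smokers; caffeine → smoking is added to cigarettes afterwards),
and an optional shared confounder.  Negative phenotype draws are truncated
at zero (count logged) to keep the instrument-exposure relation linear.
A configurable fraction of individuals form 2-person sibling clusters
whose dosages correlate ≈0.5 and who may share a family-level noise
component, giving the cluster-robust machinery something real to correct.

## Numerical choices and problem sizes

- Gauss–Hermite: 24 nodes/dimension (pattern probabilities accurate to
  ~1e-7; the orthant-sum identity holds exactly).
- Deviances are deterministic and reproducible to printing precision;
  the generic integrator uses absolute tolerance 1e-7 with a fixed seed.
- Recovery studies use 20 replicates per setting; twin samples at the
  cohort-scale pair counts above, summary statistics at M = 50 000.  These
  sizes put the Monte-Carlo SE of each reported mean well inside the
  tolerance it is compared at (e.g. SE(mean rA) ≈ 0.01 over 20 replicates).
- Saturated fits report bound hits (|r| > 0.975) instead of applying
  continuity corrections to zero cells.

## Known limitations

- No sex-limitation models: variance components and component correlations
  are equated across sexes (only thresholds differ), matching the
  best-fitting constraint pattern of the motivating analysis.
- No birth-order-asymmetric saturated models (the symmetric structure is
  assumed, not tested).
- LD scores are synthetic draws, not computed from a reference panel; no
  MAF/INFO filtering, no liability-scale heritability conversion.
- One-sample MR only; no MR-Egger/median estimators.
- Liability normality is assumed throughout; the continuous variant's
  Gaussian measurement model understates the skew of real consumption data.
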