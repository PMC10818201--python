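# Methods

## Model

A continuous trait `y` measured on `n` unrelated subjects is modeled as

    y = X b + g + m + e

with fixed effects `X b` (intercept, age in years, a sex indicator,
scanner-batch indicators and the leading ancestry principal components —
20 by default at study scale) and three random terms: a genomic effect `g`,
a morphological effect `m` and residual noise `e`. Under Model 1 the random
effects are independent with

    var(y) = s2_g * GRM + s2_b * BRM + s2_e * I.

The genomic relatedness matrix GRM is `G G' / p` for the subject-by-SNP
matrix `G` of allele counts standardized column-wise to mean 0 and
*population* standard deviation 1 (divisor `n`), so `trace(GRM)/n = 1`
exactly and variance components are on the phenotypic scale. The brain
relatedness matrix BRM applies the identical construction to vertex-wise
cortical-thickness values (or any continuous feature matrix). Zero-variance
columns are dropped with a warning; missing genotypes are mean-imputed per
SNP before standardization.

Model 2 (the CORE extension) adds a covariance between the two random
effects. Both kernels are bent to positive definite (their cross-product
construction is exactly singular along the ones vector, since column
centering forces `GRM @ 1 = 0`), Cholesky-factored as `L_G`, `L_B`, and the
covariance enters through the symmetrized product kernel

    CORE = L_G L_B' + L_B L_G',     var(y) = ... + s_bg * CORE.

A single factor product is asymmetric in general; the symmetrized form
makes `var(y)` well defined, and its coefficient `s_bg` is the effect
covariance itself (the factor 2 implied by symmetrization is absorbed: the
joint effect covariance `cov(g, m) = s_bg L_G L_B'` gives
`var(g + m) = s2_g GRM + s2_b BRM + s_bg CORE` exactly).

Derived summaries:

* heritability `h2 = s2_g / D` and morphometricity `m2 = s2_b / D`, with
  `D = s2_g + s2_b + s2_e` under Model 1 and, by default,
  `D = s2_g + s2_b + 2 s_bg + s2_e` under Model 2 (the total phenotypic
  variance implied by the symmetrized kernel; a
  `denominator_includes_covariance=False` switch restores the
  covariance-free denominator);
* effect correlation `r_bg = s_bg / sqrt(s2_b * s2_g)`.

Standard errors of all three are first-order Delta propagations of the
inverse average-information matrix at convergence; component and ratio
tests are 1-df Wald chi-square tests against zero, Model 1 vs Model 2 is a
1-df likelihood-ratio test, and p-value columns are Benjamini–Hochberg
adjusted across traits, one family per column. Wald tests use the plain
chi-square(1) tail with no boundary mixture correction, which is
conservative for variance components tested at zero (confirmed by the null
calibration below).

## Estimation

Restricted maximum likelihood, maximized by average-information (AI)
updates after one expectation–maximization burn-in step, with step-halving
on likelihood decreases. Implementation details that matter:

* **Projected evaluation.** All quantities are computed in an orthonormal
  basis `Q` of the orthogonal complement of `span(X)`: the REML projection
  is `P = Q (Q'VQ)^-1 Q'`, so the likelihood, score and AI matrix reduce to
  the `(n - p)`-dimensional projected kernels `Q'KQ`, computed once per
  fit. Besides speed, this removes the exact singular direction the
  centered kernels share with the intercept and keeps evaluations well
  conditioned when the residual variance approaches its floor. The reported
  log-likelihood is restored to the conventional
  `-(log|V| + log|X'V^-1X| + y'Py)/2` normalization (additive constant
  omitted) via the data-constant `log|X'X|` offset.
* **Constraints.** Variance components are floored at `1e-6 * var(y)`;
  the CORE coefficient is unconstrained in sign. Components sitting at the
  floor that the AI step would push below it are pinned and the reduced
  system re-solved — without this the ill-conditioned full step overshoots
  and the fit creeps.
* **Convergence** is declared when the log-likelihood change falls below
  `1e-8`, or equivalently when the quadratic-model prediction of the
  attainable gain (the Newton decrement of the AI system) falls below the
  same tolerance; the latter form is robust to the ~1e-9-relative
  floating-point noise of repeated likelihood evaluations. Step acceptance
  allows the same noise band. Non-convergence at the iteration cap
  (default 200) is reported on the fit, not raised.
* **Nesting.** Model 2 warm-starts at the nested Model 1 optimum, so the
  wider model cannot converge below the model it nests and LRT statistics
  are non-negative up to a small ordering tolerance (default 1e-3).
  Fixing the covariance at zero (`fix_covariance_zero=True`) reproduces
  Model 1 exactly.
* The asymptotic covariance of the estimates is the inverse AI matrix at
  convergence. Across 100 simulated cohorts at n = 500 the reported SEs
  agree with the empirical SD of the estimates within a few percent.

The `r_bg` ratio is reported as-is, without clipping to [-1, 1]; fits with
a variance at its floor, |r_bg| > 1, or no convergence carry an
`unreliable` flag. At moderate cohort sizes the per-fit correlation ratio
is heavy-tailed, so replicate studies should summarize the (unbiased)
components and form the pooled ratio of means rather than averaging
per-fit ratios — the acceptance checks do exactly this.

## Preprocessing

Per trait, in fixed order: an optional plausibility range filter (closed
interval, configurable per outcome), robust outlier masking at `k = 4`
scaled median absolute deviations from the median (consistency constant
1.4826; a zero-MAD vector masks nothing), complete-case dropping, then
ordered-quantile normalization `Phi^-1((r - 0.5)/n)` on average-for-ties
ranks. The quantile offset is configurable; 0.5 is the default.

Vertex features are harmonized across scanner batches before BRM
construction with a parametric empirical-Bayes location–scale model
(ComBat): per feature, batch locations and scales are estimated on
covariate-standardized residuals, shrunk across features within batch
(normal prior on locations, inverse-gamma on squared scales, moment-matched
hyperparameters, iterated conditional modes) and removed; covariates listed
for protection — in the intended workflow, the outcome set plus
demographics — are restored untouched, and the design's condition number is
logged because protecting many correlated outcomes can approach rank
deficiency. Harmonization removes an injected (+2.0, x1.5) location–scale
batch effect to mean differences < 0.05 and variance ratios within
[0.9, 1.1] while recovering a protected slope of 0.5 within 0.05. Note that
empirical-Bayes shrinkage deliberately leaves a fraction of per-feature
sampling noise, so re-applying harmonization is a near no-op (second-pass
changes ~1-2% of first-pass changes) but not an exact fixed point.

Subjects are pruned before analysis so that no retained pair has
relatedness at or above a cutoff (default 0.05), by greedily removing the
subject in the most over-cutoff pairs (ties: the later id), which retains a
maximum unrelated set on clique-structured relatedness. The cutoff should
sit above the kernel's sampling-noise floor: GRM off-diagonals have
standard deviation ~ `1/sqrt(n_snps)`, so small simulated SNP panels need a
proportionally higher cutoff (the bundled small-scale tests use 0.25).

## Synthetic cohorts

The generator draws, per seed and with deterministic per-stage substreams:

* genotypes: per-SNP allele frequency uniform on [0.05, 0.5], counts as two
  Bernoulli trials (Hardy–Weinberg equilibrium);
* features: `sqrt(rho) * PGS + sqrt(1 - rho) * noise`, where the polygenic
  score uses random SNP weights and the noise mixes ~30 shared subject-level
  factors (weight 0.3) with unique variation — emulating the correlation
  structure of smoothed cortical maps — plus optional per-batch location
  shifts and scale factors;
* phenotypes: `y = X b + L_V z` with `L_V` a factor of the model covariance
  built from the *realized* kernels, so estimator error is assessed against
  the exact kernels the estimator receives (a joint-effects sampler over
  the 2n-dimensional effect covariance is provided as a cross-check and is
  marginally identical);
* covariates: age ~ N(9.9, 0.6) years, 46.8% female, with small fixed
  effects (0.05/year, 0.1) — matching a late-childhood cohort baseline.

Defaults are n = 500 subjects, 2000 SNPs, 1000 features and components
(s2_g, s2_b, s2_e) = (0.3, 0.2, 0.5) with r_bg = 0: large enough that
Model-1 components are recovered with informative SEs (~0.08–0.14) on one
CPU in under a second per fit. What the generator does **not** emulate:
linkage disequilibrium between SNPs, spatially organized cortical geometry
(features are exchangeable), family/pedigree structure, non-Gaussian trait
distributions beyond what ORQ normalization removes, and scanner effects
beyond location–scale. Passing recovery tests therefore demonstrate
estimator correctness under the stated generative model, not robustness to
those real-data complications.

## Problem sizes used in the checks

Parameter-recovery and SE-calibration checks run 50–100 cohorts at the
defaults above; covariance recovery runs 50 cohorts with a generating
r_bg = 0.5 (s2_g = s2_b = 0.3); null calibrations run 200 replicates at
n = 200 with 600 SNPs and 400 features, where the LRT rejects ~3–6% and
the boundary Wald test <=2% at the nominal 0.05 level. Delta-method SEs of
m2 agree with the SD of the ratio over 1e5 parametric draws from the
fitted asymptotic covariance within 10%.

## Known limitations

* Dense `O(n^3)` linear algebra per iteration: comfortable to a few
  thousand subjects, not to biobank scale.
* The Fisher-z interval of the off-diagonal kernel correlation treats the
  n(n-1)/2 pairs as independent, ignoring their shared-subject dependence.
* Continuous traits only; no liability-scale transformation for binary
  outcomes, at most two substantive kernels plus CORE, and no
  LD-aware or allele-frequency-weighted kernel variants.
* Harmonization is parametric-EB only (no nonparametric prior) and
  cross-sectional.
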