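# morphgreml

Joint variance decomposition of childhood traits by **genomic similarity**
and **brain-morphological similarity**, in one linear mixed model.

Individual differences in a trait `y` can be partitioned by how similar
subjects are genome-wide and how similar their cortical anatomy is. From a
subject-by-SNP matrix of standardized allele counts `G` and a
subject-by-vertex matrix of standardized cortical-thickness values `B`, the
package builds the two kernels

    GRM = G G' / n_snps        BRM = B B' / n_vertices

and fits, by average-information restricted maximum likelihood (AI-REML),

    Model 1:  y = X b + g + m + e,   var(y) = s2_g GRM + s2_b BRM + s2_e I
    Model 2:  var(y) = s2_g GRM + s2_b BRM + s_bg CORE + s2_e I

where `X` holds fixed effects (age, sex, scanner batch, ancestry principal
components), and CORE — the symmetrized product `L_G L_B' + L_B L_G'` of the
Cholesky factors of the positive-definite-bent kernels — carries the
covariance `s_bg` between the genomic and morphological random effects
(the CORE GREML extension). The headline summaries are

* **SNP-based heritability**  `h2 = s2_g / (s2_g + s2_b + s2_e)`,
* **morphometricity**         `m2 = s2_b / (s2_g + s2_b + s2_e)`,
* **effect correlation**      `r_bg = s_bg / sqrt(s2_b s2_g)`,

each with a Delta-method standard error from the inverse average-information
matrix, Wald tests, a 1-df likelihood-ratio test of Model 2 vs Model 1, and
Benjamini–Hochberg FDR adjustment across traits.

The package also covers the surrounding workflow: PLINK 1 binary and GCTA
binary-GRM I/O, relatedness pruning, ComBat-style empirical-Bayes scanner
harmonization with protected covariates, robust (MAD) outlier masking,
ordered-quantile normalization of outcomes, ancestry PCA, and a synthetic
cohort generator with known ground truth, so the full pipeline is testable
without access-restricted cohort data.

## Worked example

Simulate a cohort of 500 subjects (2000 SNPs, 1000 correlated vertex
features) with generating components (0.3, 0.2, 0.5), and fit Model 1:

```python
import morphgreml as mg

cohort = mg.simulate_cohort(seed=11)
fit = mg.fit_greml(cohort.phenotype, cohort.X, [cohort.grm, cohort.brm])
m2, h2 = fit.variance_proportions()
for name, value in fit.varcomp_.items():
    print(f"{name:9s} = {value:.3f} (SE {fit.component_se(name):.3f})")
print(f"h2 = {h2.value:.3f} +/- {h2.se:.3f} (Wald p = {h2.p_value:.3g})")
print(f"m2 = {m2.value:.3f} +/- {m2.se:.3f} (Wald p = {m2.p_value:.3g})")
```

prints

```
sigma2_g  = 0.339 (SE 0.132)
sigma2_b  = 0.186 (SE 0.073)
sigma2_e  = 0.481 (SE 0.137)
h2 = 0.337 +/- 0.126 (Wald p = 0.00756)
m2 = 0.185 +/- 0.068 (Wald p = 0.00683)
```

— the generating heritability (0.3) and morphometricity (0.2) are recovered
within one standard error, and both kernels explain significant variance.

The model-comparison workflow reproduces a published 19-trait example from
the bundled reference table of restricted log-likelihoods:

```python
from morphgreml.datasets import cohort_model_comparison
from morphgreml.greml import compare_models

df = cohort_model_comparison()
table = compare_models(df["loglik_model1"], df["loglik_model2"], df["trait"])
print(table[["trait", "lrt_stat", "lrt_p", "lrt_p_fdr"]].head(4).to_string(index=False))
```

```
           trait  lrt_stat    lrt_p  lrt_p_fdr
          Height       0.0 1.000000   1.000000
          Weight       1.2 0.273322   0.865519
    Birth weight       1.6 0.205903   0.865519
Age at pregnancy       6.0 0.014306   0.271812
```

The age-at-pregnancy row — the largest model-2 improvement in the table —
has LRT statistic `2 x (-3308.9 - (-3311.9)) = 6.0` and a BH-adjusted p of
0.272 across the 19 traits: no trait shows a significant effect covariance.

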