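"""End-to-end study orchestration.

``run_study`` executes the full workflow from a :class:`StudyConfig`:
relatedness pruning, feature harmonization, kernel construction and
positive-definite bending, the CORE kernel, per-trait outcome preparation
(range filter, MAD masking, complete-case drop, ordered-quantile
normalization), Model 1 and Model 2 REML fits, ratio and correlation
estimates, Wald and likelihood-ratio tests, and per-column FDR adjustment.
Results are returned as data frames (and written as TSV when an output
directory is set).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import io as mio
from .datatypes import PhenotypeTable
from .greml import compare_models, fdr_adjust, fit_greml
from .kernels import (GenotypePCA, bend_to_pd, core_product, make_brm,
                      make_grm, prune_by_relatedness)
from .preprocess import harmonize_features, mad_filter, orq_transform, range_filter

logger = logging.getLogger(__name__)


@dataclass
class StudyConfig:
    """Paths, trait list and tuning knobs for a full study run.

    Either raw sources (``genotypes`` PLINK prefix, ``features`` TSV) or
    precomputed kernels (``grm_prefix``/``brm_prefix`` GCTA triplets) may be
    given; precomputed kernels short-circuit construction.  ``covariates``
    name phenotype-table columns (non-numeric ones are dummy-coded);
    ``batch_col`` adds scanner indicators as fixed effects and drives
    harmonization.
    """

    phenotypes: str
    traits: list[str]
    genotypes: str | None = None
    features: str | None = None
    grm_prefix: str | None = None
    brm_prefix: str | None = None
    covariates: list[str] = field(default_factory=list)
    batch_col: str | None = None
    n_pcs: int = 20
    relatedness_cutoff: float = 0.05
    mad_k: float = 4.0
    trait_ranges: dict = field(default_factory=dict)  # trait -> [min, max]
    models: list[int] = field(default_factory=lambda: [1, 2])
    harmonize: bool = True
    denominator_includes_covariance: bool = True
    max_iter: int = 200
    tol: float = 1e-8
    seed: int = 0
    out_dir: str | None = None

    @classmethod
    def from_yaml(cls, path: str | Path) -> "StudyConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        return cls(**raw)


@dataclass
class StudyResult:
    """Per-model estimate tables plus the Model 1 vs Model 2 comparison."""

    estimates: pd.DataFrame
    comparison: pd.DataFrame | None
    subject_counts: dict

    def write(self, out_dir: str | Path) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        for model in sorted(self.estimates["model"].unique()):
            sub = self.estimates[self.estimates["model"] == model]
            sub.to_csv(out / f"model{model}_estimates.tsv", sep="\t",
                       index=False, na_rep="NA", float_format="%.6g")
        if self.comparison is not None:
            self.comparison.to_csv(out / "model_comparison.tsv", sep="\t",
                                   index=False, na_rep="NA", float_format="%.6g")


def _build_design(pheno: PhenotypeTable, covariates, batch_col, pcs):
    """Fixed-effect design: intercept, covariates (dummied), batch, PCs.

    Returns (matrix, column names); rows align with the table.
    """
    cols = [pd.Series(1.0, index=pheno.data.index, name="intercept")]
    names = ["intercept"]
    use = list(covariates)
    if batch_col and batch_col not in use:
        use.append(batch_col)
    for c in use:
        col = pheno.data[c]
        if pd.api.types.is_numeric_dtype(col):
            cols.append(col.astype(float))
            names.append(c)
        else:
            dummies = pd.get_dummies(col, prefix=c, drop_first=True, dtype=float)
            for name in dummies.columns:
                cols.append(dummies[name])
                names.append(name)
    X = pd.concat(cols, axis=1).to_numpy(dtype=float)
    if pcs is not None and pcs.shape[1]:
        X = np.column_stack([X, pcs])
        names += [f"PC{i + 1}" for i in range(pcs.shape[1])]
    return X, names


def run_study(config: StudyConfig) -> StudyResult:
    """Execute the full pruning -> harmonization -> kernels -> REML workflow."""
    counts = {}
    pheno = mio.read_table(config.phenotypes, role="phenotype")
    for trait in config.traits:
        if trait not in pheno.data.columns:
            raise ValueError(f"trait {trait!r} missing from phenotype table")
    for cov in config.covariates:
        if cov not in pheno.data.columns:
            raise ValueError(f"covariate {cov!r} missing from phenotype table")

    geno = mio.read_plink(config.genotypes) if config.genotypes else None
    grm = mio.read_grm_bin(config.grm_prefix, "GRM") if config.grm_prefix else None
    features = mio.read_table(config.features, role="feature") if config.features else None
    brm = mio.read_grm_bin(config.brm_prefix, "BRM") if config.brm_prefix else None

    sources = [s for s in (geno, grm, features, brm, pheno) if s is not None]
    aligned = mio.align_subjects(*sources)
    it = iter(aligned)
    geno = next(it) if geno is not None else None
    grm = next(it) if grm is not None else None
    features = next(it) if features is not None else None
    brm = next(it) if brm is not None else None
    pheno = next(it)
    counts["aligned"] = pheno.n_subjects
    logger.info("aligned subject set: %d", counts["aligned"])

    if grm is None:
        if geno is None:
            raise ValueError("either genotypes or a precomputed GRM is required")
        grm = make_grm(geno)

    kept = prune_by_relatedness(grm, config.relatedness_cutoff)
    counts["after_pruning"] = len(kept)
    logger.info("relatedness pruning at %.3g kept %d of %d subjects",
                config.relatedness_cutoff, len(kept), grm.n_subjects)
    grm = grm.subset(kept)
    pheno = pheno.subset(kept)
    if geno is not None:
        geno = geno.subset(kept)
    if features is not None:
        features = features.subset(kept)
    if brm is not None:
        brm = brm.subset(kept)

    batch_labels = None
    if config.batch_col:
        batch_labels = pheno.data[config.batch_col].to_numpy()

    if brm is None:
        if features is None:
            raise ValueError("either features or a precomputed BRM is required")
        if config.harmonize and batch_labels is not None:
            protect = _protection_covariates(pheno, config)
            features = harmonize_features(features, batch_labels, protect)
            logger.info("harmonized %d features across %d batches",
                        features.n_features, len(np.unique(batch_labels)))
        brm = make_brm(features)

    pcs = None
    if geno is not None and config.n_pcs > 0:
        pcs = GenotypePCA(n_components=config.n_pcs).fit_transform(geno)

    X_full, design_names = _build_design(pheno, config.covariates,
                                         config.batch_col, pcs)

    core = None
    if 2 in config.models:
        core = core_product(bend_to_pd(grm), bend_to_pd(brm))

    rows = []
    ll_pairs = {}
    rbg_rows = {}
    for trait in config.traits:
        y_raw = pd.to_numeric(pheno.data[trait], errors="coerce").to_numpy(dtype=float)
        lo, hi = config.trait_ranges.get(trait, (None, None))
        y = y_raw.copy()
        y[range_filter(y, lo, hi)] = np.nan
        y[mad_filter(y, k=config.mad_k)] = np.nan
        ok = ~np.isnan(y) & ~np.isnan(X_full).any(axis=1)
        y[~ok] = np.nan
        y[ok] = orq_transform(y[ok])
        counts[f"n_{trait}"] = int(ok.sum())
        logger.info("trait %s: %d complete cases", trait, int(ok.sum()))

        fits = {}
        for model in sorted(config.models):
            kernels = [grm, brm] if model == 1 else [grm, brm, core]
            fit = fit_greml(y, X_full, kernels, max_iter=config.max_iter,
                            tol=config.tol,
                            denominator_includes_covariance=config.denominator_includes_covariance)
            fits[model] = fit
            m2, h2 = fit.variance_proportions()
            row = {
                "trait": trait, "model": model, "n": fit.n_,
                "converged": fit.converged_,
                "loglik": fit.loglik_,
                **{k: v for k, v in fit.varcomp_.items()},
                "h2": h2.value, "h2_se": h2.se, "h2_p": h2.p_value,
                "m2": m2.value, "m2_se": m2.se, "m2_p": m2.p_value,
            }
            if model == 2:
                try:
                    r = fit.effect_correlation()
                    row.update({"r_bg": r.value, "r_bg_se": r.se,
                                "r_bg_p": r.p_value, "r_bg_reliable": r.reliable})
                except ValueError:
                    row.update({"r_bg": np.nan, "r_bg_se": np.nan,
                                "r_bg_p": np.nan, "r_bg_reliable": False})
                rbg_rows[trait] = row
            if not fit.converged_:
                logger.warning("trait %s model %d did not converge", trait, model)
            rows.append(row)
        if 1 in fits and 2 in fits:
            ll_pairs[trait] = (fits[1].loglik_, fits[2].loglik_)

    estimates = pd.DataFrame(rows)
    # FDR families: one per p-value column within each model, across traits
    for model in sorted(config.models):
        sel = estimates["model"] == model
        for col in ("h2_p", "m2_p", "r_bg_p"):
            if col in estimates.columns:
                vals = estimates.loc[sel, col]
                if vals.notna().all() and len(vals):
                    estimates.loc[sel, col.replace("_p", "_p_fdr")] = \
                        fdr_adjust(vals.to_numpy())

    comparison = None
    if ll_pairs:
        traits = list(ll_pairs)
        comparison = compare_models([ll_pairs[t][0] for t in traits],
                                    [ll_pairs[t][1] for t in traits], traits)
        rbg = pd.DataFrame([{ "trait": t,
                              "r_bg": rbg_rows[t]["r_bg"],
                              "r_bg_se": rbg_rows[t]["r_bg_se"],
                              "r_bg_p": rbg_rows[t]["r_bg_p"]}
                            for t in traits])
        ok = rbg["r_bg_p"].notna()
        rbg["r_bg_p_fdr"] = np.nan
        if ok.any():
            rbg.loc[ok, "r_bg_p_fdr"] = fdr_adjust(rbg.loc[ok, "r_bg_p"].to_numpy())
        comparison = comparison.merge(rbg, on="trait")

    result = StudyResult(estimates, comparison, counts)
    if config.out_dir:
        result.write(config.out_dir)
    return result


def _protection_covariates(pheno: PhenotypeTable, config: StudyConfig):
    """Numeric design protecting outcomes and covariates during harmonization.

    Mirrors the practice of adding all outcome measures plus demographic
    covariates so harmonization does not strip biological variance; rows
    with missing entries are mean-filled for the harmonization design only.
    """
    cols = []
    for c in list(config.traits) + [c for c in config.covariates]:
        col = pd.to_numeric(pheno.data[c], errors="coerce") \
            if not pd.api.types.is_numeric_dtype(pheno.data[c]) else pheno.data[c]
        if pd.api.types.is_numeric_dtype(col):
            filled = col.astype(float).fillna(col.astype(float).mean())
            cols.append(filled.to_numpy())
        else:
            dummies = pd.get_dummies(pheno.data[c], drop_first=True, dtype=float)
            cols.extend(dummies[name].to_numpy() for name in dummies.columns)
    if not cols:
        return None
    C = np.column_stack(cols)
    keep = C.std(axis=0) > 0
    return C[:, keep] if keep.any() else None


def render_report(result: StudyResult) -> str:
    """Human-readable study summary (deterministic: trait then model order).

    Per trait: dot-and-interval lines of h2 +/- SE and m2 +/- SE for each
    fitted model, then a model-comparison block with the LRT and the effect
    correlation when Model 2 was fitted.
    """
    est = result.estimates
    if not len(est):
        raise ValueError("no result rows to report")
    lines = ["Variance decomposition by genomic and brain similarity",
             "=" * 56, ""]
    for trait in sorted(est["trait"].unique()):
        lines.append(f"{trait}")
        sub = est[est["trait"] == trait].sort_values("model")
        for _, row in sub.iterrows():
            flag = "" if row["converged"] else "  [did not converge]"
            lines.append(f"  model {int(row['model'])}  "
                         f"h2 = {row['h2']:.3f} +/- {row['h2_se']:.3f}   "
                         f"m2 = {row['m2']:.3f} +/- {row['m2_se']:.3f}   "
                         f"(n = {int(row['n'])}){flag}")
        lines.append("")
    if result.comparison is not None and len(result.comparison):
        lines += ["Model comparison (covariance of genomic and brain effects)",
                  "-" * 56]
        for _, row in result.comparison.sort_values("trait").iterrows():
            if np.isnan(row["r_bg"]):
                corr = "r_bg unavailable (fit unreliable)"
            else:
                corr = (f"r_bg = {row['r_bg']:.3f} +/- {row['r_bg_se']:.3f}, "
                        f"adj. p = {row['r_bg_p_fdr']:.3f}")
            lines.append(f"  {row['trait']}: LRT = {row['lrt_stat']:.2f}, "
                         f"adj. p = {row['lrt_p_fdr']:.3f}; {corr}")
    else:
        lines.append("Model comparison: not available (Model 2 not fitted).")
    return "\n".join(lines) + "\n"
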