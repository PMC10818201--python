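"""Similarity-kernel construction and transformation.

The genomic relatedness matrix (GRM) is the average cross-product of
column-standardized allele counts, ``G G' / n_snps``; the brain relatedness
matrix (BRM) applies the identical formula to standardized vertex-wise
cortical-thickness values.  The CORE kernel is the symmetrized product of
the Cholesky factors of the two (positive-definite-bent) kernels; its
coefficient in a mixed model is the covariance of the two random effects.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.utils.validation import check_is_fitted

from .datatypes import FeatureMatrix, GenotypeMatrix, RelatednessMatrix

logger = logging.getLogger(__name__)


class NotPositiveDefiniteError(np.linalg.LinAlgError):
    """Kernel is not positive definite; bend it first (see :func:`bend_to_pd`)."""


def standardize_columns(matrix: np.ndarray, return_kept: bool = False):
    """Column-wise z-scores with the population (divisor-``n``) standard deviation.

    Zero-variance columns carry no similarity information and are dropped
    with a warning rather than raising.  With ``return_kept=True`` the index
    of retained columns is returned as well.
    """
    M = np.asarray(matrix, dtype=float)
    if M.ndim != 2 or M.shape[0] < 2:
        raise ValueError("need a 2-d matrix with at least 2 subjects")
    if np.isnan(M).any():
        raise ValueError("impute missing entries before standardizing")
    mean = M.mean(axis=0)
    sd = M.std(axis=0)  # population sd: trace(GRM)/n is then exactly 1
    kept = np.flatnonzero(sd > 0)
    if kept.size < sd.size:
        warnings.warn(f"dropping {sd.size - kept.size} zero-variance column(s)",
                      UserWarning, stacklevel=2)
    Z = (M[:, kept] - mean[kept]) / sd[kept]
    return (Z, kept) if return_kept else Z


def relatedness_from_matrix(matrix: np.ndarray, kind: str,
                            subject_ids=None) -> RelatednessMatrix:
    """Cross-product kernel ``M M' / n_markers`` from a standardized matrix."""
    M = np.asarray(matrix, dtype=float)
    if M.ndim != 2 or M.shape[0] < 2:
        raise ValueError("need at least 2 subjects to build a kernel")
    if M.shape[1] < 1:
        raise ValueError("need at least 1 marker column")
    n_markers = M.shape[1]
    values = (M @ M.T) / n_markers
    if subject_ids is None:
        subject_ids = np.array([f"S{i}" for i in range(M.shape[0])])
    return RelatednessMatrix(np.asarray(subject_ids), values, kind, n_markers)


def make_grm(geno: GenotypeMatrix) -> RelatednessMatrix:
    """GRM from allele counts: mean-impute, standardize, cross-product."""
    Z = standardize_columns(geno.imputed())
    return relatedness_from_matrix(Z, "GRM", geno.subject_ids)


def make_brm(features: FeatureMatrix) -> RelatednessMatrix:
    """BRM from continuous brain features (same formula as the GRM)."""
    values = features.values
    if np.isnan(values).any():
        col_mean = np.nanmean(values, axis=0)
        values = np.where(np.isnan(values), col_mean, values)
    Z = standardize_columns(values)
    return relatedness_from_matrix(Z, "BRM", features.subject_ids)


def prune_by_relatedness(grm: RelatednessMatrix, cutoff: float = 0.05) -> np.ndarray:
    """Greedily drop subjects until no pair has relatedness >= ``cutoff``.

    At each step the subject participating in the most over-cutoff pairs is
    removed (ties broken by dropping the later subject in id order), which
    retains the maximum unrelated set on clique-structured relatedness.
    Default cutoff 0.05 targets familial or cryptic relatedness.
    """
    if cutoff <= 0:
        raise ValueError("cutoff must be positive")
    n = grm.n_subjects
    adj = (grm.values >= cutoff)
    np.fill_diagonal(adj, False)
    alive = np.ones(n, dtype=bool)
    while True:
        degree = (adj & alive[None, :] & alive[:, None]).sum(axis=1)
        degree[~alive] = -1
        worst = degree.max()
        if worst <= 0:
            break
        # np.argmax takes the first maximum; we want the later subject on ties
        worst_idx = np.flatnonzero(degree == worst)[-1]
        alive[worst_idx] = False
    if not alive.any():
        warnings.warn("all subjects removed by relatedness pruning", UserWarning)
    return grm.subject_ids[alive]


def bend_to_pd(matrix: RelatednessMatrix, floor: float | None = None) -> RelatednessMatrix:
    """Clip the eigenvalues of a kernel at a small positive floor.

    Default floor is ``1e-6`` times the mean eigenvalue (trace / n).  Inputs
    already satisfying the floor are returned unchanged, which makes the
    operation idempotent; a 1% relative slack on the floor absorbs the tiny
    trace shift clipping itself introduces.
    """
    values = matrix.values
    scale = max(1.0, float(np.abs(values).max()))
    if np.abs(values - values.T).max() > 1e-8 * scale:
        raise ValueError("bend_to_pd requires a symmetric matrix")
    eigval, eigvec = np.linalg.eigh((values + values.T) / 2.0)
    if floor is None:
        floor = 1e-6 * float(eigval.mean())
        if floor <= 0:
            floor = 1e-6
    if eigval.min() >= floor * 0.99:
        return matrix
    clipped = np.maximum(eigval, floor)
    bent = (eigvec * clipped) @ eigvec.T
    bent = (bent + bent.T) / 2.0
    return RelatednessMatrix(matrix.subject_ids, bent, matrix.kind, matrix.n_markers)


def core_product(grm_pd: RelatednessMatrix, brm_pd: RelatednessMatrix) -> RelatednessMatrix:
    """Symmetrized product of the Cholesky factors of two PD kernels.

    With lower-triangular factors ``L_G`` and ``L_B``, returns
    ``L_G L_B' + L_B L_G'``.  The symmetrization makes ``var(y)`` well
    defined; the factor 2 is absorbed by the covariance coefficient, so the
    fitted coefficient on this kernel is the effect covariance itself.
    """
    if not np.array_equal(grm_pd.subject_ids, brm_pd.subject_ids):
        raise ValueError("kernels must share the same ordered subject set")
    try:
        L_g = np.linalg.cholesky(grm_pd.values)
        L_b = np.linalg.cholesky(brm_pd.values)
    except np.linalg.LinAlgError as exc:
        raise NotPositiveDefiniteError(
            "Cholesky failed: bend the kernels to positive definite first"
        ) from exc
    C = L_g @ L_b.T
    return RelatednessMatrix(grm_pd.subject_ids, C + C.T, "CORE")


@dataclass
class OffdiagCorrelation:
    """Pearson correlation of two kernels' strict lower triangles."""

    r: float
    ci_low: float
    ci_high: float
    n_pairs: int


def offdiag_correlation(a: RelatednessMatrix, b: RelatednessMatrix,
                        confidence: float = 0.95) -> OffdiagCorrelation:
    """Pearson r between off-diagonal kernel elements, with a Fisher-z CI.

    The CI treats the n(n-1)/2 pairs as independent, matching the simple
    descriptive use; dependence among pairs sharing a subject is ignored.
    """
    if not np.array_equal(a.subject_ids, b.subject_ids):
        raise ValueError("kernels must share the same ordered subject set")
    if a.n_subjects < 3:
        raise ValueError("need at least 3 subjects")
    x, y = a.offdiag(), b.offdiag()
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("off-diagonal elements are constant; correlation undefined")
    res = stats.pearsonr(x, y)
    ci = res.confidence_interval(confidence_level=confidence)
    return OffdiagCorrelation(float(res.statistic), float(ci.low), float(ci.high),
                              x.size)


class GenotypePCA(BaseEstimator, TransformerMixin):
    """Principal components of standardized genotypes (ancestry axes).

    Scores are ``U S`` from the thin SVD of the column-standardized
    allele-count matrix, ordered by decreasing variance; the leading
    components separate ancestral subpopulations and enter the mixed models
    as fixed-effect covariates against population stratification.

    Parameters
    ----------
    n_components : int, default 20
        Number of leading axes to keep.  If the matrix rank is lower, the
        available components are returned with a warning.
    """

    def __init__(self, n_components: int = 20):
        self.n_components = n_components

    @staticmethod
    def _as_array(G) -> np.ndarray:
        return G.imputed() if isinstance(G, GenotypeMatrix) else np.asarray(G, dtype=float)

    def fit(self, G, y=None):
        X = self._as_array(G)
        Z, kept = standardize_columns(X, return_kept=True)
        self.kept_columns_ = kept
        self.mean_ = X[:, kept].mean(axis=0)
        self.scale_ = X[:, kept].std(axis=0)
        U, s, Vt = np.linalg.svd(Z, full_matrices=False)
        tol = s.max(initial=0.0) * max(Z.shape) * np.finfo(float).eps
        rank = int((s > tol).sum())
        k = min(self.n_components, rank)
        if k < self.n_components:
            warnings.warn(f"rank {rank} < requested {self.n_components} components;"
                          f" returning {k}", UserWarning)
        self.n_components_ = k
        self.singular_values_ = s[:k]
        self.components_ = Vt[:k]
        self.scores_ = U[:, :k] * s[:k]
        return self

    def transform(self, G):
        check_is_fitted(self, "components_")
        X = self._as_array(G)
        Z = (X[:, self.kept_columns_] - self.mean_) / self.scale_
        return Z @ self.components_.T

    def fit_transform(self, G, y=None, **fit_params):
        return self.fit(G).scores_


def genotype_pcs(geno: GenotypeMatrix, k: int = 20) -> np.ndarray:
    """Top-``k`` ancestry principal-component scores of a genotype matrix."""
    return GenotypePCA(n_components=k).fit_transform(geno)
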