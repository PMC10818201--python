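"""Outcome preprocessing and scanner/batch harmonization.

Outcomes are cleaned per trait: an optional plausibility range filter,
robust outlier masking at k scaled median absolute deviations (default
k = 4), complete-case dropping, then a rank-based ordered-quantile (ORQ)
mapping to standard-normal quantiles.  Vertex features are harmonized
across scanners with a parametric empirical-Bayes location-scale model
(ComBat) before kernel construction, protecting specified biological
covariates.
"""

from __future__ import annotations

import logging
import warnings

import numpy as np
from scipy import stats
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.utils.validation import check_is_fitted

from .datatypes import FeatureMatrix

logger = logging.getLogger(__name__)

#: consistency constant making the MAD estimate the normal sd
MAD_SCALE = 1.4826


def mad_filter(values, k: float = 4.0, scale: float = MAD_SCALE) -> np.ndarray:
    """Boolean mask of entries more than ``k`` scaled MADs from the median.

    Missing (NaN) entries are never masked.  An all-equal vector has zero
    MAD and, by convention, masks nothing.
    """
    if k <= 0:
        raise ValueError("k must be positive")
    x = np.asarray(values, dtype=float)
    finite = ~np.isnan(x)
    if finite.sum() < 3:
        raise ValueError("need at least 3 non-missing values")
    med = np.median(x[finite])
    mad = scale * np.median(np.abs(x[finite] - med))
    mask = np.zeros(x.shape, dtype=bool)
    if mad > 0:
        mask[finite] = np.abs(x[finite] - med) > k * mad
    return mask


def range_filter(values, min_value: float | None = None,
                 max_value: float | None = None) -> np.ndarray:
    """Boolean mask of entries outside a closed plausibility range."""
    x = np.asarray(values, dtype=float)
    mask = np.zeros(x.shape, dtype=bool)
    finite = ~np.isnan(x)
    if min_value is not None:
        mask |= finite & (x < min_value)
    if max_value is not None:
        mask |= finite & (x > max_value)
    return mask


def orq_transform(values, offset: float = 0.5) -> np.ndarray:
    """Ordered-quantile normalization: ranks mapped to normal quantiles.

    Non-missing entries receive ``Phi^-1((r - offset) / n)`` where ``r`` is
    the average-for-ties rank among the ``n`` non-missing values; missing
    entries pass through untouched.  Strictly monotone on distinct inputs.
    """
    x = np.asarray(values, dtype=float)
    out = np.full(x.shape, np.nan)
    finite = ~np.isnan(x)
    n = int(finite.sum())
    if n < 3:
        raise ValueError("need at least 3 non-missing values")
    obs = x[finite]
    if np.ptp(obs) == 0:
        raise ValueError("all values identical; ranks undefined")
    ranks = stats.rankdata(obs, method="average")
    out[finite] = stats.norm.ppf((ranks - offset) / n)
    return out


class OrderedQuantileNormalizer(BaseEstimator, TransformerMixin):
    """Transformer form of :func:`orq_transform`.

    ``fit`` memorizes the empirical value-to-normal-quantile map of the
    training vector; ``transform`` interpolates new values linearly on that
    map (extrapolating flat at the extremes).  ``fit_transform`` reproduces
    the exact in-sample ORQ mapping.
    """

    def __init__(self, offset: float = 0.5):
        self.offset = offset

    def fit(self, X, y=None):
        x = np.asarray(X, dtype=float).ravel()
        obs = x[~np.isnan(x)]
        if obs.size < 3:
            raise ValueError("need at least 3 non-missing values")
        order = np.sort(obs)
        ranks = stats.rankdata(order, method="average")
        self.train_values_ = order
        self.train_quantiles_ = stats.norm.ppf((ranks - self.offset) / obs.size)
        return self

    def transform(self, X):
        check_is_fitted(self, "train_values_")
        x = np.asarray(X, dtype=float).ravel()
        out = np.full(x.shape, np.nan)
        finite = ~np.isnan(x)
        out[finite] = np.interp(x[finite], self.train_values_, self.train_quantiles_)
        return out

    def fit_transform(self, X, y=None, **fit_params):
        self.fit(X)
        x = np.asarray(X, dtype=float).ravel()
        out = np.full(x.shape, np.nan)
        finite = ~np.isnan(x)
        obs = x[finite]
        ranks = stats.rankdata(obs, method="average")
        out[finite] = stats.norm.ppf((ranks - self.offset) / obs.size)
        return out


class MADOutlierFilter(BaseEstimator, TransformerMixin):
    """Transformer form of :func:`mad_filter`: outliers are set to NaN."""

    def __init__(self, k: float = 4.0, scale: float = MAD_SCALE):
        self.k = k
        self.scale = scale

    def fit(self, X, y=None):
        x = np.asarray(X, dtype=float).ravel()
        finite = ~np.isnan(x)
        if finite.sum() < 3:
            raise ValueError("need at least 3 non-missing values")
        self.median_ = float(np.median(x[finite]))
        self.mad_ = self.scale * float(np.median(np.abs(x[finite] - self.median_)))
        return self

    def transform(self, X):
        check_is_fitted(self, "median_")
        x = np.asarray(X, dtype=float).ravel().copy()
        if self.mad_ > 0:
            with np.errstate(invalid="ignore"):
                x[np.abs(x - self.median_) > self.k * self.mad_] = np.nan
        return x


class ComBatHarmonizer(BaseEstimator, TransformerMixin):
    """Parametric empirical-Bayes location-scale harmonization across batches.

    Per feature, values are modeled as covariate effects plus a batch
    location shift ``gamma`` and multiplicative scale ``delta``.  Raw
    per-batch estimates are shrunk across features within each batch
    (normal prior on ``gamma``, inverse-gamma on ``delta^2``, moment-matched
    hyperparameters, iterated conditional modes), then removed; covariate
    effects listed for protection are restored untouched.  After
    harmonization, per-batch residual means are ~0 and residual variances
    ~equal across batches.

    Parameters
    ----------
    empirical_bayes : bool, default True
        Shrink batch effects across features before removal; with False the
        raw per-batch estimates are removed (no pooling).
    tol, max_iter : convergence controls of the conditional-mode iteration.
    """

    def __init__(self, empirical_bayes: bool = True, tol: float = 1e-6,
                 max_iter: int = 200):
        self.empirical_bayes = empirical_bayes
        self.tol = tol
        self.max_iter = max_iter

    # -- estimation -------------------------------------------------------

    def fit(self, X, y=None, *, batch, covariates=None):
        """Estimate batch and covariate effects.

        Parameters
        ----------
        X : (n_subjects, n_features) array of feature values.
        batch : length-n vector of batch/scanner labels.
        covariates : optional (n_subjects, q) design of biological
            covariates to protect (no intercept column needed).
        """
        X = np.asarray(X, dtype=float)
        n, p = X.shape
        batch = np.asarray(batch)
        self.batches_, batch_idx = np.unique(batch, return_inverse=True)
        n_batch = self.batches_.size
        counts = np.bincount(batch_idx, minlength=n_batch)
        for b, c in zip(self.batches_, counts):
            if c < 2:
                raise ValueError(f"batch {b!r} has {c} subject(s); need at least 2")
        if covariates is not None:
            C = np.asarray(covariates, dtype=float)
            if C.ndim == 1:
                C = C[:, None]
            cond = np.linalg.cond(np.column_stack([np.ones(n), C]))
            logger.info("harmonization covariate design condition number: %.3g", cond)
        else:
            C = np.empty((n, 0))
        self.n_covariates_ = C.shape[1]

        # full design: one indicator per batch (no intercept) + covariates
        D = np.column_stack([(batch_idx == i).astype(float) for i in range(n_batch)] + [C])
        if np.linalg.matrix_rank(D) < D.shape[1]:
            raise ValueError("covariate design is rank deficient given batch indicators")
        B_hat, *_ = np.linalg.lstsq(D, X, rcond=None)
        gamma_hat_fit = B_hat[:n_batch]           # per-batch locations, n_batch x p
        self.beta_ = B_hat[n_batch:]              # covariate coefficients, q x p
        w = counts / n
        self.grand_mean_ = w @ gamma_hat_fit      # weighted grand location per feature
        resid = X - D @ B_hat
        self.pooled_var_ = (resid ** 2).mean(axis=0)
        if (self.pooled_var_ <= 0).any():
            raise ValueError("zero residual variance for some feature(s)")

        stand_mean = self.grand_mean_[None, :] + C @ self.beta_
        Z = (X - stand_mean) / np.sqrt(self.pooled_var_)[None, :]

        gamma_hat = np.empty((n_batch, p))
        delta_sq_hat = np.empty((n_batch, p))
        for i in range(n_batch):
            Zi = Z[batch_idx == i]
            gamma_hat[i] = Zi.mean(axis=0)
            delta_sq_hat[i] = Zi.var(axis=0, ddof=1)
        self.gamma_hat_ = gamma_hat
        self.delta_sq_hat_ = delta_sq_hat

        if self.empirical_bayes and p >= 2:
            self.gamma_star_, self.delta_sq_star_ = self._shrink(
                Z, batch_idx, counts, gamma_hat, delta_sq_hat)
        else:
            self.gamma_star_, self.delta_sq_star_ = gamma_hat, delta_sq_hat
        return self

    def _shrink(self, Z, batch_idx, counts, gamma_hat, delta_sq_hat):
        """Moment-matched EB shrinkage of per-batch effects across features."""
        n_batch, p = gamma_hat.shape
        gamma_star = np.empty_like(gamma_hat)
        delta_star = np.empty_like(delta_sq_hat)
        for i in range(n_batch):
            g, d2 = gamma_hat[i], delta_sq_hat[i]
            g_bar, tau_sq = g.mean(), g.var(ddof=1)
            m, s2 = d2.mean(), d2.var(ddof=1)
            if s2 <= 0:
                lam, theta = np.inf, np.inf  # degenerate prior -> keep m
            else:
                lam = (m * m + 2 * s2) / s2          # inverse-gamma shape
                theta = (m ** 3 + m * s2) / s2       # inverse-gamma scale
            n_i = counts[i]
            Zi = Z[batch_idx == i]
            g_new = g.copy()
            d_new = d2.copy()
            if tau_sq <= 0:
                g_new = np.full(p, g_bar)
            for _ in range(self.max_iter):
                g_old, d_old = g_new.copy(), d_new.copy()
                if tau_sq > 0:
                    g_new = (n_i * tau_sq * g + d_new * g_bar) / (n_i * tau_sq + d_new)
                sse = ((Zi - g_new[None, :]) ** 2).sum(axis=0)
                if np.isfinite(lam):
                    d_new = (theta + 0.5 * sse) / (n_i / 2 + lam - 1)
                else:
                    d_new = sse / max(n_i - 1, 1)
                change = max(np.abs(g_new - g_old).max(initial=0.0),
                             np.abs(d_new - d_old).max(initial=0.0))
                if change < self.tol:
                    break
            gamma_star[i], delta_star[i] = g_new, d_new
        return gamma_star, delta_star

    # -- adjustment -------------------------------------------------------

    def transform(self, X, *, batch, covariates=None):
        check_is_fitted(self, "gamma_star_")
        X = np.asarray(X, dtype=float)
        batch = np.asarray(batch)
        if covariates is not None:
            C = np.asarray(covariates, dtype=float)
            if C.ndim == 1:
                C = C[:, None]
        else:
            C = np.empty((X.shape[0], 0))
        lookup = {b: i for i, b in enumerate(self.batches_)}
        try:
            batch_idx = np.array([lookup[b] for b in batch])
        except KeyError as exc:
            raise ValueError(f"unseen batch label {exc.args[0]!r}") from exc
        stand_mean = self.grand_mean_[None, :] + C @ self.beta_
        sd = np.sqrt(self.pooled_var_)[None, :]
        Z = (X - stand_mean) / sd
        Z_adj = (Z - self.gamma_star_[batch_idx]) / np.sqrt(self.delta_sq_star_)[batch_idx]
        return Z_adj * sd + stand_mean

    def fit_transform(self, X, y=None, **params):
        return self.fit(X, **params).transform(X, **params)


def harmonize_features(features: FeatureMatrix, batch_labels=None,
                       covariates=None, empirical_bayes: bool = True) -> FeatureMatrix:
    """Harmonize a :class:`FeatureMatrix` across scanner batches.

    With fewer than two batches there is nothing to harmonize and the input
    values are returned unchanged (with a warning).
    """
    if batch_labels is None:
        batch_labels = features.batch_labels
    if batch_labels is None:
        raise ValueError("no batch labels available")
    batch_labels = np.asarray(batch_labels)
    if np.unique(batch_labels).size < 2:
        warnings.warn("fewer than 2 batches; returning features unchanged",
                      UserWarning)
        return FeatureMatrix(features.subject_ids, features.feature_ids,
                             features.values.copy(), batch_labels)
    model = ComBatHarmonizer(empirical_bayes=empirical_bayes)
    values = model.fit_transform(features.values, batch=batch_labels,
                                 covariates=covariates)
    return FeatureMatrix(features.subject_ids, features.feature_ids,
                         values, batch_labels)


def prepare_outcome(values, mad_k: float = 4.0, min_value: float | None = None,
                    max_value: float | None = None) -> np.ndarray:
    """Range filter, then MAD outlier masking, then ORQ normalization.

    Masked and missing entries come back as NaN; callers drop them
    per-trait (complete-case analysis).
    """
    x = np.asarray(values, dtype=float).copy()
    x[range_filter(x, min_value, max_value)] = np.nan
    x[mad_filter(x, k=mad_k)] = np.nan
    return orq_transform(x)
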