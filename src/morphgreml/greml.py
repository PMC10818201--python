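"""Restricted maximum likelihood for multi-kernel variance components.

Model 1 decomposes a trait as ``y = X beta + g + b + e`` with
``var(y) = sigma2_g GRM + sigma2_b BRM + sigma2_e I``; Model 2 (CORE GREML)
adds ``sigma_bg CORE`` where CORE is the symmetrized Cholesky cross-product
kernel and ``sigma_bg`` the covariance of the genomic and morphological
random effects.  Estimation maximizes the restricted likelihood by
average-information (AI) updates after one expectation-maximization burn-in
step, with step-halving on likelihood decreases.  The inverse AI matrix at
convergence supplies asymptotic standard errors; ratios (heritability h2,
morphometricity m2, effect correlation r_bg) get Delta-method SEs.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import linalg, stats
from sklearn.base import BaseEstimator
from sklearn.utils.validation import check_is_fitted
from statsmodels.stats.multitest import multipletests

from .datatypes import RelatednessMatrix
from .kernels import NotPositiveDefiniteError

logger = logging.getLogger(__name__)


class ConvergenceOrderingError(ValueError):
    """The wider model's log-likelihood fell below the nested model's."""


# ---------------------------------------------------------------------------
# Design-matrix utilities
# ---------------------------------------------------------------------------

def clean_design(X: np.ndarray) -> np.ndarray:
    """Drop linearly dependent columns so the design has full column rank.

    Column selection uses a rank-revealing pivoted QR; the retained span is
    unchanged, so REML values are invariant to the repair.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if X.shape[0] < X.shape[1]:
        raise ValueError("more fixed-effect columns than subjects")
    _, R, piv = linalg.qr(X, mode="economic", pivoting=True)
    diag = np.abs(np.diag(R))
    tol = diag.max(initial=0.0) * max(X.shape) * np.finfo(float).eps
    rank = int((diag > tol).sum())
    keep = np.sort(piv[:rank])
    return X[:, keep]


def _kernel_values(K) -> np.ndarray:
    return K.values if isinstance(K, RelatednessMatrix) else np.asarray(K, dtype=float)


# ---------------------------------------------------------------------------
# Restricted log-likelihood
# ---------------------------------------------------------------------------

def restricted_loglik(y, X, kernels, params) -> float:
    """Restricted log-likelihood (additive constant omitted).

    ``-(log|V| + log|X'V^-1 X| + y'Py) / 2`` with
    ``V = sum_k params_k * K_k`` and ``P`` the REML projection.  The kernel
    list must include the residual identity explicitly; raises
    :class:`NotPositiveDefiniteError` when V is not PD at ``params``.
    """
    y = np.asarray(y, dtype=float).ravel()
    X = clean_design(X)
    Ks = [_kernel_values(K) for K in kernels]
    params = np.asarray(params, dtype=float)
    if len(Ks) != params.size:
        raise ValueError("one parameter per kernel required")
    V = sum(th * K for th, K in zip(params, Ks))
    try:
        L = np.linalg.cholesky(V)
    except np.linalg.LinAlgError as exc:
        raise NotPositiveDefiniteError("V is not positive definite") from exc
    logdet_V = 2.0 * np.log(np.diag(L)).sum()
    A = linalg.solve_triangular(L, X, lower=True)
    u = linalg.solve_triangular(L, y, lower=True)
    M = A.T @ A  # X' V^-1 X
    sign, logdet_M = np.linalg.slogdet(M)
    if sign <= 0:
        raise NotPositiveDefiniteError("X'V^-1X is singular")
    Atu = A.T @ u
    quad = u @ u - Atu @ np.linalg.solve(M, Atu)
    return float(-0.5 * (logdet_V + logdet_M + quad))


class _ProjectedWorkspace:
    """REML quantities in the null-space basis of the fixed effects.

    With ``Q`` an orthonormal basis of the orthogonal complement of
    ``span(X)``, the REML projection is ``P = Q (Q'VQ)^-1 Q'``, so every
    likelihood/score/average-information quantity reduces to the
    ``(n - p)``-dimensional projected kernels ``Q'KQ`` (computed once per
    fit).  Working in this basis removes the singular direction that
    column-centered cross-product kernels share with the intercept and
    keeps evaluations well conditioned near the variance floor; the
    ``log|X'X|`` offset restores the ``log|V| + log|X'V^-1X|``
    normalization of :func:`restricted_loglik`.
    """

    def __init__(self, y, X, Ks):
        n, p = X.shape
        Qfull, _ = np.linalg.qr(X, mode="complete")
        self.Q = Qfull[:, p:]
        self.yp = self.Q.T @ y
        self.Kps = [np.ascontiguousarray(self.Q.T @ K @ self.Q) for K in Ks]
        _, logdet_xx = np.linalg.slogdet(X.T @ X)
        self.offset = -0.5 * logdet_xx
        self.m = n - p

    def state(self, theta):
        """Restricted log-likelihood, score and AI matrix at ``theta``."""
        Vp = sum(th * Kp for th, Kp in zip(theta, self.Kps))
        try:
            L = np.linalg.cholesky(Vp)
        except np.linalg.LinAlgError as exc:
            raise NotPositiveDefiniteError("V not PD") from exc
        Linv = linalg.solve_triangular(L, np.eye(self.m), lower=True)
        Vpinv = Linv.T @ Linv
        u = Vpinv @ self.yp
        ll = -0.5 * (2.0 * np.log(np.diag(L)).sum() + self.yp @ u) + self.offset
        k = len(self.Kps)
        score = np.empty(k)
        W = np.empty((self.m, k))
        for j, Kp in enumerate(self.Kps):
            w = Kp @ u
            W[:, j] = w
            # tr(PK) = tr(Vp^-1 Kp); y'PKPy = u'Kp u
            score[j] = -0.5 * (float(np.sum(Vpinv * Kp)) - u @ w)
        AI = 0.5 * (W.T @ Vpinv @ W)
        return ll, score, AI


def _gls_beta(y, X, Ks, theta):
    """Generalized least-squares fixed effects at the fitted components."""
    V = sum(th * K for th, K in zip(theta, Ks))
    L = np.linalg.cholesky(V)
    A = linalg.solve_triangular(L, X, lower=True)
    b = linalg.solve_triangular(L, y, lower=True)
    return np.linalg.solve(A.T @ A, A.T @ b)


@dataclass
class RatioEstimate:
    """A variance proportion or correlation with Delta-method inference."""

    name: str  # "m2", "h2" or "r_bg"
    value: float
    se: float
    p_value: float
    model: int
    reliable: bool = True


class GREML(BaseEstimator):
    """Average-information REML for genomic/morphological variance components.

    A scikit-learn style estimator: ``fit(X, y, kernels=[...])`` takes the
    fixed-effect design ``X`` and subject-aligned similarity kernels.
    Kernels of kind ``CORE`` get a sign-unconstrained coefficient (the
    effect covariance); all other coefficients are variances floored at
    ``var_floor_scale * var(y)``.  The residual identity kernel is always
    appended internally.

    Parameters
    ----------
    max_iter : int, default 200
        Iteration cap; hitting it sets ``converged_ = False`` (reported,
        not raised).
    tol : float, default 1e-8
        Convergence threshold on the restricted log-likelihood change.
    var_floor_scale : float, default 1e-6
        Variance floor as a fraction of the phenotypic variance.
    fix_covariance_zero : bool, default False
        Pin the CORE coefficient at 0 (Model 2 then reproduces Model 1).
    denominator_includes_covariance : bool, default True
        Whether ratio denominators add ``2 sigma_bg`` under Model 2 (the
        total phenotypic variance implied by the symmetrized CORE kernel).

    Attributes
    ----------
    theta_ : fitted components in kernel order plus residual.
    param_names_ : e.g. ``["sigma2_g", "sigma2_b", "sigma_bg", "sigma2_e"]``.
    acov_ : inverse average-information matrix (asymptotic covariance).
    loglik_ : maximized restricted log-likelihood (constant omitted).
    beta_ : GLS fixed-effect estimates at the final parameters.
    converged_, n_iter_ : convergence flag and iteration count.
    """

    def __init__(self, max_iter: int = 200, tol: float = 1e-8,
                 var_floor_scale: float = 1e-6,
                 fix_covariance_zero: bool = False,
                 denominator_includes_covariance: bool = True,
                 step_halvings: int = 30):
        self.max_iter = max_iter
        self.tol = tol
        self.var_floor_scale = var_floor_scale
        self.fix_covariance_zero = fix_covariance_zero
        self.denominator_includes_covariance = denominator_includes_covariance
        self.step_halvings = step_halvings

    # -- fitting ----------------------------------------------------------

    def fit(self, X, y, kernels, init=None):
        y = np.asarray(y, dtype=float).ravel()
        n = y.size
        X = clean_design(X)
        if X.shape[0] != n:
            raise ValueError("design and phenotype lengths differ")

        kinds = [K.kind if isinstance(K, RelatednessMatrix) else "GRM"
                 for K in kernels]
        names = []
        seen = {}
        for kind in kinds:
            base = {"GRM": "sigma2_g", "BRM": "sigma2_b", "CORE": "sigma_bg",
                    "IDENTITY": "sigma2_i"}[kind]
            seen[base] = seen.get(base, 0) + 1
            names.append(base if seen[base] == 1 else f"{base}{seen[base]}")
        names.append("sigma2_e")
        Ks = [np.ascontiguousarray(_kernel_values(K)) for K in kernels]
        Ks.append(np.eye(n))
        for K in Ks:
            if K.shape != (n, n):
                raise ValueError("kernel dimension does not match phenotype")
        is_cov = np.array([k == "CORE" for k in kinds] + [False])
        free = np.ones(len(Ks), dtype=bool)
        if self.fix_covariance_zero:
            free[is_cov] = False

        var_y = float(np.var(y))
        floor = self.var_floor_scale * var_y
        n_var = int((~is_cov).sum())
        if init is not None:
            theta = np.asarray(init, dtype=float).copy()
            if theta.size != len(Ks):
                raise ValueError("init length must match kernel count + residual")
        elif is_cov.any() and not self.fix_covariance_zero:
            # warm start at the nested no-covariance optimum so the wider
            # model can never converge below the model it nests
            nested = GREML(max_iter=self.max_iter, tol=self.tol,
                           var_floor_scale=self.var_floor_scale,
                           fix_covariance_zero=True,
                           step_halvings=self.step_halvings)
            nested.fit(X, y, kernels)
            theta = nested.theta_.copy()
        else:
            theta = np.where(is_cov, 0.0, var_y / n_var)

        def clip(th):
            th = th.copy()
            th[~is_cov] = np.maximum(th[~is_cov], floor)
            th[~free & is_cov] = 0.0
            return th

        proj = _ProjectedWorkspace(y, X, Ks)
        ll, score, AI = proj.state(theta)

        # one EM burn-in step: robust far from the optimum; the EM increment
        # theta^2/n (y'PKPy - tr(PK)) equals theta^2/n * 2*score
        em = clip(np.where(free, theta + (theta ** 2 / n) * 2.0 * score, theta))
        try:
            state_em = proj.state(em)
            if state_em[0] >= ll - 1e-8 * max(1.0, abs(ll)):
                ll, score, AI = state_em
                theta = em
        except NotPositiveDefiniteError:
            pass

        converged = False
        n_iter = 0
        for n_iter in range(1, self.max_iter + 1):
            # components at the floor that the AI step would push below it
            # are pinned and the reduced system re-solved; otherwise the
            # ill-conditioned full step overshoots and stalls
            idx = np.flatnonzero(free)
            while idx.size:
                AI_f = AI[np.ix_(idx, idx)]
                try:
                    delta = np.linalg.solve(AI_f, score[idx])
                except np.linalg.LinAlgError:
                    delta = np.linalg.pinv(AI_f) @ score[idx]
                at_floor = (~is_cov[idx]) & (theta[idx] <= floor * (1 + 1e-12))
                pushing_down = theta[idx] + delta < floor
                pin = at_floor & pushing_down
                if not pin.any():
                    break
                idx = idx[~pin]
            if idx.size == 0:
                converged = True
                break
            # quadratic-model prediction of the attainable gain; below
            # tolerance means the likelihood change criterion is met up to
            # evaluation noise (ll evaluations are only reproducible to
            # ~1e-7 near a floored component)
            pred_gain = 0.5 * float(score[idx] @ delta)
            if 0.0 <= pred_gain < self.tol:
                converged = True
                break
            # step acceptance allows a band of floating-point evaluation
            # noise so a genuinely uphill step is never rejected as a
            # spurious hairline decrease
            slack = 1e-9 * max(1.0, abs(ll))
            step = 1.0
            accepted = False
            last_ll = None
            for _ in range(self.step_halvings):
                prop = theta.copy()
                prop[idx] = theta[idx] + step * delta
                prop = clip(prop)
                try:
                    ll_new, score_new, AI_new = proj.state(prop)
                except NotPositiveDefiniteError:
                    step *= 0.5
                    continue
                last_ll = ll_new
                if ll_new >= ll - slack:
                    accepted = True
                    break
                step *= 0.5
            if not accepted:
                # AI direction exhausted; a negligible remaining change means
                # we are at the maximum, otherwise fall back to an EM step
                if last_ll is not None and abs(last_ll - ll) < self.tol:
                    converged = True
                    break
                prop = clip(np.where(free, theta + (theta ** 2 / n) * 2.0 * score,
                                     theta))
                try:
                    ll_new, score_new, AI_new = proj.state(prop)
                except NotPositiveDefiniteError:
                    break
                if ll_new < ll - slack:
                    break
            d_ll = abs(ll_new - ll)
            theta, ll, score, AI = prop, ll_new, score_new, AI_new
            if d_ll < self.tol:
                converged = True
                break
        if not converged:
            logger.warning("REML did not converge in %d iterations "
                           "(|dll| tolerance %.1e); estimates unreliable",
                           n_iter, self.tol)

        self.param_names_ = names
        self.theta_ = theta
        self.is_covariance_ = is_cov
        self.free_ = free
        self.floor_ = floor
        self.loglik_ = float(ll)
        self.beta_ = _gls_beta(y, X, Ks, theta)
        self.converged_ = converged
        self.n_iter_ = n_iter
        self.n_ = n
        self.model_ = 2 if is_cov.any() else 1
        acov = np.zeros((len(Ks), len(Ks)))
        idx = np.flatnonzero(free)
        AI_f = AI[np.ix_(idx, idx)]
        try:
            acov_f = np.linalg.inv(AI_f)
        except np.linalg.LinAlgError:
            acov_f = np.linalg.pinv(AI_f)
        acov[np.ix_(idx, idx)] = acov_f
        self.acov_ = (acov + acov.T) / 2.0
        return self

    # -- accessors --------------------------------------------------------

    @property
    def varcomp_(self) -> dict:
        check_is_fitted(self, "theta_")
        return dict(zip(self.param_names_, self.theta_.tolist()))

    def _param_index(self, name: str) -> int:
        try:
            return self.param_names_.index(name)
        except ValueError as exc:
            raise KeyError(f"no component named {name!r}; have {self.param_names_}") from exc

    def component_se(self, name: str) -> float:
        i = self._param_index(name)
        return float(np.sqrt(max(self.acov_[i, i], 0.0)))

    # -- derived quantities ----------------------------------------------

    def _denominator_gradient(self):
        """Total-variance denominator and its gradient w.r.t. theta."""
        grad = np.where(self.is_covariance_, 2.0, 1.0) \
            if self.denominator_includes_covariance \
            else np.where(self.is_covariance_, 0.0, 1.0)
        return float(grad @ self.theta_), grad

    def variance_proportions(self) -> list[RatioEstimate]:
        """Morphometricity m2 and heritability h2 with Delta-method SEs.

        Under Model 2 the default denominator is the total phenotypic
        variance implied by the symmetrized CORE kernel,
        ``sigma2_g + sigma2_b + 2 sigma_bg + sigma2_e``.
        """
        check_is_fitted(self, "theta_")
        D, dD = self._denominator_gradient()
        if D <= 0:
            raise ValueError("non-positive total variance; proportions undefined")
        out = []
        for name, label in (("sigma2_b", "m2"), ("sigma2_g", "h2")):
            i = self._param_index(name)
            value = self.theta_[i] / D
            grad = -value / D * dD
            grad[i] += 1.0 / D
            se = float(np.sqrt(max(grad @ self.acov_ @ grad, 0.0)))
            p = wald_p_value(value, se)
            out.append(RatioEstimate(label, float(value), se, p, self.model_))
        return out

    def effect_correlation(self) -> RatioEstimate:
        """Correlation of the genomic and morphological random effects.

        ``r_bg = sigma_bg / sqrt(sigma2_b sigma2_g)`` with a Delta-method SE
        from the full asymptotic covariance and a Wald test against zero.
        A fit with either variance at its floor is flagged unreliable, and
        values outside [-1, 1] are reported as-is with the same flag.
        """
        check_is_fitted(self, "theta_")
        ig = self._param_index("sigma2_g")
        ib = self._param_index("sigma2_b")
        ic = self._param_index("sigma_bg")
        s2g, s2b, sbg = self.theta_[ig], self.theta_[ib], self.theta_[ic]
        if s2g <= 0 or s2b <= 0:
            raise ValueError("both variances must be positive for r_bg")
        denom = np.sqrt(s2g * s2b)
        r = sbg / denom
        grad = np.zeros_like(self.theta_)
        grad[ic] = 1.0 / denom
        grad[ig] = -r / (2.0 * s2g)
        grad[ib] = -r / (2.0 * s2b)
        se = float(np.sqrt(max(grad @ self.acov_ @ grad, 0.0)))
        p = wald_p_value(r, se)
        at_floor = (s2g <= self.floor_ * (1 + 1e-9)) or (s2b <= self.floor_ * (1 + 1e-9))
        reliable = self.converged_ and not at_floor and abs(r) <= 1.0
        if not reliable:
            warnings.warn("effect correlation flagged unreliable "
                          "(boundary variance, |r|>1, or non-convergence)",
                          UserWarning)
        return RatioEstimate("r_bg", float(r), se, p, self.model_, reliable)

    def wald_component_test(self, name: str) -> float:
        """One-degree-of-freedom Wald p-value for a component against zero."""
        check_is_fitted(self, "theta_")
        i = self._param_index(name)
        return wald_p_value(float(self.theta_[i]), self.component_se(name))


def fit_greml(y, X, kernels, **options) -> GREML:
    """Functional wrapper: fit a :class:`GREML` model and return it.

    Rows with missing phenotype or design entries are dropped first
    (complete-case analysis); kernels are subset to the retained rows.
    """
    y = np.asarray(y, dtype=float).ravel()
    X = np.atleast_2d(np.asarray(X, dtype=float))
    keep = ~np.isnan(y) & ~np.isnan(X).any(axis=1)
    if not keep.all():
        idx = np.flatnonzero(keep)
        y, X = y[idx], X[idx]
        kernels = [K.values[np.ix_(idx, idx)] if not isinstance(K, RelatednessMatrix)
                   else RelatednessMatrix(K.subject_ids[idx],
                                          K.values[np.ix_(idx, idx)], K.kind,
                                          K.n_markers)
                   for K in kernels]
    return GREML(**options).fit(X, y, kernels)


# ---------------------------------------------------------------------------
# Tests and multiplicity
# ---------------------------------------------------------------------------

def wald_p_value(estimate: float, se: float) -> float:
    """Upper chi-square(1) tail of ``(estimate / se)^2``."""
    if estimate == 0:
        return 1.0
    if se == 0 or not np.isfinite(se):
        raise ZeroDivisionError("degenerate Wald test: zero or non-finite SE")
    W = (estimate / se) ** 2
    return float(stats.chi2.sf(W, df=1))


def likelihood_ratio_test(loglik1: float, loglik2: float,
                          tol: float = 1e-3) -> tuple[float, float]:
    """LRT of a nested pair: statistic ``2 (ll2 - ll1)`` and chi2(1) p-value.

    The wider model must not fit worse than the nested one beyond numerical
    tolerance; small negative statistics are clipped to zero.
    """
    stat = 2.0 * (loglik2 - loglik1)
    if stat < -tol:
        raise ConvergenceOrderingError(
            f"wider model log-likelihood {loglik2} below nested {loglik1}")
    stat = max(stat, 0.0)
    return stat, float(stats.chi2.sf(stat, df=1))


def fdr_adjust(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (input order preserved)."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.isnan(p).any() or (p < 0).any() or (p > 1).any():
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def compare_models(loglik1, loglik2, labels=None) -> pd.DataFrame:
    """Model-comparison table: LRT statistics, raw and BH-adjusted p-values.

    ``loglik1`` / ``loglik2`` are aligned vectors of restricted
    log-likelihoods for the nested (no-covariance) and wider model per
    trait; the adjustment family is the whole column, as in a multi-trait
    screen.
    """
    ll1 = np.asarray(loglik1, dtype=float)
    ll2 = np.asarray(loglik2, dtype=float)
    if ll1.shape != ll2.shape:
        raise ValueError("log-likelihood vectors must align")
    stats_p = [likelihood_ratio_test(a, b) for a, b in zip(ll1, ll2)]
    stat = np.array([s for s, _ in stats_p])
    raw = np.array([p for _, p in stats_p])
    out = pd.DataFrame({
        "loglik_model1": ll1,
        "loglik_model2": ll2,
        "lrt_stat": stat,
        "lrt_p": raw,
        "lrt_p_fdr": fdr_adjust(raw),
    })
    if labels is not None:
        out.insert(0, "trait", list(labels))
    return out
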