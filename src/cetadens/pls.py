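"""Partial least squares regression for the seasonally-adjusted log-contrast model.

The response is u_i = log(y_i / g(i,y)) (log density deviation from the
seasonal average) and the predictors are v_ij = log(z_ij / g(i,z_j)) (log
typical-abundance-ratio deviations).  With thousands of candidate ASVs and
a couple of dozen cruises the least-squares problem is ill-posed, so the
coefficients are estimated through K latent components T = ZA:

* :class:`SIMPLSRegressor` computes the SIMPLS loading sequence — each
  loading maximises squared covariance with the response subject to unit
  norm and orthogonality of its score to all previous scores — and
  back-propagates least-squares estimates on the components to the original
  predictors, beta* = A (T'T)^-1 T'Y.
* :class:`SparsePLSRegressor` soft-thresholds each component's direction
  surrogate at a fraction ``threshold`` of its largest absolute entry,
  zeroing small loadings; the surviving variables (the active set) then get
  coefficients from a dense SIMPLS refit.

Both follow the scikit-learn estimator contract (fit/predict/get_params)
and compose with sklearn model selection.
"""

from __future__ import annotations

import numpy as np
from sklearn.base import BaseEstimator, RegressorMixin
from sklearn.utils.validation import check_array, check_is_fitted, check_X_y

__all__ = [
    "SIMPLSRegressor",
    "SparsePLSRegressor",
    "simpls_fit",
    "spls_fit",
    "association_measure",
    "fit_summary",
    "predict_density",
]

_EPS = 1e-12


def _simpls_loadings(Z: np.ndarray, y: np.ndarray, n_components: int,
                     threshold: float = 0.0):
    """Core SIMPLS iteration on centred data.

    Returns (A, T, n_used).  With ``threshold`` > 0 each component's
    direction surrogate s is soft-thresholded at threshold * max|s| before
    normalisation (the sparse-PLS surrogate); threshold = 0 reproduces
    plain SIMPLS.  Stops early when the residual covariance degenerates.
    """
    n, p = Z.shape
    s = Z.T @ y  # covariance direction surrogate
    A = []
    V = []  # orthonormal basis of x-loadings, used to deflate s
    T = []
    for _ in range(n_components):
        direction = s.copy()
        if threshold > 0.0:
            cutoff = threshold * np.max(np.abs(direction))
            direction = np.sign(direction) * np.maximum(np.abs(direction) - cutoff, 0.0)
        norm = np.linalg.norm(direction)
        if norm <= _EPS * max(1.0, np.linalg.norm(s)) or norm == 0.0:
            break
        a = direction / norm
        t = Z @ a
        tt = float(t @ t)
        if tt <= _EPS:
            break
        p_load = Z.T @ t / tt
        v = p_load.copy()
        for v_prev in V:
            v -= (v_prev @ v) * v_prev
        v_norm = np.linalg.norm(v)
        if v_norm <= _EPS:
            A.append(a)
            T.append(t)
            break
        v /= v_norm
        s = s - v * (v @ s)
        A.append(a)
        T.append(t)
        V.append(v)
    if not A:
        return np.zeros((p, 0)), np.zeros((n, 0)), 0
    return np.column_stack(A), np.column_stack(T), len(A)


def _back_propagate(A: np.ndarray, T: np.ndarray, y: np.ndarray) -> np.ndarray:
    """beta* = A (T'T)^-1 T'Y on centred data."""
    if A.shape[1] == 0:
        return np.zeros(A.shape[0])
    gram = T.T @ T
    return A @ np.linalg.solve(gram, T.T @ y)


class SIMPLSRegressor(RegressorMixin, BaseEstimator):
    """Univariate-response SIMPLS partial least squares regression.

    Parameters
    ----------
    n_components : int, default 2
        Number of latent components K.  Capped at min(n - 1, p) during fit;
        components are dropped early if the covariance direction degenerates
        (rank deficiency), in which case ``n_components_`` < K.

    Attributes
    ----------
    x_loadings_ : ndarray (p, K) — unit-norm loading matrix A.
    x_scores_ : ndarray (n, K) — scores T = ZA on centred training data.
    coef_ : ndarray (p,) — back-propagated coefficients on the original scale.
    intercept_ : float
    """

    def __init__(self, n_components: int = 2):
        self.n_components = n_components

    def _fit_centred(self, Z, y):
        return _simpls_loadings(Z, y, self._k_eff, threshold=0.0)

    def fit(self, X, y):
        X, y = check_X_y(X, y, y_numeric=True)
        if self.n_components < 1:
            raise ValueError("n_components must be >= 1")
        n, p = X.shape
        self._k_eff = int(min(self.n_components, max(n - 1, 1), p))
        self.x_mean_ = X.mean(axis=0)
        self.y_mean_ = float(np.mean(y))
        Z = X - self.x_mean_
        yc = y - self.y_mean_
        A, T, k = self._fit_centred(Z, yc)
        self.x_loadings_ = A
        self.x_scores_ = T
        self.n_components_ = k
        self.coef_ = _back_propagate(A, T, yc)
        self.intercept_ = self.y_mean_ - float(self.x_mean_ @ self.coef_)
        self.n_features_in_ = p
        return self

    def predict(self, X):
        check_is_fitted(self, "coef_")
        X = check_array(X)
        return X @ self.coef_ + self.intercept_


class SparsePLSRegressor(SIMPLSRegressor):
    """Sparse PLS via soft-thresholding of the SIMPLS direction surrogates.

    Parameters
    ----------
    n_components : int, default 2
    threshold : float in [0, 1), default 0.0
        Fractional soft-threshold lambda: within each component, entries of
        the direction surrogate smaller in magnitude than lambda times the
        largest entry are shrunk to exactly zero.  lambda = 0 reproduces
        plain SIMPLS; as lambda -> 1 at most one variable survives per
        component.
    refit : bool, default True
        Refit a dense SIMPLS model restricted to the active set (the union
        of surviving variables over components) for the final coefficients.
        With ``refit=False`` coefficients are back-propagated from the
        thresholded loadings directly.

    Attributes
    ----------
    active_ : ndarray of int — indices with nonzero coefficients.
    coef_ : ndarray (p,) — exactly zero off the active set.
    """

    def __init__(self, n_components: int = 2, threshold: float = 0.0,
                 refit: bool = True):
        super().__init__(n_components=n_components)
        self.threshold = threshold
        self.refit = refit

    def fit(self, X, y):
        if not 0.0 <= self.threshold < 1.0:
            raise ValueError("threshold must lie in [0, 1)")
        X, y = check_X_y(X, y, y_numeric=True)
        n, p = X.shape
        k_req = int(min(self.n_components, max(n - 1, 1), p))
        self.x_mean_ = X.mean(axis=0)
        self.y_mean_ = float(np.mean(y))
        Z = X - self.x_mean_
        yc = y - self.y_mean_

        A, T, k = _simpls_loadings(Z, yc, k_req, threshold=self.threshold)
        active = np.flatnonzero(np.any(np.abs(A) > 0, axis=1)) if k else np.array([], int)
        self.active_ = active
        self.n_features_in_ = p
        coef = np.zeros(p)
        if active.size == 0:
            self.empty_model_ = True
            self.x_loadings_ = np.zeros((p, 0))
            self.x_scores_ = np.zeros((n, 0))
            self.n_components_ = 0
            self.coef_ = coef
            self.intercept_ = self.y_mean_
            return self
        self.empty_model_ = False
        if self.refit:
            k_refit = int(min(k_req, active.size, max(n - 1, 1)))
            A_r, T_r, k_r = _simpls_loadings(Z[:, active], yc, k_refit)
            coef[active] = _back_propagate(A_r, T_r, yc)
            loadings = np.zeros((p, A_r.shape[1]))
            loadings[active] = A_r
            self.x_loadings_ = loadings
            self.x_scores_ = T_r
            self.n_components_ = k_r
        else:
            coef = _back_propagate(A, T, yc)
            self.x_loadings_ = A
            self.x_scores_ = T
            self.n_components_ = k
        self.coef_ = coef
        self.intercept_ = self.y_mean_ - float(self.x_mean_ @ self.coef_)
        return self


def simpls_fit(Z, y, n_components: int) -> SIMPLSRegressor:
    """Thin functional wrapper over :class:`SIMPLSRegressor`."""
    return SIMPLSRegressor(n_components=n_components).fit(Z, y)


def spls_fit(Z, y, n_components: int, threshold: float,
             refit: bool = True) -> SparsePLSRegressor:
    """Thin functional wrapper over :class:`SparsePLSRegressor`."""
    return SparsePLSRegressor(
        n_components=n_components, threshold=threshold, refit=refit
    ).fit(Z, y)


def association_measure(beta):
    """Multiplicative density change per doubling of an ASV's ratio.

    The model is a power law, density ratio = (abundance ratio)**beta, so the
    exponent is the same whatever log base the model was fitted on.  Every
    doubling of the ASV's seasonally-adjusted ratio multiplies the median
    seasonally-adjusted density by m = 2**beta.

    Returns (factor, percent_change) with percent_change = 100 * (m - 1);
    a factor of 1.338 reads as a 33.8% increase per doubling.
    """
    beta = np.asarray(beta, dtype=float)
    factor = np.exp2(beta)
    percent = 100.0 * (factor - 1.0)
    if factor.ndim == 0:
        return float(factor), float(percent)
    return factor, percent


def _adjusted_r2(y, y_hat, dof_model: int) -> tuple[float, float]:
    y = np.asarray(y, dtype=float)
    resid = y - np.asarray(y_hat, dtype=float)
    n = y.size
    ss_res = float(resid @ resid)
    centred = y - y.mean()
    ss_tot = float(centred @ centred)
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0
    if n - dof_model - 1 <= 0:
        raise ValueError("too few observations to adjust R^2")
    adj = 1.0 - (1.0 - r2) * (n - 1) / (n - dof_model - 1)
    return r2, adj


def fit_summary(fit, V, u, y, seasonal_g) -> dict:
    """Adjusted R^2 of a fitted model on the log and original scales.

    Parameters
    ----------
    fit : fitted PLS regressor
    V : (n, p) log-ratio predictor matrix used in the fit
    u : (n,) log-scale response log(y / g)
    y : (n,) densities on the original scale
    seasonal_g : (n,) per-cruise seasonal geometric means of the density

    Degrees of freedom for adjustment equal the number of latent
    components.
    """
    u_hat = fit.predict(V)
    k = max(int(getattr(fit, "n_components_", 1)), 1)
    r2_log, adj_log = _adjusted_r2(u, u_hat, k)
    y_hat = np.asarray(seasonal_g, dtype=float) * np.exp(u_hat)
    r2_orig, adj_orig = _adjusted_r2(np.asarray(y, dtype=float), y_hat, k)
    return {
        "r2_log": r2_log,
        "adjusted_r2_log": adj_log,
        "r2_original": r2_orig,
        "adjusted_r2_original": adj_orig,
        "n_components": k,
    }


def predict_density(fit, V_new, seasonal_g_new):
    """Back-transform log-scale predictions to densities.

    y_hat = g(i,y) * exp(beta_0 + sum_j beta_j v_ij), with g taken from the
    training partition's seasonal means for the new cruises' quarters.
    """
    V_new = np.asarray(V_new, dtype=float)
    if V_new.ndim == 1:
        V_new = V_new[None, :]
    if V_new.shape[1] != fit.n_features_in_:
        raise ValueError(
            f"model expects {fit.n_features_in_} predictors, got {V_new.shape[1]}"
        )
    u_hat = fit.predict(V_new)
    return np.asarray(seasonal_g_new, dtype=float) * np.exp(u_hat)
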