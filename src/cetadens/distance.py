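"""Multiple-covariate line-transect distance sampling.

Per-cruise whale density is estimated in two stages.  First a detection
function g(x, z) — the probability of detecting a group at perpendicular
distance x given sighting covariates z — is fitted by maximum likelihood to
the distances of all sightings of a species, truncated at w (default
2400 m).  Key functions are uniform, half-normal g = exp(-x^2 / 2 sigma^2)
and hazard-rate g = 1 - exp(-(x/sigma)^-b); series adjustments (cosine for
uniform/half-normal, simple polynomial for hazard-rate) or covariates on the
log scale parameter are added by forward AIC selection.  Second, density on
cruise i follows the Horvitz-Thompson-style estimator

    y_i = 1 / (2 L_i w) * sum_g s_g / p_hat_g(z_g)

with p_hat_g = (1/w) * integral_0^w g(x, z_g) dx, reported as individuals
per 1000 km^2.  Variance combines a between-transect encounter-rate
component with a delta-method detection-function component on the CV scale.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import integrate, optimize, stats

__all__ = [
    "DetectionFunction",
    "fit_detection_function",
    "select_detection_model",
    "cvm_gof",
    "average_detection_probability",
    "estimate_density",
    "density_variance",
    "DEFAULT_TRUNCATION_M",
]

DEFAULT_TRUNCATION_M = 2400.0
_G_EPS = 1e-12
# Gauss-Legendre rule reused for all detection-function integrals
_GL_NODES, _GL_WEIGHTS = np.polynomial.legendre.leggauss(101)

KEY_FUNCTIONS = ("uniform", "half-normal", "hazard-rate")
COSINE_ORDERS = {"uniform": (1, 2, 3), "half-normal": (2, 3)}
POLY_ORDERS = {"hazard-rate": (4, 6)}


def _design_matrix(sightings: pd.DataFrame, covariates) -> np.ndarray:
    """Numeric design matrix for the log scale parameter (factors one-hot,
    first level dropped)."""
    if not covariates:
        return np.zeros((len(sightings), 0))
    cols = []
    for cov in covariates:
        if cov not in sightings.columns:
            raise ValueError(f"covariate column {cov!r} missing from sightings")
        col = sightings[cov]
        if col.isna().any():
            raise ValueError(f"covariate {cov!r} has missing values")
        if col.dtype == object or isinstance(col.dtype, pd.CategoricalDtype):
            levels = sorted(col.astype(str).unique())
            for level in levels[1:]:
                cols.append((col.astype(str) == level).to_numpy(float))
        else:
            cols.append(col.to_numpy(float))
    return np.column_stack(cols) if cols else np.zeros((len(sightings), 0))


class DetectionFunction:
    """Line-transect detection function with MLE fitting.

    Parameters
    ----------
    key : {"uniform", "half-normal", "hazard-rate"}
    adjustment_orders : tuple of int
        Cosine orders (uniform / half-normal key) or even polynomial orders
        (hazard-rate key).  Adjustments cannot be combined with covariates.
    covariates : tuple of str
        Sighting-table columns entering the log scale parameter,
        log sigma(z) = beta_0 + beta' z (not available with the uniform key).
    w : float
        Truncation distance in metres; sightings must already satisfy x <= w.
    n_starts : int
        Multi-start count for the quasi-Newton optimiser.

    Fitted attributes: ``params_``, ``loglik_``, ``aic_``, ``n_params_``,
    ``converged_``, ``p_hat_`` (per sighting), ``cdf_values_`` (per
    sighting), ``vcov_``.
    """

    def __init__(self, key: str = "half-normal", adjustment_orders=(),
                 covariates=(), w: float = DEFAULT_TRUNCATION_M,
                 n_starts: int = 5):
        if key not in KEY_FUNCTIONS:
            raise ValueError(f"unknown key function {key!r}")
        if key == "uniform" and covariates:
            raise ValueError("the uniform key has no scale parameter for covariates")
        if adjustment_orders and covariates:
            raise ValueError("adjustments and covariates are fitted in separate sets")
        if w <= 0:
            raise ValueError("truncation distance must be positive")
        self.key = key
        self.adjustment_orders = tuple(adjustment_orders)
        self.covariates = tuple(covariates)
        self.w = float(w)
        self.n_starts = int(n_starts)

    # --- parameter layout -------------------------------------------------
    @property
    def _n_scale(self) -> int:
        return {"uniform": 0, "half-normal": 1, "hazard-rate": 2}[self.key]

    def _n_params(self, n_cov: int) -> int:
        return self._n_scale + n_cov + len(self.adjustment_orders)

    def _split(self, params: np.ndarray, n_cov: int):
        k = self._n_scale
        scale = params[:k]
        betas = params[k:k + n_cov]
        alphas = params[k + n_cov:]
        return scale, betas, alphas

    # --- evaluation -------------------------------------------------------
    def _sigma(self, params, design) -> np.ndarray:
        scale, betas, _ = self._split(params, design.shape[1])
        if self.key == "uniform":
            return np.ones(design.shape[0])
        return np.exp(scale[0] + design @ betas)

    def _g_raw(self, x, sigma, params, n_cov):
        scale, _, alphas = self._split(params, n_cov)
        x = np.asarray(x, dtype=float)
        if self.key == "uniform":
            key = np.ones_like(x)
        elif self.key == "half-normal":
            key = np.exp(-(x**2) / (2.0 * sigma**2))
        else:  # hazard-rate
            b = np.exp(scale[1])
            with np.errstate(divide="ignore", over="ignore"):
                ratio = np.where(x > 0, x / sigma, np.inf)  # placeholder for x=0
                key = 1.0 - np.exp(-np.power(ratio, -b, where=x > 0,
                                             out=np.full_like(x, np.inf)))
            key = np.where(x > 0, key, 1.0)
        if alphas.size:
            xs = x / self.w
            if self.key == "hazard-rate":
                series = 1.0 + sum(
                    a * xs**m for a, m in zip(alphas, self.adjustment_orders)
                )
                series0 = 1.0
            else:
                series = 1.0 + sum(
                    a * np.cos(m * np.pi * xs)
                    for a, m in zip(alphas, self.adjustment_orders)
                )
                series0 = 1.0 + alphas.sum()
                if series0 <= _G_EPS:
                    return np.full_like(x, np.nan)
            key = key * series / series0
        return np.clip(key, _G_EPS, 1.0)

    def g(self, x, z_row=None, params=None) -> np.ndarray:
        """Evaluate the (fitted) detection function at distances x."""
        if params is None:
            params = self.params_
        x = np.atleast_1d(np.asarray(x, dtype=float))
        if z_row is None:
            z = np.zeros((1, len(getattr(self, "_design_columns_", []))
                          if self.covariates else 0))
        else:
            z = np.atleast_2d(np.asarray(z_row, dtype=float))
        sigma = self._sigma(params, z)
        return self._g_raw(x, float(sigma[0]), params, z.shape[1])

    def _mu(self, params, design) -> np.ndarray:
        """integral_0^w g(x, z) dx per design row (Gauss-Legendre)."""
        nodes = 0.5 * self.w * (_GL_NODES + 1.0)
        weights = 0.5 * self.w * _GL_WEIGHTS
        sigma = self._sigma(params, design)
        uniq, inv = np.unique(np.round(sigma, 12), return_inverse=True)
        mus = np.empty(uniq.size)
        for k, s in enumerate(uniq):
            gx = self._g_raw(nodes, s, params, design.shape[1])
            mus[k] = float(weights @ gx)
        return mus[inv]

    def _nll(self, params, x, design) -> float:
        with np.errstate(all="ignore"):
            sigma = self._sigma(params, design)
            gx = np.empty_like(x)
            uniq, inv = np.unique(np.round(sigma, 12), return_inverse=True)
            for k, s in enumerate(uniq):
                sel = inv == k
                gx[sel] = self._g_raw(x[sel], s, params, design.shape[1])
            mu = self._mu(params, design)
        if (not np.all(np.isfinite(gx))) or (not np.all(np.isfinite(mu))) \
                or np.any(mu <= 0):
            return 1e10
        return float(np.sum(np.log(mu)) - np.sum(np.log(gx)))

    # --- fitting ----------------------------------------------------------
    def fit(self, sightings: pd.DataFrame):
        if len(sightings) == 0:
            raise ValueError("cannot fit a detection function to zero sightings")
        x = sightings["distance_m"].to_numpy(dtype=float)
        if (x < 0).any():
            raise ValueError("negative perpendicular distances")
        if (x > self.w).any():
            raise ValueError("sightings beyond the truncation distance; truncate first")
        design = _design_matrix(sightings, self.covariates)
        self._design_columns_ = list(range(design.shape[1]))
        n_par = self._n_params(design.shape[1])

        if n_par == 0:  # uniform key, no adjustments: closed form
            self.params_ = np.zeros(0)
            self.loglik_ = -len(x) * np.log(self.w)
            self.converged_ = True
        else:
            sd = max(float(np.std(x)), 1e-3)
            init = np.zeros(n_par)
            if self.key != "uniform":
                init[0] = np.log(sd)
            if self.key == "hazard-rate":
                init[1] = np.log(2.0)
            rng = np.random.default_rng(12345)
            best = None
            for start in range(self.n_starts):
                p0 = init if start == 0 else init + rng.normal(0, 0.5, n_par)
                res = optimize.minimize(
                    self._nll, p0, args=(x, design), method="L-BFGS-B",
                )
                if best is None or res.fun < best.fun:
                    best = res
                if best.success and start >= 1:
                    break
            self.params_ = best.x
            self.loglik_ = -float(best.fun)
            self.converged_ = bool(best.success and best.fun < 1e9)
            if not self.converged_:
                warnings.warn(
                    f"detection-function fit did not converge ({self.key}, "
                    f"adjustments={self.adjustment_orders}, "
                    f"covariates={self.covariates})"
                )
        self.n_params_ = n_par
        self.aic_ = 2.0 * n_par - 2.0 * self.loglik_
        self._x_ = x
        self._design_ = design
        self.vcov_ = self._vcov(x, design)
        mu = self._mu(self.params_, design)
        self.p_hat_ = mu / self.w
        self.cdf_values_ = self._cdf(x, design)
        return self

    def _vcov(self, x, design):
        n_par = self.params_.size
        if n_par == 0:
            return np.zeros((0, 0))
        h = 1e-4 * np.maximum(1.0, np.abs(self.params_))
        hess = np.empty((n_par, n_par))
        f0 = self._nll(self.params_, x, design)
        for i in range(n_par):
            for j in range(i, n_par):
                pp = self.params_.copy(); pp[i] += h[i]; pp[j] += h[j]
                pm = self.params_.copy(); pm[i] += h[i]; pm[j] -= h[j]
                mp = self.params_.copy(); mp[i] -= h[i]; mp[j] += h[j]
                mm = self.params_.copy(); mm[i] -= h[i]; mm[j] -= h[j]
                hess[i, j] = hess[j, i] = (
                    self._nll(pp, x, design) - self._nll(pm, x, design)
                    - self._nll(mp, x, design) + self._nll(mm, x, design)
                ) / (4.0 * h[i] * h[j])
        del f0
        try:
            return np.linalg.inv(hess)
        except np.linalg.LinAlgError:
            return None

    def _cdf(self, x, design) -> np.ndarray:
        """Fitted CDF of perpendicular distance per sighting."""
        mu = self._mu(self.params_, design)
        sigma = self._sigma(self.params_, design)
        out = np.empty_like(x)
        for g_idx in range(x.size):
            if x[g_idx] == 0:
                out[g_idx] = 0.0
                continue
            nodes = 0.5 * x[g_idx] * (_GL_NODES + 1.0)
            weights = 0.5 * x[g_idx] * _GL_WEIGHTS
            gx = self._g_raw(nodes, sigma[g_idx], self.params_, design.shape[1])
            out[g_idx] = float(weights @ gx) / mu[g_idx]
        return np.clip(out, 0.0, 1.0)

    def p_hat(self, sightings: pd.DataFrame, params=None) -> np.ndarray:
        """Average detection probability p_hat(z) = mu(z)/w per sighting."""
        design = _design_matrix(sightings, self.covariates)
        return self._mu(self.params_ if params is None else params, design) / self.w


def fit_detection_function(sightings, w=DEFAULT_TRUNCATION_M,
                           key="half-normal", adjustment_orders=(),
                           covariates=()) -> DetectionFunction:
    """Fit one candidate detection function (thin class wrapper)."""
    return DetectionFunction(
        key=key, adjustment_orders=adjustment_orders,
        covariates=covariates, w=w,
    ).fit(sightings)


def select_detection_model(sightings, w=DEFAULT_TRUNCATION_M,
                           covariates=("beaufort", "swell_m", "platform",
                                       "group_size")):
    """Forward AIC selection over two candidate sets, as in the analysis.

    Set A starts from each key function and adds series adjustment terms
    one at a time while AIC decreases.  Set B starts from the half-normal
    and hazard-rate keys and forward-selects scale covariates while AIC
    decreases.  Returns (best_fit, trace); the trace records every
    candidate with its AIC and whether the addition was accepted.
    """
    trace: list[dict] = []
    fits: list[DetectionFunction] = []

    def try_fit(**kwargs):
        try:
            fit = fit_detection_function(sightings, w=w, **kwargs)
        except Exception as exc:
            trace.append({**kwargs, "aic": None, "error": str(exc)})
            return None
        trace.append({**kwargs, "aic": fit.aic_,
                      "converged": fit.converged_})
        return fit

    # Set A: key + series adjustments
    for key in KEY_FUNCTIONS:
        orders = COSINE_ORDERS.get(key, POLY_ORDERS.get(key, ()))
        current = try_fit(key=key)
        if current is None:
            continue
        chosen: list[int] = []
        for order in orders:
            cand = try_fit(key=key, adjustment_orders=tuple(chosen + [order]))
            if cand is not None and cand.aic_ < current.aic_:
                current = cand
                chosen.append(order)
                trace[-1]["accepted"] = True
            else:
                if cand is not None:
                    trace[-1]["accepted"] = False
                break
        fits.append(current)

    # Set B: half-normal / hazard-rate keys + scale covariates
    for key in ("half-normal", "hazard-rate"):
        current = try_fit(key=key)
        if current is None:
            continue
        chosen_cov: list[str] = []
        remaining = [c for c in covariates if c in sightings.columns]
        improved = True
        while improved and remaining:
            improved = False
            best_cand, best_cov = None, None
            for cov in remaining:
                cand = try_fit(key=key, covariates=tuple(chosen_cov + [cov]))
                if cand is not None and (
                    best_cand is None or cand.aic_ < best_cand.aic_
                ):
                    best_cand, best_cov = cand, cov
            if best_cand is not None and best_cand.aic_ < current.aic_:
                current = best_cand
                chosen_cov.append(best_cov)
                remaining.remove(best_cov)
                improved = True
        fits.append(current)

    if not fits:
        raise RuntimeError(f"all detection-function fits failed: {trace}")
    best = min(fits, key=lambda f: f.aic_)
    return best, trace


def cvm_gof(fit: DetectionFunction):
    """Cramer-von Mises goodness of fit on the fitted CDF values.

    With u the sorted fitted CDF values, W^2 = 1/(12n) +
    sum_i (u_(i) - (2i-1)/(2n))^2; the p-value comes from the W^2 reference
    distribution for a fully specified null (uniformity of u).
    """
    u = np.asarray(fit.cdf_values_, dtype=float)
    if u.size == 0:
        raise ValueError("no fitted CDF values")
    res = stats.cramervonmises(u, "uniform")
    return float(res.statistic), float(res.pvalue)


def average_detection_probability(fit: DetectionFunction, z_row=None) -> float:
    """p_hat(z) = (1/w) * integral_0^w g_hat(x, z) dx by adaptive quadrature."""
    if z_row is None:
        z = np.zeros(0)
    else:
        z = np.asarray(z_row, dtype=float)
    value, _ = integrate.quad(
        lambda xx: float(fit.g(np.array([xx]),
                               z_row=z[None, :] if z.size else None)[0]),
        0.0, fit.w, epsabs=1e-8, epsrel=1e-8, limit=200,
    )
    return value / fit.w


def _check_units(effort: pd.DataFrame):
    if (effort["length_km"] <= 0).any():
        raise ValueError("transect lengths must be positive")
    w_values = effort["truncation_w"].unique()
    if len(w_values) > 1:
        raise ValueError("truncation distance must be uniform within an analysis")
    return float(w_values[0])


def estimate_density(sightings: pd.DataFrame, effort: pd.DataFrame,
                     fit: DetectionFunction) -> pd.DataFrame:
    """Per-cruise density, individuals per 1000 km^2.

    y_i = 1/(2 L_i w) * sum_g s_g / p_hat_g with L_i in km and w converted
    to km; cruises without sightings get y_i = 0.
    """
    w = _check_units(effort)
    if abs(w - fit.w) > 1e-9:
        raise ValueError("effort truncation distance differs from the fitted w")
    sightings = sightings[sightings["distance_m"] <= w]
    cruise_effort = effort.groupby("cruise")["length_km"].sum()
    missing = set(sightings["cruise"]) - set(cruise_effort.index)
    if missing:
        raise ValueError(f"cruises with sightings but no effort: {sorted(missing)}")
    p_hat = fit.p_hat(sightings)
    if np.any(p_hat <= 0) or np.any(p_hat > 1 + 1e-9):
        raise ValueError("invalid detection probabilities")
    weights = sightings["group_size"].to_numpy(dtype=float) / p_hat
    per_cruise = pd.Series(weights, index=sightings["cruise"].to_numpy()) \
        .groupby(level=0).sum()
    w_km = w / 1000.0
    rows = []
    for cruise, L in cruise_effort.items():
        total = float(per_cruise.get(cruise, 0.0))
        n_i = int((sightings["cruise"] == cruise).sum())
        density_km2 = total / (2.0 * L * w_km)
        rows.append({
            "cruise": cruise, "n_sightings": n_i,
            "density": 1000.0 * density_km2,  # per 1000 km^2
        })
    return pd.DataFrame(rows).set_index("cruise").sort_index()


def _encounter_rate_cv(sightings, effort, cruise) -> tuple[float, bool]:
    """Effort-weighted between-transect (R2-style) encounter-rate CV."""
    eff = effort[effort["cruise"] == cruise]
    K = len(eff)
    if K < 2:
        return 0.0, False
    L = eff["length_km"].sum()
    counts = sightings[sightings["cruise"] == cruise] \
        .groupby("transect").size()
    n_k = eff.set_index("transect").index.map(
        lambda t: float(counts.get(t, 0))
    ).to_numpy()
    l_k = eff["length_km"].to_numpy(dtype=float)
    n = n_k.sum()
    if n == 0:
        return 0.0, True
    rate = n / L
    var_rate = K / (L * (K - 1)) * float(np.sum(l_k * (n_k / l_k - rate) ** 2))
    return float(np.sqrt(var_rate) / rate), True


def density_variance(sightings: pd.DataFrame, effort: pd.DataFrame,
                     fit: DetectionFunction) -> pd.DataFrame:
    """Variance components per cruise, combined on the CV scale.

    cv^2(y) = cv^2(encounter rate) + cv^2(detection); the encounter-rate
    component is an effort-weighted between-transect estimator and the
    detection component comes from the delta method on the detection MLEs.
    Single-transect cruises carry only the detection component and are
    flagged.
    """
    w = _check_units(effort)
    dens = estimate_density(sightings, effort, fit)
    sightings = sightings[sightings["distance_m"] <= w]
    n_par = fit.params_.size

    rows = []
    for cruise in dens.index:
        y = float(dens.loc[cruise, "density"])
        cv_n, multi = _encounter_rate_cv(sightings, effort, cruise)
        cv_p = 0.0
        if n_par and y > 0 and fit.vcov_ is not None:
            sub = sightings[sightings["cruise"] == cruise]
            s_g = sub["group_size"].to_numpy(dtype=float)
            h = 1e-5 * np.maximum(1.0, np.abs(fit.params_))
            grad = np.zeros(n_par)
            base_total = float(np.sum(s_g / fit.p_hat(sub)))
            if base_total > 0:
                for j in range(n_par):
                    plus = fit.params_.copy(); plus[j] += h[j]
                    minus = fit.params_.copy(); minus[j] -= h[j]
                    tp = float(np.sum(s_g / fit.p_hat(sub, params=plus)))
                    tm = float(np.sum(s_g / fit.p_hat(sub, params=minus)))
                    grad[j] = (tp - tm) / (2.0 * h[j])
                var_total = float(grad @ fit.vcov_ @ grad)
                cv_p = float(np.sqrt(max(var_total, 0.0)) / base_total)
        cv = float(np.sqrt(cv_n**2 + cv_p**2))
        if not multi:
            warnings.warn(
                f"cruise {cruise!r} has a single transect; encounter-rate "
                "variance unavailable, reporting detection component only"
            )
        rows.append({
            "cruise": cruise, "density": y,
            "cv_encounter": cv_n, "cv_detection": cv_p, "cv": cv,
            "variance": (cv * y) ** 2,
            "encounter_component_available": multi,
        })
    return pd.DataFrame(rows).set_index("cruise")
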