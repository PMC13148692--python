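"""Stability selection over a sparsity path with PFER control.

Variables (ASVs) are selected by how often sparse PLS picks them across
leave-one-out data partitions, along a grid of sparsity thresholds lambda.
For each fold the seasonal adjustment is recomputed from the training
cruises only, so held-out observations never inform their own fold.  The
sparsity region Lambda is chosen so that the expected number of falsely
selected variables (the per-family error rate, PFER) is bounded:

    q_lambda**2 / ((2 * pi_max - 1) * p) <= pfer_level

where q_lambda is the average active-set size across folds.  The stable set
collects every variable whose selection probability reaches pi_max for at
least one admissible lambda.  The number of latent components K is chosen
by leave-one-out mean squared prediction error over a grid (default 4..12).

The procedure is fully deterministic given the data and the grids: the
subsampling scheme is exhaustive leave-one-out, not random.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.base import BaseEstimator

from .pls import SIMPLSRegressor, SparsePLSRegressor
from .seasonal import partition_aware_adjust

__all__ = [
    "SelectionPath",
    "StableSet",
    "model_matrices",
    "selection_probabilities",
    "lambda_region_pfer",
    "stable_set",
    "select_num_components",
    "StabilitySelector",
    "DEFAULT_LAMBDA_GRID",
    "DEFAULT_K_GRID",
]

DEFAULT_LAMBDA_GRID = np.linspace(0.5, 0.95, 21)
DEFAULT_K_GRID = tuple(range(4, 13))


@dataclass
class ModelMatrices:
    """Centred log-ratio response and predictors for the log-contrast model."""

    u: np.ndarray          # log(y / g(i,y)), all cruises
    V: np.ndarray          # log(z / g(i,z_j)), all cruises x ASVs
    g_y: np.ndarray        # seasonal geometric means of the density
    g_z: np.ndarray        # seasonal geometric means of the ratios
    train: np.ndarray      # boolean mask of training cruises


def model_matrices(y, z, quarters, heldout=None) -> ModelMatrices:
    """Build u_i and v_ij with seasonal means from the training partition.

    ``heldout`` marks cruises excluded from every seasonal mean; their rows
    are still returned (adjusted against training means) so they can be
    predicted.  Densities must be strictly positive (apply a zero offset
    upstream when a species has sighting-free cruises).
    """
    y = np.asarray(y, dtype=float)
    z = np.asarray(z, dtype=float)
    n = y.shape[0]
    if heldout is None:
        heldout = np.zeros(n, dtype=bool)
    else:
        mask = np.zeros(n, dtype=bool)
        idx = np.asarray(heldout)
        if idx.dtype == bool:
            mask = idx.copy()
        else:
            mask[idx] = True
        heldout = mask
    y_ratio, g_y = partition_aware_adjust(y, quarters, heldout)
    z_ratio, g_z = partition_aware_adjust(z, quarters, heldout)
    return ModelMatrices(
        u=np.log(y_ratio),
        V=np.log(z_ratio),
        g_y=g_y,
        g_z=g_z,
        train=~heldout,
    )


@dataclass
class SelectionPath:
    """Per-lambda selection probabilities estimated from LOO folds."""

    lambda_grid: np.ndarray
    pi: np.ndarray             # (p, n_lambda) selection probabilities
    q: np.ndarray              # (n_lambda,) mean active-set size across folds
    n_folds: int
    n_folds_used: int
    p: int
    failures: list = field(default_factory=list)


class EmptyRegionError(ValueError):
    """No lambda on the grid satisfies the PFER bound."""


def selection_probabilities(
    z, y, quarters, lambda_grid=None, n_components: int = 4
) -> SelectionPath:
    """Estimate pi_j(lambda) = P(beta_j^lambda != 0) over exhaustive LOO folds.

    Each fold holds out one cruise, recomputes the seasonal adjustment on
    the remaining cruises, fits sparse PLS at every lambda on the grid and
    records the nonzero-coefficient pattern.  Folds whose exclusion empties
    a quarter (or whose fit fails) are dropped with a warning; if fewer than
    90% of folds succeed the procedure errors out.
    """
    if lambda_grid is None:
        lambda_grid = DEFAULT_LAMBDA_GRID
    lambda_grid = np.asarray(lambda_grid, dtype=float)
    y = np.asarray(y, dtype=float)
    z = np.asarray(z, dtype=float)
    n, p = z.shape
    if n < 3:
        raise ValueError("need at least 3 cruises for leave-one-out selection")
    counts = np.zeros((p, lambda_grid.size))
    sizes = np.zeros(lambda_grid.size)
    failures: list[tuple[int, str]] = []
    used = 0
    for i in range(n):
        try:
            mm = model_matrices(y, z, quarters, heldout=[i])
            Zt = mm.V[mm.train]
            ut = mm.u[mm.train]
            for l, lam in enumerate(lambda_grid):
                fit = SparsePLSRegressor(
                    n_components=n_components, threshold=float(lam)
                ).fit(Zt, ut)
                nz = fit.coef_ != 0
                counts[:, l] += nz
                sizes[l] += nz.sum()
        except Exception as exc:  # fold-level failure, recorded
            failures.append((i, str(exc)))
            continue
        used += 1
    if used < 0.9 * n:
        raise RuntimeError(
            f"only {used}/{n} leave-one-out folds succeeded: {failures}"
        )
    return SelectionPath(
        lambda_grid=lambda_grid,
        pi=counts / used,
        q=sizes / used,
        n_folds=n,
        n_folds_used=used,
        p=p,
        failures=failures,
    )


@dataclass
class LambdaRegion:
    """Admissible sparsity region under the PFER bound."""

    lambdas: np.ndarray        # admissible grid values
    mask: np.ndarray           # boolean over the full grid
    interval: tuple            # (min admissible, max admissible)
    bound: np.ndarray          # q_lambda^2 / ((2 pi_max - 1) p) on the grid


def lambda_region_pfer(
    path: SelectionPath, pi_max: float = 0.9, pfer_level: float = 0.5,
    p: int | None = None,
) -> LambdaRegion:
    """Grid lambdas whose expected false-selection bound is below the level.

    Admissible iff q_lambda**2 / ((2 pi_max - 1) p) <= pfer_level, i.e.
    q_lambda <= sqrt(pfer * (2 pi_max - 1) * p).
    """
    if not pi_max > 0.5:
        raise ValueError("pi_max must exceed 0.5")
    if p is None:
        p = path.p
    bound = path.q**2 / ((2.0 * pi_max - 1.0) * p)
    mask = bound <= pfer_level
    if not mask.any():
        raise EmptyRegionError(
            "no admissible lambda: smallest attainable PFER bound is "
            f"{bound.min():.3g} (level {pfer_level})"
        )
    lambdas = path.lambda_grid[mask]
    return LambdaRegion(
        lambdas=lambdas,
        mask=mask,
        interval=(float(lambdas.min()), float(lambdas.max())),
        bound=bound,
    )


@dataclass
class StableSet:
    """Variables whose selection probability reaches pi_max inside Lambda."""

    indices: np.ndarray
    pi_max: float
    pfer_level: float
    region: LambdaRegion
    n_components: int
    p: int

    def __len__(self) -> int:
        return int(self.indices.size)


def stable_set(
    path: SelectionPath, region: LambdaRegion, pi_max: float = 0.9,
    pfer_level: float = 0.5, n_components: int = 4,
) -> StableSet:
    """S = {j : pi_j(lambda) >= pi_max for some lambda in the region}."""
    if not region.mask.any():
        raise ValueError("region is empty")
    pi_in_region = path.pi[:, region.mask]
    selected = np.flatnonzero(pi_in_region.max(axis=1) >= pi_max)
    return StableSet(
        indices=selected,
        pi_max=pi_max,
        pfer_level=pfer_level,
        region=region,
        n_components=n_components,
        p=path.p,
    )


def _stability_for_k(z, y, quarters, k, lambda_grid, pi_max, pfer_level):
    path = selection_probabilities(z, y, quarters, lambda_grid, n_components=k)
    region = lambda_region_pfer(path, pi_max=pi_max, pfer_level=pfer_level)
    sset = stable_set(path, region, pi_max=pi_max,
                      pfer_level=pfer_level, n_components=k)
    return path, region, sset


def loo_mspe(z, y, quarters, support, n_components: int) -> float:
    """Leave-one-out mean squared prediction error on the log-ratio scale.

    Per fold the seasonal adjustment is recomputed from training cruises;
    a SIMPLS model on the supported columns predicts the held-out u_i.  An
    empty support yields the seasonal-mean prediction u_hat = 0.
    """
    y = np.asarray(y, dtype=float)
    z = np.asarray(z, dtype=float)
    support = np.asarray(support, dtype=int)
    n = y.shape[0]
    errors = np.empty(n)
    for i in range(n):
        mm = model_matrices(y, z, quarters, heldout=[i])
        if support.size == 0:
            u_hat = 0.0
        else:
            Zt = mm.V[np.ix_(mm.train, support)]
            k = int(min(n_components, support.size, Zt.shape[0] - 1))
            fit = SIMPLSRegressor(n_components=max(k, 1)).fit(Zt, mm.u[mm.train])
            u_hat = float(fit.predict(mm.V[[i]][:, support])[0])
        errors[i] = (mm.u[i] - u_hat) ** 2
    return float(errors.mean())


def select_num_components(
    z, y, quarters, k_grid=DEFAULT_K_GRID, lambda_grid=None,
    pi_max: float = 0.9, pfer_level: float = 0.5,
):
    """Choose K by LOO MSPE of the SIMPLS fit on each K's stable set.

    Returns (k_best, results) where results maps K to a dict with the
    stable set, selection path, region and MSPE.  Ties break toward the
    smaller K.  Grid values for which the whole stability pipeline fails
    are recorded and skipped; if every K fails an error is raised.
    """
    results: dict[int, dict] = {}
    best = None
    for k in k_grid:
        try:
            path, region, sset = _stability_for_k(
                z, y, quarters, int(k), lambda_grid, pi_max, pfer_level
            )
            mspe = loo_mspe(z, y, quarters, sset.indices, int(k))
        except Exception as exc:
            results[int(k)] = {"error": str(exc)}
            continue
        results[int(k)] = {
            "path": path, "region": region, "stable_set": sset, "mspe": mspe,
        }
        if best is None or mspe < best[1] - 1e-15:
            best = (int(k), mspe)
    if best is None:
        raise RuntimeError(f"stability selection failed for every K: {results}")
    return best[0], results


class StabilitySelector(BaseEstimator):
    """Stability-selection feature selector for the log-contrast model.

    Parameters
    ----------
    n_components : int or "auto", default "auto"
        Latent components K for the sparse PLS fits.  ``"auto"`` chooses K
        from ``k_grid`` by leave-one-out MSPE.
    k_grid : iterable of int, default 4..12
    lambda_grid : array-like, default 21 points on [0.5, 0.95]
    pi_max : float, default 0.9
        Selection-probability threshold (must exceed 0.5).
    pfer_level : float, default 0.5
        Bound on the expected number of falsely selected variables.

    Attributes (after fit)
    ----------
    support_ : int indices of the stable set
    path_, region_, stable_set_, n_components_, mspe_, k_results_
    """

    def __init__(self, n_components="auto", k_grid=DEFAULT_K_GRID,
                 lambda_grid=None, pi_max: float = 0.9,
                 pfer_level: float = 0.5):
        self.n_components = n_components
        self.k_grid = k_grid
        self.lambda_grid = lambda_grid
        self.pi_max = pi_max
        self.pfer_level = pfer_level

    def fit(self, z, y, quarters):
        if self.n_components == "auto":
            k, results = select_num_components(
                z, y, quarters, k_grid=self.k_grid,
                lambda_grid=self.lambda_grid,
                pi_max=self.pi_max, pfer_level=self.pfer_level,
            )
            chosen = results[k]
            self.k_results_ = results
            self.mspe_ = chosen["mspe"]
            self.path_ = chosen["path"]
            self.region_ = chosen["region"]
            self.stable_set_ = chosen["stable_set"]
            self.n_components_ = k
        else:
            k = int(self.n_components)
            path, region, sset = _stability_for_k(
                z, y, quarters, k, self.lambda_grid,
                self.pi_max, self.pfer_level,
            )
            self.path_ = path
            self.region_ = region
            self.stable_set_ = sset
            self.n_components_ = k
            self.mspe_ = loo_mspe(z, y, quarters, sset.indices, k)
        self.support_ = self.stable_set_.indices
        return self

    def get_support(self, indices: bool = True):
        if indices:
            return self.support_
        mask = np.zeros(self.stable_set_.p, dtype=bool)
        mask[self.support_] = True
        return mask
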