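"""Nested leave-one-out validation, naive baselines and consistency measures.

The outer validation re-runs the entire stability-selection procedure with
one cruise held out at a time, yielding n stable sets whose agreement is
summarised by a thresholded Jaccard index: the fraction of the union of
selected taxa that recur in at least a fraction alpha of the sets.
Predictive skill is measured by leave-one-out RMSPE on the log-ratio and
original density scales and benchmarked against two naive forecasts —
carrying forward the most recent same-quarter observation (lag) and the
training-quarter average (mean).  Prediction uncertainty comes from a
quarter-stratified cruise bootstrap.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .pls import SIMPLSRegressor
from .stability import StabilitySelector, model_matrices

__all__ = [
    "outer_validation",
    "thresholded_jaccard",
    "loo_predictions",
    "naive_predictions",
    "reduction_vs_baseline",
    "bootstrap_intervals",
    "annotation_overlap",
    "PredictionReport",
]


def outer_validation(z, y, quarters, n_components="auto", **selector_kwargs):
    """Stable sets from re-running stability selection minus one cruise each.

    Returns a list of n sets of column indices (into z).  Inner leave-one-out
    folds therefore run on n - 2 cruises.  Per-fold failures are recorded as
    ``None`` entries rather than aborting the whole validation.
    """
    y = np.asarray(y, dtype=float)
    z = np.asarray(z, dtype=float)
    quarters = np.asarray(quarters)
    n = y.shape[0]
    if n < 3:
        raise ValueError("need at least 3 cruises")
    sets = []
    for i in range(n):
        keep = np.arange(n) != i
        try:
            sel = StabilitySelector(
                n_components=n_components, **selector_kwargs
            ).fit(z[keep], y[keep], quarters[keep])
            sets.append(set(int(j) for j in sel.support_))
        except Exception:
            sets.append(None)
    return sets


def thresholded_jaccard(sets, alpha: float = 0.5) -> float:
    """J_alpha = |{j : selected in >= n*alpha of the sets}| / |union of sets|.

    ``sets`` is a sequence of index/label sets (failed folds as None are
    skipped).  Undefined (raises) when every set is empty.
    """
    usable = [s for s in sets if s is not None]
    if not usable:
        raise ValueError("no stable sets available")
    n = len(usable)
    union = set().union(*usable)
    if not union:
        raise ValueError("all stable sets are empty; J is undefined")
    counts = {j: sum(j in s for s in usable) for j in union}
    recurrent = [j for j, c in counts.items() if c >= n * alpha]
    return len(recurrent) / len(union)


@dataclass
class PredictionReport:
    """Per-cruise leave-one-out predictions with summary metrics."""

    table: pd.DataFrame       # y, y_hat, u, u_hat, quarter, g_train
    rmspe_log: float
    rmspe_original: float
    correlation_log: float
    correlation_original: float


def _corr(a, b) -> float:
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    if a.std() == 0 or b.std() == 0:
        return float("nan")
    return float(np.corrcoef(a, b)[0, 1])


def loo_predictions(z, y, quarters, support, n_components: int,
                    reselect: bool = False, **selector_kwargs) -> PredictionReport:
    """Out-of-sample density predictions from exhaustive leave-one-out folds.

    For each fold the seasonal adjustment is recomputed on the training
    cruises, a SIMPLS model is fitted on the supported columns, and the
    held-out cruise's density is predicted as g(i,y) * exp(u_hat).  With
    ``reselect=True`` the stable set is re-estimated inside every fold
    (nested validation); the default reuses the fixed ``support``.
    """
    y = np.asarray(y, dtype=float)
    z = np.asarray(z, dtype=float)
    quarters = np.asarray(quarters)
    n = y.shape[0]
    support = np.asarray(support, dtype=int)
    rows = []
    for i in range(n):
        mm = model_matrices(y, z, quarters, heldout=[i])
        train = mm.train
        cols = support
        if reselect:
            keep = np.flatnonzero(train)
            sel = StabilitySelector(
                n_components=n_components, **selector_kwargs
            ).fit(z[keep], y[keep], quarters[keep])
            cols = sel.support_
        if cols.size == 0:
            u_hat = 0.0
            k = 0
        else:
            Zt = mm.V[np.ix_(train, cols)]
            k = int(min(n_components, cols.size, Zt.shape[0] - 1))
            fit = SIMPLSRegressor(n_components=max(k, 1)).fit(Zt, mm.u[train])
            u_hat = float(fit.predict(mm.V[[i]][:, cols])[0])
        rows.append({
            "quarter": quarters[i],
            "y": y[i],
            "u": mm.u[i],
            "u_hat": u_hat,
            "g_train": mm.g_y[i],
            "y_hat": mm.g_y[i] * np.exp(u_hat),
        })
    table = pd.DataFrame(rows)
    return PredictionReport(
        table=table,
        rmspe_log=float(np.sqrt(np.mean((table.u - table.u_hat) ** 2))),
        rmspe_original=float(np.sqrt(np.mean((table.y - table.y_hat) ** 2))),
        correlation_log=_corr(table.u, table.u_hat),
        correlation_original=_corr(table.y, table.y_hat),
    )


def naive_predictions(y, quarters, method: str = "lag") -> np.ndarray:
    """Leave-one-out baseline forecasts of per-cruise density.

    ``lag`` carries forward the chronologically nearest prior observation
    from the same quarter (falling back to the nearest subsequent one at
    the start of the series); ``mean`` uses the training-quarter geometric
    mean, matching the pipeline's seasonal means.  Cruises are assumed to
    be in chronological order.  Errors if a quarter occurs only once.
    """
    y = np.asarray(y, dtype=float)
    quarters = np.asarray(quarters)
    n = y.shape[0]
    preds = np.empty(n)
    for i in range(n):
        same = np.flatnonzero((quarters == quarters[i]) & (np.arange(n) != i))
        if same.size == 0:
            raise ValueError(f"quarter {quarters[i]!r} absent from training data")
        if method == "lag":
            prior = same[same < i]
            preds[i] = y[prior.max()] if prior.size else y[same.min()]
        elif method == "mean":
            vals = y[same]
            if (vals <= 0).any():
                raise ValueError("geometric mean requires positive densities")
            preds[i] = float(np.exp(np.mean(np.log(vals))))
        else:
            raise ValueError("method must be 'lag' or 'mean'")
    return preds


def reduction_vs_baseline(model_rmspe: float, baseline_rmspe: float) -> float:
    """Percent reduction in prediction error relative to a baseline."""
    if baseline_rmspe <= 0:
        raise ValueError("baseline RMSPE must be positive")
    return 100.0 * (baseline_rmspe - model_rmspe) / baseline_rmspe


def bootstrap_intervals(z, y, quarters, support, n_components: int,
                        n_boot: int = 200, level: float = 0.90,
                        seed: int | None = None) -> pd.DataFrame:
    """Quarter-stratified cruise-bootstrap percentile intervals per prediction.

    For every leave-one-out fold, training cruises are resampled with
    replacement within quarters, the model is refitted on the supported
    columns and the held-out cruise re-predicted; the interval is the
    percentile range of the bootstrap predictions on the log scale,
    back-transformed to densities.
    """
    if n_boot < 50:
        raise ValueError("need at least 50 bootstrap resamples")
    rng = np.random.default_rng(seed)
    y = np.asarray(y, dtype=float)
    z = np.asarray(z, dtype=float)
    quarters = np.asarray(quarters)
    n = y.shape[0]
    support = np.asarray(support, dtype=int)
    lo_q, hi_q = 100 * (1 - level) / 2, 100 * (1 + level) / 2
    rows = []
    for i in range(n):
        train_idx = np.flatnonzero(np.arange(n) != i)
        by_quarter = {
            q: train_idx[quarters[train_idx] == q]
            for q in np.unique(quarters[train_idx])
        }
        boots = np.empty(n_boot)
        for b in range(n_boot):
            for _attempt in range(100):
                resampled = np.concatenate([
                    rng.choice(members, size=members.size, replace=True)
                    for members in by_quarter.values()
                ])
                if all(
                    (quarters[resampled] == q).any() for q in by_quarter
                ):
                    break
            else:
                raise RuntimeError("bootstrap kept emptying a quarter")
            yb, zb, qb = y[resampled], z[resampled], quarters[resampled]
            mm_b = model_matrices(
                np.append(yb, y[i]), np.vstack([zb, z[[i]]]),
                np.append(qb, quarters[i]), heldout=[len(yb)],
            )
            if support.size == 0:
                u_hat = 0.0
            else:
                Zt = mm_b.V[np.ix_(mm_b.train, support)]
                k = int(min(n_components, support.size, Zt.shape[0] - 1))
                fit = SIMPLSRegressor(n_components=max(k, 1)).fit(
                    Zt, mm_b.u[mm_b.train]
                )
                u_hat = float(fit.predict(mm_b.V[[-1]][:, support])[0])
            boots[b] = mm_b.g_y[-1] * np.exp(u_hat)
        log_boots = np.log(boots)
        rows.append({
            "lower": float(np.exp(np.percentile(log_boots, lo_q))),
            "upper": float(np.exp(np.percentile(log_boots, hi_q))),
        })
    return pd.DataFrame(rows)


def annotation_overlap(sets_by_species: dict) -> dict:
    """Partition annotation labels by how many species models share them.

    ``sets_by_species`` maps each species to the set of annotation labels
    selected by its models (union across markers).  Returns counts and
    percentages of labels shared by all three species, by exactly two, and
    unique to one.
    """
    species = list(sets_by_species)
    sets = {s: set(v) for s, v in sets_by_species.items()}
    union = set().union(*sets.values()) if sets else set()
    tally = {label: sum(label in sets[s] for s in species) for label in union}
    all_three = {l for l, c in tally.items() if c == len(species) and c >= 3}
    exactly_two = {l for l, c in tally.items() if c == 2}
    unique = {l for l, c in tally.items() if c == 1}
    unique_by = {
        s: sorted(l for l in unique if l in sets[s]) for s in species
    }
    total = len(union)
    pct = lambda k: 100.0 * k / total if total else float("nan")
    return {
        "total": total,
        "all_three": sorted(all_three),
        "exactly_two": sorted(exactly_two),
        "unique": sorted(unique),
        "unique_by_species": unique_by,
        "counts": {
            "all_three": len(all_three),
            "exactly_two": len(exactly_two),
            "unique": len(unique),
        },
        "percent": {
            "all_three": pct(len(all_three)),
            "exactly_two": pct(len(exactly_two)),
            "unique": pct(len(unique)),
        },
    }
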