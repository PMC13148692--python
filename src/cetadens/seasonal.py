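"""Seasonal adjustment by within-quarter geometric means.

Cruise-level quantities (estimated whale densities, typical-abundance
ratios) carry strong quarterly seasonality.  It is removed with a secondary
ratio against the geometric mean of all cruises sharing the same quarter:
a value of 0.5 means "half of the seasonal average".  When data partitions
are formed (leave-one-out folds), the quarter means must be recomputed from
the training cruises only so that held-out observations never leak into
their own adjustment.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

__all__ = [
    "seasonal_geometric_means",
    "seasonal_adjust",
    "partition_aware_adjust",
    "zero_density_offset",
]


def _as_array(values) -> np.ndarray:
    arr = np.asarray(values, dtype=float)
    if arr.ndim == 1:
        arr = arr[:, None]
    return arr


def zero_density_offset(values, fraction: float = 0.5) -> float:
    """Offset added to a density series containing zeros before log-ratios.

    Cruises with no sightings of a species have an estimated density of
    exactly zero, which breaks the log-ratio transform.  The offset is
    ``fraction`` times the smallest nonzero value of the series (0.0 when
    the series has no zeros).
    """
    arr = np.asarray(values, dtype=float)
    if arr.size == 0 or (arr > 0).all():
        return 0.0
    positive = arr[arr > 0]
    if positive.size == 0:
        raise ValueError("all values are zero; no offset can be formed")
    return fraction * float(positive.min())


def seasonal_geometric_means(values, quarters, partition=None) -> np.ndarray:
    """Per-observation geometric mean over the observations sharing its quarter.

    Parameters
    ----------
    values : array-like, shape (n,) or (n, p)
        Strictly positive values (apply :func:`zero_density_offset` first if
        the series contains zeros).
    quarters : sequence of length n
        Quarter label of each observation.
    partition : boolean array-like of length n, optional
        Mask of observations forming the active (training) partition.  The
        geometric means are computed from partition members only, but are
        returned for every observation (out-of-partition observations get
        their quarter's training mean).

    Returns
    -------
    ndarray with the same shape as ``values``.
    """
    arr = np.asarray(values, dtype=float)
    squeeze = arr.ndim == 1
    mat = _as_array(arr)
    if np.any(mat <= 0):
        raise ValueError("values must be strictly positive for geometric means")
    quarters = np.asarray(quarters)
    if quarters.shape[0] != mat.shape[0]:
        raise ValueError("quarters length does not match values")
    if partition is None:
        mask = np.ones(mat.shape[0], dtype=bool)
    else:
        mask = np.asarray(partition, dtype=bool)
    out = np.empty_like(mat)
    logmat = np.log(mat)
    for q in pd.unique(quarters):
        in_q = quarters == q
        train_q = in_q & mask
        if not train_q.any():
            raise ValueError(f"quarter {q!r} has no cruises in the partition")
        out[in_q] = np.exp(logmat[train_q].mean(axis=0))
    return out[:, 0] if squeeze else out


def seasonal_adjust(values, quarters, partition=None):
    """Ratio of each value to its quarter's geometric mean."""
    g = seasonal_geometric_means(values, quarters, partition)
    return np.asarray(values, dtype=float) / g, g


def partition_aware_adjust(values, quarters, heldout):
    """Seasonal ratios with the held-out cruises excluded from every mean.

    ``heldout`` is a boolean mask (or index array) of cruises excluded from
    the quarter means; their ratios are computed against the training-only
    means.  Raises if exclusion empties any quarter.
    """
    n = len(np.asarray(quarters))
    mask = np.zeros(n, dtype=bool)
    heldout = np.asarray(heldout)
    if heldout.dtype == bool:
        mask = heldout.copy()
    else:
        mask[heldout] = True
    return seasonal_adjust(values, quarters, partition=~mask)
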