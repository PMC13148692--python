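"""Cruise-level compositional transforms of ASV count tables.

The pipeline turns sample-level ASV counts into one strictly positive
"typical-abundance ratio" per (cruise, ASV):

1. prevalence filtering (drop ASVs seen in <1% or >99% of samples),
2. geometric Bayesian-multiplicative (GBM) replacement of count zeros,
3. weighted geometric-mean aggregation of sample compositions to cruises,
4. centring each cruise's aggregated abundances by their geometric mean,
   giving z_ij = x_ij / g_i (z = 2 reads "twice as abundant as the typical
   ASV on this cruise").

All operations act on a samples x ASVs pandas DataFrame of counts plus a
per-sample metadata frame with columns ``cruise``, ``transect``, ``station``
and ``depth`` (``surface`` or ``DCM``).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "CruiseComposition",
    "filter_prevalence",
    "impute_zeros_gbm",
    "aggregation_weights",
    "aggregate_to_cruise",
    "typical_ratio",
    "cruise_composition",
]

METADATA_COLUMNS = ("cruise", "transect", "station", "depth")
DEPTH_LEVELS = ("surface", "DCM")


@dataclass
class CruiseComposition:
    """Aggregated cruise-level composition and its centred ratios."""

    x: pd.DataFrame          # cruises x ASVs, aggregated average relative abundance
    g: pd.Series             # per-cruise geometric mean across retained ASVs
    z: pd.DataFrame          # typical-abundance ratios x_ij / g_i
    retained: list = field(default_factory=list)

    @property
    def n_asvs(self) -> int:
        return self.x.shape[1]


def _validate_counts(counts: pd.DataFrame) -> None:
    values = counts.to_numpy()
    if (values < 0).any():
        raise ValueError("counts must be non-negative")
    if (values.sum(axis=1) <= 0).any():
        raise ValueError("every sample must have a positive total count")


def filter_prevalence(counts: pd.DataFrame, lo: float = 0.01, hi: float = 0.99):
    """Keep ASVs whose prevalence lies in [lo, hi], pooled over all samples.

    Prevalence is the fraction of samples (across all cruises) in which the
    ASV has a nonzero count.  Rare (<lo) and ubiquitous (>hi) ASVs carry too
    little variation to support prediction.  Boundaries are inclusive.
    """
    if not 0 <= lo < hi <= 1:
        raise ValueError("thresholds must satisfy 0 <= lo < hi <= 1")
    _validate_counts(counts)
    prevalence = (counts > 0).mean(axis=0)
    keep = (prevalence >= lo) & (prevalence <= hi)
    retained = list(counts.columns[keep])
    if not retained:
        raise ValueError("no candidates survive filtering")
    return counts.loc[:, retained], retained


def impute_zeros_gbm(
    counts: pd.DataFrame,
    prior_strength: float | str = "parts",
    prior: np.ndarray | None = None,
) -> pd.DataFrame:
    """Geometric Bayesian-multiplicative replacement of count zeros.

    For a sample with total count n, a zero for ASV j is replaced by
    ``t_j * s / (n + s)`` where s is the prior strength and t_j the prior
    proportion; observed proportions are then shrunk multiplicatively so the
    sample still sums to one.  By default t is the geometric mean of the
    observed (nonzero) per-sample proportions of each ASV, renormalised.

    ``prior_strength="parts"`` (default) sets s to the number of ASVs — a
    total prior mass of one pseudo-read per part — which places replacements
    just below the detection limit 1/n.  Much weaker priors (s = 1) impute
    orders of magnitude lower, creating large log-scale outliers at typical
    library sizes.  Returns strictly positive per-sample proportions.
    """
    _validate_counts(counts)
    if prior_strength == "parts":
        prior_strength = float(counts.shape[1])
    values = counts.to_numpy(dtype=float)
    totals = values.sum(axis=1, keepdims=True)
    props = values / totals

    if prior is None:
        # geometric mean of observed proportions, per ASV, over samples
        # where the ASV was detected
        with np.errstate(divide="ignore"):
            logp = np.log(props)
        logp[~np.isfinite(logp)] = np.nan
        detected = np.isfinite(logp)
        if not detected.any(axis=0).all():
            raise ValueError("an ASV has zero count in every sample; filter first")
        t = np.exp(np.nanmean(logp, axis=0))
        t = t / t.sum()
    else:
        t = np.asarray(prior, dtype=float)
        if t.shape != (values.shape[1],):
            raise ValueError("prior has wrong length")
        t = t / t.sum()

    s = float(prior_strength)
    n = totals[:, 0]
    zero = props == 0
    imputed = zero * (t[None, :] * (s / (n + s))[:, None])
    imputed_total = imputed.sum(axis=1)
    if (imputed_total >= 1).any():
        raise ValueError("imputed mass exceeds 1; reduce prior strength")
    out = np.where(zero, imputed, props * (1 - imputed_total)[:, None])
    return pd.DataFrame(out, index=counts.index, columns=counts.columns)


def _entropy(p: np.ndarray) -> float:
    p = p / p.sum()
    return float(-(p * np.log(p)).sum())


def aggregation_weights(
    metadata: pd.DataFrame,
    proportions: pd.DataFrame | None = None,
    depth_grid: np.ndarray | None = None,
) -> pd.Series:
    """Per-sample aggregation weights, normalised to sum 1 within each cruise.

    The spatial factor is inversely proportional to local sampling density
    (1 / number of samples at the same station on the cruise).  The depth
    factor assigns weight r to DCM samples and 1 - r to surface samples,
    with r chosen on a grid to maximise the Shannon entropy (alpha
    diversity) of the resulting aggregated composition, ties broken toward
    the DCM; when no composition is supplied r = 0.5.
    """
    for col in ("cruise", "station", "depth"):
        if col not in metadata.columns:
            raise ValueError(f"metadata missing column {col!r}")
    if len(metadata) == 0:
        raise ValueError("cruise with zero samples")

    station_counts = metadata.groupby(["cruise", "station"])["depth"].transform("size")
    spatial = 1.0 / station_counts.to_numpy(dtype=float)
    is_dcm = (metadata["depth"].astype(str) == "DCM").to_numpy()

    def weights_for(r: float) -> pd.Series:
        depth_factor = np.where(is_dcm, r, 1.0 - r)
        raw = pd.Series(spatial * depth_factor, index=metadata.index)
        if (raw.to_numpy() <= 0).any():
            return None  # r degenerate: a sample would get zero weight
        sums = raw.groupby(metadata["cruise"].to_numpy()).transform("sum")
        return raw / sums

    if proportions is None:
        w = weights_for(0.5)
        if w is None:
            raise ValueError("degenerate weights")
        return w

    if depth_grid is None:
        # interior grid: the endpoints would zero out one depth stratum,
        # violating strictly positive weights
        depth_grid = np.linspace(0.05, 0.95, 19)
    best = None
    for r in depth_grid:
        w = weights_for(float(r))
        if w is None:
            continue
        agg = aggregate_to_cruise(proportions, w, metadata["cruise"])
        total_entropy = sum(_entropy(agg.loc[c].to_numpy()) for c in agg.index)
        # ties broken toward DCM: >= with increasing r keeps the larger r
        if best is None or total_entropy >= best[0] - 1e-12:
            if best is None or total_entropy > best[0] + 1e-12 or r > best[1]:
                best = (total_entropy, float(r), w)
    if best is None:
        raise ValueError("no valid depth weighting found")
    return best[2]


def aggregate_to_cruise(
    proportions: pd.DataFrame, weights: pd.Series, cruises: pd.Series
) -> pd.DataFrame:
    """Weighted geometric mean of sample compositions within each cruise.

    x_ij = prod over samples of (x_ijklm ** w_klm), the "average relative
    abundance" of ASV j on cruise i.
    """
    values = proportions.to_numpy(dtype=float)
    if (values <= 0).any():
        raise ValueError("proportions must be strictly positive; impute zeros first")
    w = weights.to_numpy(dtype=float)
    logx = np.log(values) * w[:, None]
    frame = pd.DataFrame(logx, index=cruises.to_numpy(), columns=proportions.columns)
    agg = np.exp(frame.groupby(level=0, sort=False).sum())
    # keep cruises in order of first appearance, not lexicographic order
    agg = agg.reindex(pd.unique(cruises))
    agg.index.name = "cruise"
    return agg


def typical_ratio(x: pd.DataFrame):
    """Centre aggregated abundances by their per-cruise geometric mean.

    Returns (z, g) with z_ij = x_ij / g_i and g_i the geometric mean over
    retained ASVs; the geometric mean of each row of z is one.
    """
    values = np.asarray(x, dtype=float)
    if (values <= 0).any():
        raise ValueError("aggregated abundances must be strictly positive")
    logx = np.log(values)
    g = np.exp(logx.mean(axis=1))
    z = values / g[:, None]
    if isinstance(x, pd.DataFrame):
        z = pd.DataFrame(z, index=x.index, columns=x.columns)
        g = pd.Series(g, index=x.index, name="g")
    return z, g


def cruise_composition(
    counts: pd.DataFrame,
    metadata: pd.DataFrame,
    lo: float = 0.01,
    hi: float = 0.99,
    prior_strength: float | str = "parts",
) -> CruiseComposition:
    """Full sample-counts -> cruise typical-abundance-ratio pipeline."""
    filtered, retained = filter_prevalence(counts, lo=lo, hi=hi)
    proportions = impute_zeros_gbm(filtered, prior_strength=prior_strength)
    weights = aggregation_weights(metadata, proportions)
    x = aggregate_to_cruise(proportions, weights, metadata["cruise"])
    z, g = typical_ratio(x)
    return CruiseComposition(x=x, g=g, z=z, retained=retained)
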