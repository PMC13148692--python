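"""Synthetic survey, sighting and ASV-count data with known ground truth.

The generator emulates the joint structure the analysis assumes: quarterly
cruises over several years, line-transect effort with sparse whale
sightings produced by a known detection function, and sample-level ASV
count tables whose cruise-level composition drives density anomalies
through a planted log-contrast signal.

Generative model
----------------
* Design: one cruise per (year, quarter), first ``n_cruises`` kept; each
  cruise runs 2-7 transects with a few stations each, sampled at two depth
  strata (surface and deep chlorophyll maximum).
* Compositions: latent log abundances are ASV baseline + quarter effect +
  onshore-offshore gradient + depth effect + per-cruise driver anomaly +
  Gaussian noise; softmax gives sample proportions and counts are
  multinomial with fixed library size, so zeros arise naturally
  (a logistic-normal composition model).  Planted drivers carry
  independent per-cruise anomalies by default; ``driver_common_factor``
  optionally lets them co-vary through a shared habitat factor, signed so
  that whale-enriched and whale-depleted taxa move against each other.
  Driver baselines are placed so the planted taxa are reliably quantified
  at the configured library size without being ubiquitous.
* Density: log(D_i / seasonal mean) = sum_j beta_j v_ij + eps_i with
  eps_i ~ N(0, sigma_eps^2), where v_ij are the planted per-cruise driver
  log-anomalies; a doubling of a driver's ratio multiplies density by
  2**beta_j.
* Sightings: groups per transect are Poisson with mean
  2 w L D 1e-6 / mean group size (w in m, L in km, D individuals per
  1000 km^2); perpendicular distances are uniform and thinned by the
  detection function, group sizes are zero-truncated Poisson.

All randomness flows through a single seed; sub-streams are spawned
deterministically per component.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

__all__ = [
    "SimConfig",
    "DetectionConfig",
    "SimTruth",
    "SurveyDesign",
    "SimDataset",
    "simulate_design",
    "simulate_compositions",
    "simulate_density",
    "simulate_sightings",
    "generate_dataset",
]

QUARTERS = ("winter", "spring", "summer", "fall")
PLATFORM_LEVELS = ("low", "mid", "high")


@dataclass
class DetectionConfig:
    """Detection-function parameters used to thin simulated sightings."""

    key: str = "half-normal"
    sigma_m: float = 1200.0
    shape_b: float = 2.5                      # hazard-rate only
    covariate_effects: dict = field(default_factory=dict)  # on log sigma


@dataclass
class SimConfig:
    """Study conditions for the synthetic data generator.

    Defaults mirror the survey the analysis targets: 25 quarterly cruises
    over 7 years, 2-7 transects per cruise sampled at two depths, a few
    hundred candidate ASVs at desk scale with a small planted driver set,
    half-normal detection with sigma = 1200 m truncated at 2400 m, and
    strongly seasonal whale density (summer peak, sparse winter sightings).
    """

    n_years: int = 7
    quarters: tuple = QUARTERS
    n_cruises: int = 25
    transects_per_cruise: tuple = (2, 7)
    stations_per_transect: int = 3
    depths: tuple = ("surface", "DCM")
    effort_km_range: tuple = (150.0, 450.0)
    library_size: int = 10_000
    p_asvs: int = 500
    driver_count: int = 5
    beta_range: tuple = (1.0, 1.5)          # |beta|, exponent per log-unit
    driver_anomaly_sd: float = 0.5           # per-cruise log anomaly of drivers
    driver_common_factor: float = 0.0        # shared habitat-factor variance fraction
    driver_mean_count: float = 8.0           # target mean reads/sample for drivers
    baseline_sd: float = 2.0                 # ASV baseline log abundance spread
    quarter_effect_sd: float = 0.75
    gradient_sd: float = 0.5
    depth_effect_sd: float = 0.5
    sample_noise_sd: float = 0.5
    seasonal_density_effects: dict = field(default_factory=lambda: {
        "winter": 0.4, "spring": 1.0, "summer": 2.5, "fall": 0.7,
    })
    encounter_intensity: float = 2.0         # expected groups per 1000 km^2
    mean_group_size: float = 1.2
    sigma_eps: float = 0.2                   # residual sd of log density anomaly
    detection: DetectionConfig = field(default_factory=DetectionConfig)
    truncation_w: float = 2400.0
    seed: int = 0

    def validate(self) -> None:
        if not (self.p_asvs >= self.driver_count >= 0):
            raise ValueError("need p_asvs >= driver_count >= 0")
        if self.library_size <= 0:
            raise ValueError("library_size must be positive")
        if self.truncation_w <= 0:
            raise ValueError("truncation_w must be positive")
        if self.n_cruises > self.n_years * len(self.quarters):
            raise ValueError("more cruises requested than (year, quarter) pairs")
        for q in self.quarters:
            if q not in self.seasonal_density_effects:
                raise ValueError(f"no seasonal density effect for quarter {q!r}")

    def rngs(self, n: int = 5):
        return [np.random.default_rng(s)
                for s in np.random.SeedSequence(self.seed).spawn(n)]


@dataclass
class SimTruth:
    """Planted ground truth recorded for recovery and calibration tests."""

    driver_set: np.ndarray        # ASV column indices
    beta: np.ndarray              # exponent per driver
    anomalies: np.ndarray         # (n_cruises, driver_count) log anomalies v_ij
    true_density: np.ndarray      # individuals per 1000 km^2 per cruise
    seasonal_means: dict          # quarter -> generative mean density
    detection_params: DetectionConfig = field(default_factory=DetectionConfig)
    sigma_eps: float = 0.0
    quarters: np.ndarray | None = None

    def to_dict(self) -> dict:
        return {
            "driver_set": [int(j) for j in self.driver_set],
            "beta": [float(b) for b in self.beta],
            "anomalies": self.anomalies.tolist(),
            "true_density": self.true_density.tolist(),
            "seasonal_means": {k: float(v) for k, v in self.seasonal_means.items()},
            "detection_params": asdict(self.detection_params),
            "sigma_eps": float(self.sigma_eps),
            "quarters": list(self.quarters) if self.quarters is not None else None,
        }


@dataclass
class SurveyDesign:
    cruises: pd.DataFrame    # cruise, year, quarter
    transects: pd.DataFrame  # cruise, transect, length_km
    samples: pd.DataFrame    # sample_id, cruise, transect, station, depth, position


@dataclass
class SimDataset:
    sightings: pd.DataFrame
    effort: pd.DataFrame
    counts: pd.DataFrame     # samples x ASVs
    metadata: pd.DataFrame   # per-sample cruise/transect/station/depth
    design: SurveyDesign
    truth: SimTruth


def simulate_design(config: SimConfig, rng=None) -> SurveyDesign:
    """Survey layout: cruises with quarters, transects with effort, stations.

    One cruise per (year, quarter) in calendar order, truncated to
    ``n_cruises``.  Raises if any quarter ends up represented in fewer than
    two distinct years.
    """
    config.validate()
    rng = rng or config.rngs(1)[0]
    rows = []
    for year in range(config.n_years):
        for q in config.quarters:
            rows.append({"year": 2014 + year, "quarter": q})
    cruises = pd.DataFrame(rows[: config.n_cruises])
    cruises["cruise"] = [
        f"{r.year}-{r.quarter}" for r in cruises.itertuples()
    ]
    years_per_quarter = cruises.groupby("quarter")["year"].nunique()
    if (years_per_quarter < 2).any():
        bad = years_per_quarter[years_per_quarter < 2].index.tolist()
        raise ValueError(f"invalid design: quarters {bad} observed in < 2 years")

    lo, hi = config.transects_per_cruise
    t_rows, s_rows = [], []
    for cruise in cruises["cruise"]:
        n_t = int(rng.integers(lo, hi + 1)) if hi > lo else int(lo)
        for t in range(n_t):
            tid = f"T{t + 1}"
            t_rows.append({
                "cruise": cruise, "transect": tid,
                "length_km": float(rng.uniform(*config.effort_km_range)),
            })
            for s in range(config.stations_per_transect):
                for depth in config.depths:
                    s_rows.append({
                        "cruise": cruise, "transect": tid,
                        "station": f"{tid}-S{s + 1}",
                        "depth": depth,
                        "position": s / max(config.stations_per_transect - 1, 1),
                    })
    samples = pd.DataFrame(s_rows)
    samples.insert(0, "sample_id", [f"sample{k:04d}" for k in range(len(samples))])
    return SurveyDesign(
        cruises=cruises[["cruise", "year", "quarter"]],
        transects=pd.DataFrame(t_rows),
        samples=samples,
    )


def _softmax(logits: np.ndarray) -> np.ndarray:
    shifted = logits - logits.max(axis=1, keepdims=True)
    expd = np.exp(shifted)
    return expd / expd.sum(axis=1, keepdims=True)


def simulate_compositions(config: SimConfig, design: SurveyDesign, rng=None,
                          driver_signs=None):
    """Sample-level ASV counts plus the planted driver anomalies.

    Returns (counts, metadata, driver_set, anomalies).  Driver anomalies
    share a per-cruise latent habitat factor (variance fraction
    ``driver_common_factor``), oriented by ``driver_signs`` so that taxa
    enriched and depleted in whale habitat move oppositely; driver
    baselines are placed so their expected per-sample read count is about
    ``driver_mean_count``, keeping them quantifiable but not ubiquitous.
    """
    config.validate()
    rng = rng or config.rngs(2)[1]
    samples = design.samples
    cruises = design.cruises["cruise"].to_numpy()
    quarters = design.cruises.set_index("cruise")["quarter"]
    p = config.p_asvs

    baseline = rng.normal(0.0, config.baseline_sd, p)
    quarter_eff = {
        q: rng.normal(0.0, config.quarter_effect_sd, p) for q in config.quarters
    }
    gradient = rng.normal(0.0, config.gradient_sd, p)
    depth_eff = rng.normal(0.0, config.depth_effect_sd, p)

    driver_set = rng.choice(p, size=config.driver_count, replace=False)
    driver_set.sort()
    if config.driver_count:
        # place drivers at a target mean read depth
        norm = np.exp(baseline).sum()
        target = np.log(config.driver_mean_count * norm / config.library_size)
        baseline[driver_set] = target + rng.normal(0.0, 0.25, config.driver_count)
    if driver_signs is None:
        driver_signs = np.ones(config.driver_count)
    driver_signs = np.asarray(driver_signs, dtype=float)
    rho = float(config.driver_common_factor)
    habitat = rng.normal(0.0, 1.0, len(cruises))
    idio = rng.normal(0.0, 1.0, (len(cruises), config.driver_count))
    anomalies = config.driver_anomaly_sd * (
        np.sqrt(rho) * habitat[:, None] * driver_signs[None, :]
        + np.sqrt(1.0 - rho) * idio
    )
    cruise_anomaly = np.zeros((len(cruises), p))
    cruise_anomaly[:, driver_set] = anomalies
    cruise_index = {c: k for k, c in enumerate(cruises)}

    logits = np.empty((len(samples), p))
    for row_i, row in enumerate(samples.itertuples()):
        q = quarters[row.cruise]
        logits[row_i] = (
            baseline
            + quarter_eff[q]
            + gradient * row.position
            + depth_eff * (row.depth == "DCM")
            + cruise_anomaly[cruise_index[row.cruise]]
        )
    logits += rng.normal(0.0, config.sample_noise_sd, logits.shape)
    proportions = _softmax(logits)
    counts = np.vstack([
        rng.multinomial(config.library_size, prob) for prob in proportions
    ])
    counts = pd.DataFrame(
        counts,
        index=samples["sample_id"],
        columns=[f"asv{j:04d}" for j in range(p)],
    )
    metadata = samples.set_index("sample_id")[
        ["cruise", "transect", "station", "depth"]
    ]
    return counts, metadata, driver_set, anomalies


def simulate_density(config: SimConfig, design: SurveyDesign,
                     anomalies: np.ndarray, beta: np.ndarray | None = None,
                     rng=None):
    """True per-cruise density with its anomaly decomposition.

    D_i = seasonal_mean(q_i) * exp(sum_j beta_j v_ij + eps_i); the seasonal
    mean is encounter intensity x mean group size x the quarter's effect.
    Returns (density, beta, seasonal_means, eps).
    """
    config.validate()
    rng = rng or config.rngs(3)[2]
    quarters = design.cruises["quarter"].to_numpy()
    if beta is None:
        lo, hi = config.beta_range
        magnitude = rng.uniform(lo, hi, config.driver_count)
        sign = rng.choice([-1.0, 1.0], config.driver_count)
        beta = magnitude * sign
    beta = np.asarray(beta, dtype=float)
    seasonal_means = {
        q: config.encounter_intensity * config.mean_group_size
        * config.seasonal_density_effects[q]
        for q in config.quarters
    }
    eps = rng.normal(0.0, config.sigma_eps, len(quarters)) \
        if config.sigma_eps > 0 else np.zeros(len(quarters))
    signal = anomalies @ beta if beta.size else np.zeros(len(quarters))
    density = np.array([
        seasonal_means[q] for q in quarters
    ]) * np.exp(signal + eps)
    return density, beta, seasonal_means, eps


def _detection_probability(config: DetectionConfig, x, covariate_shift):
    sigma = config.sigma_m * np.exp(covariate_shift)
    if config.key == "uniform":
        return np.ones_like(np.asarray(x, dtype=float))
    if config.key == "half-normal":
        return np.exp(-np.asarray(x, float) ** 2 / (2.0 * sigma**2))
    if config.key == "hazard-rate":
        x = np.asarray(x, dtype=float)
        with np.errstate(divide="ignore"):
            out = 1.0 - np.exp(-np.power(np.where(x > 0, x / sigma, 1.0), -config.shape_b))
        return np.where(x > 0, out, 1.0)
    raise ValueError(f"unknown key {config.key!r}")


def simulate_sightings(config: SimConfig, design: SurveyDesign,
                       true_density: np.ndarray, rng=None,
                       species: str = "whale"):
    """Line-transect sightings thinned by the configured detection function.

    Expected groups per transect are 2 w L D 1e-6 / mean group size (w in m,
    L in km, D individuals per 1000 km^2); candidate distances are uniform
    on [0, w] and retained with probability g(x, z).
    """
    config.validate()
    if config.truncation_w <= 0:
        raise ValueError("truncation_w must be positive")
    rng = rng or config.rngs(4)[3]
    w = config.truncation_w
    det = config.detection
    cruises = design.cruises["cruise"].to_numpy()
    density = dict(zip(cruises, np.asarray(true_density, dtype=float)))

    s_rows = []
    e_rows = []
    for t in design.transects.itertuples():
        L = t.length_km
        e_rows.append({
            "cruise": t.cruise, "transect": t.transect,
            "length_km": L, "truncation_w": w,
        })
        d_i = density[t.cruise]
        mean_groups = 2.0 * w * L * d_i * 1e-6 / config.mean_group_size
        n_candidates = rng.poisson(mean_groups)
        for _ in range(n_candidates):
            x = rng.uniform(0.0, w)
            beaufort = int(rng.integers(0, 6))
            swell = float(rng.uniform(0.3, 3.0))
            platform = str(rng.choice(PLATFORM_LEVELS))
            size = 1 + int(rng.poisson(max(config.mean_group_size - 1.0, 0.0)))
            shift = (
                det.covariate_effects.get("beaufort", 0.0) * beaufort
                + det.covariate_effects.get("swell_m", 0.0) * swell
                + det.covariate_effects.get("group_size", 0.0) * size
            )
            if rng.uniform() <= float(_detection_probability(det, x, shift)):
                s_rows.append({
                    "cruise": t.cruise, "transect": t.transect,
                    "species": species, "distance_m": x,
                    "group_size": size, "beaufort": beaufort,
                    "swell_m": swell, "platform": platform,
                })
    sightings = pd.DataFrame(
        s_rows, columns=["cruise", "transect", "species", "distance_m",
                         "group_size", "beaufort", "swell_m", "platform"],
    )
    effort = pd.DataFrame(e_rows)
    return sightings, effort


def generate_dataset(config: SimConfig) -> SimDataset:
    """Generate a complete, internally consistent synthetic dataset."""
    config.validate()
    r_design, r_comp, r_dens, r_sight, _ = config.rngs(5)
    design = simulate_design(config, rng=r_design)
    lo, hi = config.beta_range
    beta = r_dens.uniform(lo, hi, config.driver_count) \
        * r_dens.choice([-1.0, 1.0], config.driver_count)
    counts, metadata, driver_set, anomalies = simulate_compositions(
        config, design, rng=r_comp, driver_signs=np.sign(beta),
    )
    density, beta, seasonal_means, _eps = simulate_density(
        config, design, anomalies, beta=beta, rng=r_dens
    )
    sightings, effort = simulate_sightings(config, design, density, rng=r_sight)
    truth = SimTruth(
        driver_set=driver_set,
        beta=beta,
        anomalies=anomalies,
        true_density=density,
        seasonal_means=seasonal_means,
        detection_params=config.detection,
        sigma_eps=config.sigma_eps,
        quarters=design.cruises["quarter"].to_numpy(),
    )
    return SimDataset(
        sightings=sightings, effort=effort, counts=counts,
        metadata=metadata, design=design, truth=truth,
    )
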