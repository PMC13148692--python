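# Methods

## Overview

`cetadens` links two survey data streams collected on the same quarterly
cruises — line-transect whale sightings and amplicon (ASV) count tables
from seawater eDNA — through a seasonally-adjusted log-contrast regression
estimated by sparse partial least squares with stability selection. This
note records the model, the assumptions, the tunable parameters and their
defaults, what the synthetic-data generator does and does not emulate, and
the numerical and design choices made where more than one reasonable option
existed.

## Distance-sampling density estimation

Detections of a species at perpendicular distance x with covariates z are
modelled by a detection function g(x, z) on [0, w], w = 2400 m by default.
Key functions: uniform, half-normal `exp(-x²/2σ²)`, hazard-rate
`1 - exp(-(x/σ)^-b)`. Two candidate sets are searched by forward AIC
selection, mirroring standard multiple-covariate distance sampling
practice: (A) each key plus series adjustments added one order at a time
(cosine orders 1–3 for uniform, 2–3 for half-normal; simple even
polynomials (x/w)⁴, (x/w)⁶ for hazard-rate), and (B) half-normal and
hazard-rate keys with sighting covariates (Beaufort, swell, observer
platform height as a 3-level factor, group size) entering the scale as
log σ(z) = β₀ + βᵀz. The log link is chosen for positivity; the adjusted
function is rescaled to g(0) = 1 and clipped to [0, 1]. Maximisation uses
multi-start L-BFGS-B on (log σ, log b, α, β); the likelihood of x given z
is g(x,z)/∫₀ʷg, with integrals by 101-point Gauss–Legendre quadrature
(final reported p̂ uses adaptive quadrature at 1e-8 tolerance). Goodness of
fit is the Cramér–von Mises statistic on the fitted CDF values.

Density per cruise is the Horvitz–Thompson-style estimator
y_i = 1/(2L_i w) Σ s_g/p̂_g, converted to individuals per 1000 km²
(L in km, w in m). Cruises without sightings get y_i = 0. The variance
combines, on the CV scale, an effort-weighted between-transect
encounter-rate estimator (R2-style: var(n/L) = K/(L(K-1)) Σ l_k(n_k/l_k -
n/L)²; pluggable, since the choice of encounter-rate estimator is
conventional) with a delta-method detection component from the observed
information matrix. Single-transect cruises carry only the detection
component and are flagged. No correction for g(0) < 1 or size-biased
detection is attempted.

## Compositional transform

Per marker (16S, 18S-V4, 18S-V9 processed fully independently):

1. **Prevalence filter.** ASVs present in fewer than 1% or more than 99%
   of all samples (pooled over cruises; presence = count > 0; boundaries
   inclusive) are removed — neither rare nor ubiquitous taxa vary enough to
   predict anything.
2. **Zero replacement.** Count zeros are replaced by the geometric
   Bayesian-multiplicative rule: in a sample with total n, a zero for ASV j
   becomes t_j·s/(n+s), with the prior t from the geometric mean of the
   ASV's observed per-sample proportions (renormalised) and prior strength
   s; observed proportions are shrunk multiplicatively so the sample still
   sums to one. **Default s = J (the number of retained ASVs)**, a total
   prior mass of one pseudo-read per part. This places replacements just
   below the detection limit 1/n. A much weaker prior (s = 1) would impute
   roughly two orders of magnitude below the detection limit at typical
   library sizes, creating −9 natural-log outliers whenever a
   mid-prevalence taxon drops out of a sample; those outliers dominate the
   variance of the log-ratio matrix and drown real signal. Both s and t
   are configurable.
3. **Aggregation.** Samples aggregate to cruises by a weighted geometric
   mean, x_ij = Π (x_ijklm)^w_klm. Weights are inversely proportional to
   local spatial sampling density (1/number of samples at the station) and
   carry a depth factor (r for the deep-chlorophyll-maximum stratum, 1−r
   for surface) with r chosen on an interior grid [0.05, 0.95] to maximise
   the Shannon entropy of the aggregated composition, ties toward the DCM.
   Endpoints are excluded so weights stay strictly positive.
4. **Centring.** z_ij = x_ij/g_i with g_i the geometric mean over retained
   ASVs; z is kept on the ratio scale (z = 2 means twice the typical ASV)
   and logs are applied only in the model.

## Seasonal adjustment and the log-contrast model

Quarter labels index seasonality. For any positive series, the seasonal
geometric mean g(i,·) is the geometric mean over the cruises sharing i's
quarter *within the active data partition*; held-out cruises are always
adjusted with training-only means (no leakage). Zero densities (a species
unseen on a cruise) receive an offset of half the smallest nonzero density
of the series before log-ratios; the fraction is configurable and the
choice matters only for strongly seasonal, rarely-sighted species.

The regression is log(y_i/g(i,y)) = β₀ + Σ_j β_j log(z_ij/g(i,z_j)) + ε.
Natural logs are used internally; reported association measures convert to
the per-doubling scale, m = 2^β (a power law's exponent is base-free).

## Estimation: SIMPLS, sparse PLS, stability selection

SIMPLS extracts K latent components T = ZA with unit-norm loadings and
mutually orthogonal scores, maximising squared covariance with the
response; coefficients back-propagate as β* = A(TᵀT)⁻¹TᵀY. At full rank it
reproduces least squares (tested to 1e-8). The sparse variant
soft-thresholds each component's direction surrogate at λ·max|direction|,
λ ∈ [0, 1); surviving variables (the active set) get coefficients from a
dense SIMPLS refit (a no-refit variant is available). λ = 0 reproduces
SIMPLS; λ → 1 keeps at most one variable per component.

Selection probabilities π_j(λ) are the fraction of exhaustive leave-one-out
folds in which β_j^λ ≠ 0, with seasonal adjustments recomputed per fold;
the procedure is deterministic given the data and grids. The sparsity
region Λ keeps the grid values (default 21 points on [0.5, 0.95]) whose
average model size q_λ satisfies the per-family error-rate bound
q_λ²/((2π_max−1)p) ≤ PFER, defaults π_max = 0.9 and PFER = 0.5. The stable
set is every variable reaching π_max somewhere in Λ. K is chosen on a grid
(default 4–12) by leave-one-out mean squared prediction error of the
SIMPLS fit on each K's stable set, ties to the smaller K; the final fit
truncates K to min(K, |S|, n−1).

**Known behaviour of the leave-one-out substitution.** The per-family
error-rate heuristic was derived for half-sample subsampling, where
selection events across subsamples decorrelate. Leave-one-out folds share
n−1 of n cruises, so π is nearly binary and the heuristic undercontrols:
in null simulations (25 cruises, 500 ASVs, response independent of the
community) the mean stable-set size is ≈ 1.6 rather than ≤ 0.5. The
package implements the leave-one-out scheme as specified; users wanting
calibrated error control should interpret the PFER level as nominal.

## Validation

Outer validation reruns the entire selection pipeline holding out one
cruise at a time; agreement among the n stable sets is the thresholded
Jaccard index J_α (fraction of the union selected in ≥ nα sets, α = 0.5
by default). Predictive skill is leave-one-out RMSPE and correlation on
the log-ratio and original scales (ŷ = g(i,y)·exp(û), training-only
seasonal means), benchmarked as percent error reduction against the lag
baseline (chronologically nearest prior same-quarter observation; nearest
subsequent at the series start) and the mean baseline (training-quarter
geometric mean, matching the pipeline's seasonal means; an arithmetic
variant is available). Prediction intervals come from a quarter-stratified
cruise bootstrap (percentiles on the log scale, back-transformed; default
B = 200, level 0.90) on the fixed stable set. Out-of-sample predictions
reuse the full-data stable set by default; per-fold reselection is
available (`reselect=True`).

## Synthetic-data generator

The generator emulates the survey's joint structure: one cruise per
(year, quarter) over 7 years, 25 cruises kept; 2–7 transects per cruise
(effort 150–450 km each) with 3 stations sampled at two depths; latent
log abundances = ASV baseline (sd 2) + quarter effect (sd 0.75) +
onshore–offshore gradient (sd 0.5) + depth effect (sd 0.5) + per-cruise
driver anomaly + sample noise (sd 0.5); softmax then multinomial counts at
library size 10 000, so zeros arise naturally (logistic-normal model).
Default 5 driver ASVs carry independent per-cruise anomalies (sd 0.5
natural-log units; an optional shared habitat factor lets them co-vary) and
baselines targeted at ~8 reads per sample — quantifiable without being
ubiquitous, so they survive the prevalence filter. Density is
D_i = seasonal mean · exp(Σ β_j v_ij + ε), β uniform on ±[1, 1.5],
ε ~ N(0, 0.2²); seasonal means follow a summer-peaked pattern
(winter 0.4, spring 1.0, summer 2.5, fall 0.7 × 2.4 individuals per
1000 km²), giving simulated densities in the 0.2–25 per 1000 km² range of
the real estimated series. Sightings are Poisson per transect with mean
2wLD·10⁻⁶/E[s], uniform candidate distances thinned by the configured
detection function (half-normal σ = 1200 m by default), zero-truncated
Poisson group sizes (mean 1.2), and categorical/continuous sighting
covariates. All randomness flows from one seed through per-component
sub-streams.

What the generator does **not** emulate: spatially explicit whale
movement, raw sequence reads and their processing, taxonomic structure,
between-marker correlation beyond shared cruise effects, temporal
autocorrelation of anomalies, and eDNA measurement biases (extraction,
primer, amplification). Passing recovery tests therefore show that the
pipeline finds planted compositional signal under realistic sparsity and
seasonality — not that real surveys contain such signal.

## Numerical choices and degenerate inputs

* Rank-deficient PLS problems stop early at the achieved component count.
* An empty active set (λ too aggressive) returns an intercept-only model;
  an empty stable set predicts the seasonal mean.
* Empty sparsity regions raise a diagnostic error with the smallest
  attainable PFER bound; in calibration experiments they are counted as
  empty selections.
* Detection fits that fail to converge after 5 starts are flagged, and
  model selection skips candidates that error, recording them in the trace.
* Quadrature: 101-point Gauss–Legendre inside likelihoods (smooth
  integrands, sub-1e-10 error at these scales), adaptive quadrature at
  1e-8 for reported detection probabilities.
* CLR identities hold to 1e-10; imputation closure to 1e-12.

## Problem sizes used in the bundled experiments

Calibration and recovery experiments run at 25 cruises and 300–500
candidate ASVs with 100 null replicates and 20 recovery replicates —
roughly a tenth of the real candidate count per marker, which keeps the
full nested procedures exhaustive. Generation scales linearly in p and was
exercised up to p = 6000.

## Known limitations

* The per-family error rate is nominal under leave-one-out subsampling
  (see above); stable sets under weak signal are larger than the bound.
* With small stable sets, truncating K to |S| makes the final fit plain
  least squares, losing PLS shrinkage; out-of-sample predictions can
  overshoot at extreme cruises. In the intended regime (stable sets of a
  few dozen taxa) this does not arise.
* Detection-function variance uses a numerically inverted observed
  information matrix; for very small sighting counts the delta-method CV
  is unstable and should be read qualitatively.
* The depth-weighting entropy criterion and the spatial-density weight are
  one reasonable formalisation of "inverse spatial sampling density" and
  "alpha-diversity-maximising" weighting; alternatives plug in through
  `aggregation_weights`.
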