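# cetadens

Predicting baleen-whale density from planktonic community composition.

Quarterly oceanographic surveys collect two very different kinds of data at
once: visual line-transect sightings of whales, and seawater eDNA samples
whose amplicon sequencing yields counts of thousands of amplicon sequence
variants (ASVs) of bacteria, protists and small zooplankton. `cetadens`
implements the full statistical pipeline that connects them — estimating
per-cruise whale density from the sightings, reducing the ASV tables to
cruise-level compositional predictors, and finding the small planktonic
subcommunity whose seasonal anomalies track the whales'.

## The model

**Stage 1 — density.** For each species, a detection function g(x, z)
(uniform, half-normal or hazard-rate key; series adjustments or covariates
on the scale parameter, chosen by forward AIC selection; Cramér–von Mises
goodness of fit) is fitted to perpendicular sighting distances truncated at
w = 2400 m. Density on cruise *i* is

    y_i = 1 / (2 L_i w) · Σ_g s_g / p̂_g(z_g),      p̂_g = (1/w) ∫₀ʷ ĝ(x, z_g) dx

in individuals per 1000 km², with variance combining a between-transect
encounter-rate component and a delta-method detection component.

**Stage 2 — composition.** ASV counts are prevalence-filtered (kept when
present in 1–99% of samples), zeros are replaced by geometric
Bayesian-multiplicative imputation, samples are aggregated to cruises by a
weighted geometric mean, and each cruise's aggregated abundances x_ij are
centred by their geometric mean g_i to give typical-abundance ratios
z_ij = x_ij / g_i (z = 2 reads "twice as abundant as the typical ASV").

**Stage 3 — seasonally-adjusted log-contrast regression.** With quarter
geometric means g(i,·), the model is

    log(y_i / g(i,y)) = β₀ + Σ_j β_j · log(z_ij / g(i,z_j)) + ε_i

so 2^β_j is the multiplicative change in median density per doubling of ASV
j's seasonally-adjusted ratio. Because p ≫ n, coefficients are estimated by
SIMPLS partial least squares (β* = A(TᵀT)⁻¹TᵀY); variables are selected by
stability selection over sparse-PLS fits on exhaustive leave-one-out folds,
with the sparsity region chosen to bound the per-family error rate and the
component count K chosen by leave-one-out prediction error. Seasonal means
are recomputed inside every fold so held-out cruises never leak into their
own adjustment. Validation reports nested-LOO selection consistency (a
thresholded Jaccard index), out-of-sample RMSPE against carry-forward (lag)
and seasonal-mean baselines, and bootstrap percentile intervals.

A synthetic-data generator (`cetadens.simulate`) produces joint
survey/sighting/ASV datasets with this exact structure and a recorded
planted truth, for parameter-recovery and null-calibration experiments.

## Worked example

```sh
cetadens --seed 1 run --outdir demo_out
```

generates a self-contained synthetic survey (25 quarterly cruises, 200
candidate ASVs, 5 planted drivers), estimates whale density from the
simulated sightings, runs the selection pipeline and prints

```
whale/16S: |S|=3, K=4, RMSPE=9.931 per 1000 km^2
artifacts in demo_out
```

`demo_out/model_whale_16S.json` holds the full report. In this run the
selected detection function was hazard-rate with a swell covariate (CvM
p = 0.88, i.e. no evidence of misfit); the 3-member stable set contains two
of the five planted drivers; leave-one-out predictions correlate 0.90 with
the estimated densities on the original scale; and the model's prediction
error is 44.5% below the lag baseline and 38.6% below the seasonal-mean
baseline — the two naive forecasts it must outperform to be useful. The
per-ASV association measures (2^β per doubling) are in
`demo_out/coefficients_whale_16S.csv`.

The same stages are available as library calls — see
`cetadens.fit_detection_function`, `cetadens.cruise_composition`,
`cetadens.StabilitySelector`, `cetadens.loo_predictions` — and compose with
scikit-learn (`SIMPLSRegressor` and `SparsePLSRegressor` are ordinary
sklearn estimators).

## Documentation

`docs/methods.md` describes the statistical model, the generator's design
and its limits, numerical choices and known limitations.
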