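import numpy as np
import pandas as pd
import pytest
from scipy.special import erf

from cetadens.distance import (
    DetectionFunction,
    average_detection_probability,
    cvm_gof,
    density_variance,
    estimate_density,
    fit_detection_function,
    select_detection_model,
)
from cetadens.simulate import DetectionConfig, SimConfig, simulate_design, simulate_sightings


def _sightings(distances, **cov):
    n = len(distances)
    base = {"cruise": ["c1"] * n, "transect": ["t1"] * n,
            "species": ["whale"] * n, "distance_m": distances,
            "group_size": [1] * n, "beaufort": [2] * n,
            "swell_m": [1.0] * n, "platform": ["mid"] * n}
    base.update(cov)
    return pd.DataFrame(base)


def _effort(rows):
    return pd.DataFrame(rows, columns=["cruise", "transect", "length_km",
                                       "truncation_w"])


class TestDetectionFit:
    def test_uniform_loglik_closed_form(self):
        s = _sightings(np.linspace(10, 2000, 25))
        fit = fit_detection_function(s, w=2400.0, key="uniform")
        assert fit.loglik_ == pytest.approx(-25 * np.log(2400.0))
        assert fit.aic_ == pytest.approx(-2 * fit.loglik_)

    def test_aic_definition(self, hn_distances):
        fit = fit_detection_function(hn_distances, w=2400.0, key="half-normal")
        assert fit.aic_ == pytest.approx(2 * fit.n_params_ - 2 * fit.loglik_)
        assert fit.n_params_ == 1

    def test_half_normal_sigma_recovery(self):
        # average the MLE over replicates so the check is on the Monte-Carlo
        # mean, not a single draw
        sigma_true, w = 1000.0, 2400.0
        sigma_hats = []
        for seed in range(10):
            rng = np.random.default_rng(seed)
            x = []
            while len(x) < 500:
                c = rng.uniform(0, w, 4000)
                keep = rng.uniform(size=4000) < np.exp(
                    -c**2 / (2 * sigma_true**2))
                x.extend(c[keep].tolist())
            fit = fit_detection_function(_sightings(np.array(x[:500])),
                                         w=w, key="half-normal")
            sigma_hats.append(float(np.exp(fit.params_[0])))
        sigma_hats = np.array(sigma_hats)
        se = sigma_hats.std(ddof=1) / np.sqrt(len(sigma_hats))
        assert abs(sigma_hats.mean() - sigma_true) < 3 * se

    def test_zero_sightings_error(self):
        with pytest.raises(ValueError):
            fit_detection_function(_sightings([]), w=2400.0)

    def test_beyond_truncation_rejected(self):
        with pytest.raises(ValueError, match="truncat"):
            fit_detection_function(_sightings([2500.0]), w=2400.0)

    def test_covariate_scale_monotonicity(self, hn_distances):
        # larger sigma(z) must give larger average detection probability
        s = hn_distances.copy()
        s["beaufort"] = np.r_[np.zeros(250), np.full(250, 4)].astype(int)
        fit = fit_detection_function(s, w=2400.0, key="half-normal",
                                     covariates=("beaufort",))
        p0 = average_detection_probability(fit, z_row=[0.0])
        p4 = average_detection_probability(fit, z_row=[4.0])
        sig0, sig4 = np.exp(fit.params_[0]), np.exp(fit.params_[0] + 4 * fit.params_[1])
        assert (p4 > p0) == (sig4 > sig0)


class TestModelSelection:
    def test_single_candidate_returned(self, hn_distances):
        fit, trace = select_detection_model(hn_distances, w=2400.0,
                                            covariates=())
        assert fit.aic_ == min(t["aic"] for t in trace if t.get("aic"))

    def test_forward_selection_contract(self, hn_distances):
        # an adjustment that does not lower AIC is not part of the best model,
        # and the rejection is visible in the trace
        fit, trace = select_detection_model(hn_distances, w=2400.0)
        by_model = {
            (t.get("key"), tuple(t.get("adjustment_orders", ()))): t["aic"]
            for t in trace
            if t.get("aic") is not None and not t.get("covariates")
        }
        chosen = (fit.key, tuple(fit.adjustment_orders))
        if fit.adjustment_orders:
            base = (fit.key, tuple(fit.adjustment_orders)[:-1])
            assert by_model[chosen] < by_model[base]
        rejected = [t for t in trace if t.get("accepted") is False]
        for t in rejected:
            base = (t["key"], tuple(t["adjustment_orders"])[:-1])
            assert t["aic"] >= by_model[base]

    def test_selected_model_is_overall_aic_minimum(self, hn_distances):
        fit, trace = select_detection_model(hn_distances, w=2400.0)
        fitted = [t["aic"] for t in trace if t.get("aic") is not None]
        assert fit.aic_ <= min(fitted) + 1e-9

    def test_half_normal_family_usually_recovered(self):
        # data simulated from a half-normal detection process: the selected
        # key should be half-normal more often than any other key
        keys = []
        for rep in range(10):
            rng = np.random.default_rng(rep)
            x = []
            while len(x) < 300:
                c = rng.uniform(0, 2400, 3000)
                keep = rng.uniform(size=3000) < np.exp(-c**2 / (2 * 1000.0**2))
                x.extend(c[keep].tolist())
            fit, _ = select_detection_model(_sightings(np.array(x[:300])),
                                            w=2400.0, covariates=())
            keys.append(fit.key)
        counts = pd.Series(keys).value_counts()
        assert counts.idxmax() == "half-normal"


class TestCvM:
    def test_minimum_statistic_at_uniform_quantiles(self):
        n = 8
        u = (2 * np.arange(1, n + 1) - 1) / (2 * n)

        class Dummy:
            cdf_values_ = u

        stat, _ = cvm_gof(Dummy())
        assert stat == pytest.approx(1 / (12 * n), abs=1e-12)

    def test_hand_evaluated_four_point_example(self):
        u = np.array([0.1, 0.3, 0.6, 0.9])

        class Dummy:
            cdf_values_ = u

        stat, p = cvm_gof(Dummy())
        expected = 1 / 48 + sum(
            (ui - (2 * i - 1) / 8) ** 2 for i, ui in enumerate(u, start=1)
        )
        assert stat == pytest.approx(expected, abs=1e-12)
        assert 0 < p < 1

    def test_pvalues_from_fitted_model_roughly_uniform(self, hn_distances):
        fit = fit_detection_function(hn_distances, w=2400.0, key="half-normal")
        _, p = cvm_gof(fit)
        assert p > 0.01  # correctly specified model should not be rejected

    def test_empty_errors(self):
        class Dummy:
            cdf_values_ = np.array([])

        with pytest.raises(ValueError):
            cvm_gof(Dummy())


class TestAverageDetectionProbability:
    def test_uniform_key_is_one(self):
        fit = fit_detection_function(_sightings([100.0, 900.0]), w=2400.0,
                                     key="uniform")
        assert average_detection_probability(fit) == pytest.approx(1.0, abs=1e-9)

    def test_half_normal_closed_form(self, hn_distances):
        fit = fit_detection_function(hn_distances, w=2400.0, key="half-normal")
        sigma = np.exp(fit.params_[0])
        w = 2400.0
        closed = np.sqrt(np.pi / 2) * (sigma / w) * erf(w / (sigma * np.sqrt(2)))
        assert average_detection_probability(fit) == pytest.approx(closed, abs=1e-6)


class TestDensityEstimator:
    def test_unit_example_with_conversion(self):
        # L = 1000 km, w = 2400 m, one detection, s = 1, p_hat = 0.5
        # -> 1/2400 per km^2 = 0.41667 per 1000 km^2; with p_hat = 1 it is half
        s = _sightings([100.0])
        eff = _effort([["c1", "t1", 1000.0, 2400.0]])
        fit = fit_detection_function(s, w=2400.0, key="uniform")  # p_hat = 1
        d = estimate_density(s, eff, fit)
        assert d.loc["c1", "density"] == pytest.approx(1000 / (2 * 1000 * 2.4))
        # strip count / area equivalence when p_hat == 1
        area_1000km2 = 2 * 1000 * 2.4 / 1000
        assert d.loc["c1", "density"] == pytest.approx(1 / area_1000km2)

    def test_no_detection_cruise_zero(self):
        s = _sightings([100.0])
        eff = _effort([["c1", "t1", 1000.0, 2400.0],
                       ["c2", "t1", 500.0, 2400.0]])
        fit = fit_detection_function(s, w=2400.0, key="uniform")
        d = estimate_density(s, eff, fit)
        assert d.loc["c2", "density"] == 0.0
        assert d.loc["c2", "n_sightings"] == 0

    def test_linearity_in_group_size(self):
        s1 = _sightings([100.0, 500.0])
        s2 = s1.copy()
        s2["group_size"] = 2
        eff = _effort([["c1", "t1", 800.0, 2400.0]])
        fit = fit_detection_function(s1, w=2400.0, key="uniform")
        d1 = estimate_density(s1, eff, fit)
        d2 = estimate_density(s2, eff, fit)
        assert d2.loc["c1", "density"] == pytest.approx(
            2 * d1.loc["c1", "density"])

    def test_missing_effort_errors(self):
        s = _sightings([100.0])
        eff = _effort([["other", "t1", 100.0, 2400.0]])
        fit = fit_detection_function(s, w=2400.0, key="uniform")
        with pytest.raises(ValueError, match="no effort"):
            estimate_density(s, eff, fit)


class TestDensityVariance:
    def test_identical_encounter_rates_zero_component(self):
        s = pd.concat([_sightings([100.0, 200.0]),
                       _sightings([300.0, 400.0])]).reset_index(drop=True)
        s.loc[2:, "transect"] = "t2"
        eff = _effort([["c1", "t1", 500.0, 2400.0],
                       ["c1", "t2", 500.0, 2400.0]])
        fit = fit_detection_function(s, w=2400.0, key="uniform")
        v = density_variance(s, eff, fit)
        assert v.loc["c1", "cv_encounter"] == pytest.approx(0.0, abs=1e-12)

    def test_pythagorean_cv_combination(self):
        assert np.hypot(0.3, 0.4) == pytest.approx(0.5)

    def test_single_transect_flagged(self):
        s = _sightings([100.0, 700.0])
        eff = _effort([["c1", "t1", 500.0, 2400.0]])
        fit = fit_detection_function(s, w=2400.0, key="half-normal")
        with pytest.warns(UserWarning, match="single transect"):
            v = density_variance(s, eff, fit)
        assert not v.loc["c1", "encounter_component_available"]
        assert v.loc["c1", "cv"] == pytest.approx(v.loc["c1", "cv_detection"])


class TestEstimatorUnbiasedness:
    def test_mean_density_ratio_near_one(self):
        # simulated surveys from known half-normal detection and known density
        cfg = SimConfig(
            n_years=2, n_cruises=8, transects_per_cruise=(4, 4),
            effort_km_range=(400.0, 400.0), mean_group_size=1.0,
            detection=DetectionConfig(key="half-normal", sigma_m=1200.0),
            seed=21,
        )
        d_true = 20.0
        ratios = []
        for rep in range(25):
            cfg_r = SimConfig(**{**cfg.__dict__, "seed": 100 + rep})
            design = simulate_design(cfg_r)
            sightings, effort = simulate_sightings(
                cfg_r, design, np.full(8, d_true))
            fit = fit_detection_function(sightings, w=2400.0,
                                         key="half-normal")
            d = estimate_density(sightings, effort, fit)
            ratios.append(d["density"].mean() / d_true)
        assert 0.95 < np.mean(ratios) < 1.05
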