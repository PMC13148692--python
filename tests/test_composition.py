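import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from cetadens.composition import (
    aggregate_to_cruise,
    aggregation_weights,
    cruise_composition,
    filter_prevalence,
    impute_zeros_gbm,
    typical_ratio,
)


def _table(counts, samples=None):
    counts = np.asarray(counts)
    idx = samples or [f"s{i}" for i in range(counts.shape[0])]
    return pd.DataFrame(counts, index=idx,
                        columns=[f"a{j}" for j in range(counts.shape[1])])


class TestPrevalenceFilter:
    def test_toy_prevalences(self):
        # 10 samples x 4 ASVs at prevalence 0%, 10%, 90%, 100%
        counts = np.zeros((10, 4), dtype=int)
        counts[0, 1] = 5
        counts[:9, 2] = 3
        counts[:, 3] = 2
        filtered, retained = filter_prevalence(_table(counts))
        assert retained == ["a1", "a2"]

    def test_rare_asv_removed_at_paper_sample_count(self):
        # present in 5 of 743 samples = 0.67% < 1%
        counts = np.ones((743, 2), dtype=int)
        counts[:, 1] = 0
        counts[:5, 1] = 4
        # column 0 is ubiquitous (100%) and also removed; add a keeper
        counts = np.column_stack([counts, np.r_[np.ones(700), np.zeros(43)].astype(int)])
        _, retained = filter_prevalence(_table(counts))
        assert "a1" not in retained and "a2" in retained

    def test_interior_prevalence_retained(self):
        counts = np.zeros((10, 2), dtype=int)
        counts[:5, 0] = 1
        counts[:, 1] = 1  # keeps every row total positive
        _, retained = filter_prevalence(_table(counts))
        assert "a0" in retained

    def test_empty_result_errors(self):
        counts = np.ones((10, 1), dtype=int)
        with pytest.raises(ValueError, match="no candidates"):
            filter_prevalence(_table(counts))

    def test_bad_thresholds(self):
        with pytest.raises(ValueError):
            filter_prevalence(_table(np.ones((3, 1), int)), lo=0.5, hi=0.4)


class TestGBMImputation:
    def test_hand_example(self):
        # counts (0, 5, 5), n = 10, s = 1, uniform prior
        counts = _table([[0, 5, 5]])
        out = impute_zeros_gbm(counts, prior_strength=1.0,
                               prior=np.array([1 / 3] * 3))
        assert out.iloc[0, 0] == pytest.approx(1 / 33)
        assert out.iloc[0, 1] == pytest.approx(0.5 * (1 - 1 / 33))
        assert out.iloc[0, 2] == pytest.approx(0.5 * (1 - 1 / 33))

    def test_sample_without_zeros_unchanged(self):
        counts = _table([[2, 3, 5], [0, 5, 5]])
        out = impute_zeros_gbm(counts)
        assert np.allclose(out.iloc[0], [0.2, 0.3, 0.5])

    def test_closure_and_positivity(self):
        rng = np.random.default_rng(1)
        counts = _table(rng.integers(0, 20, size=(12, 8)))
        counts.iloc[:, 0] = np.maximum(counts.iloc[:, 0], 1)  # avoid all-zero col
        counts = counts.loc[counts.sum(axis=1) > 0]
        out = impute_zeros_gbm(counts)
        assert np.allclose(out.sum(axis=1), 1.0, atol=1e-12)
        assert (out.to_numpy() > 0).all()

    def test_all_zero_asv_rejected(self):
        counts = _table([[1, 0], [2, 0]])
        with pytest.raises(ValueError):
            impute_zeros_gbm(counts)


class TestAggregationWeights:
    def _meta(self, stations, depths, cruise="c1"):
        return pd.DataFrame({
            "cruise": cruise, "transect": "t1",
            "station": stations, "depth": depths,
        }, index=[f"s{i}" for i in range(len(stations))])

    def test_single_sample_gets_unit_weight(self):
        w = aggregation_weights(self._meta(["st1"], ["surface"]))
        assert w.iloc[0] == pytest.approx(1.0)

    def test_inverse_station_density(self):
        meta = self._meta(["st1", "st1", "st2"], ["surface"] * 3)
        w = aggregation_weights(meta)
        assert np.allclose(w.to_numpy(), [0.25, 0.25, 0.5])

    def test_weights_positive_and_sum_one_per_cruise(self):
        meta = pd.DataFrame({
            "cruise": ["c1"] * 3 + ["c2"] * 2,
            "transect": "t", "station": ["a", "a", "b", "c", "d"],
            "depth": ["surface", "DCM", "surface", "DCM", "surface"],
        }, index=[f"s{i}" for i in range(5)])
        props = pd.DataFrame(
            np.full((5, 4), 0.25), index=meta.index, columns=list("wxyz")
        )
        w = aggregation_weights(meta, props)
        assert (w > 0).all()
        sums = w.groupby(meta["cruise"]).sum()
        assert np.allclose(sums, 1.0)

    def test_empty_cruise_errors(self):
        with pytest.raises(ValueError):
            aggregation_weights(self._meta([], []))


class TestAggregation:
    def test_two_point_geometric_mean(self):
        props = _table([[0.1, 0.9], [0.4, 0.6]])
        w = pd.Series([0.5, 0.5], index=props.index)
        cruises = pd.Series(["c1", "c1"], index=props.index)
        agg = aggregate_to_cruise(props, w, cruises)
        assert agg.iloc[0, 0] == pytest.approx(np.sqrt(0.1 * 0.4))

    def test_identical_samples_idempotent(self):
        props = _table([[0.2, 0.8]] * 3)
        w = pd.Series([1 / 3] * 3, index=props.index)
        cruises = pd.Series(["c1"] * 3, index=props.index)
        agg = aggregate_to_cruise(props, w, cruises)
        assert np.allclose(agg.iloc[0], [0.2, 0.8])

    def test_degenerate_weight_selects_first_sample(self):
        props = _table([[0.2, 0.8], [0.7, 0.3]])
        w = pd.Series([1.0, 0.0], index=props.index)
        cruises = pd.Series(["c1", "c1"], index=props.index)
        agg = aggregate_to_cruise(props, w, cruises)
        assert np.allclose(agg.iloc[0], [0.2, 0.8])

    def test_zero_proportion_rejected(self):
        props = _table([[0.0, 1.0]])
        w = pd.Series([1.0], index=props.index)
        with pytest.raises(ValueError):
            aggregate_to_cruise(props, w, pd.Series(["c1"], index=props.index))

    def test_cruise_order_of_first_appearance_kept(self):
        props = _table([[0.5, 0.5], [0.5, 0.5]])
        w = pd.Series([1.0, 1.0], index=props.index)
        cruises = pd.Series(["zeta", "alpha"], index=props.index)
        agg = aggregate_to_cruise(props, w, cruises)
        assert list(agg.index) == ["zeta", "alpha"]


class TestTypicalRatio:
    def test_worked_example(self):
        x = pd.DataFrame([[0.1, 0.2, 0.4]], index=["c1"], columns=list("abc"))
        z, g = typical_ratio(x)
        assert g.iloc[0] == pytest.approx(0.2)
        assert np.allclose(z.iloc[0], [0.5, 1.0, 2.0])

    def test_twice_the_geometric_mean_reads_two(self):
        x = pd.DataFrame([[0.1, 0.2, 0.4]], index=["c1"], columns=list("abc"))
        z, _ = typical_ratio(x)
        assert z.iloc[0, 2] == pytest.approx(2.0)

    def test_flat_composition_all_ones(self):
        x = pd.DataFrame([[0.25] * 4], index=["c1"])
        z, _ = typical_ratio(x)
        assert np.allclose(z, 1.0)

    def test_log_ratios_sum_to_zero(self):
        rng = np.random.default_rng(5)
        x = pd.DataFrame(rng.uniform(0.01, 1, size=(6, 9)))
        z, _ = typical_ratio(x)
        assert np.abs(np.log(z.to_numpy()).sum(axis=1)).max() < 1e-10


class TestScaleInvariance:
    @settings(max_examples=20, deadline=None, derandomize=True)
    @given(st.integers(2, 50))
    def test_rescaling_one_sample_leaves_z_unchanged(self, factor):
        rng = np.random.default_rng(9)
        counts = rng.integers(0, 30, size=(8, 6))
        counts[:, 0] += 1
        counts[0] += 1
        meta = pd.DataFrame({
            "cruise": ["c1"] * 4 + ["c2"] * 4, "transect": "t1",
            "station": list("aabb") * 2,
            "depth": ["surface", "DCM"] * 4,
        }, index=[f"s{i}" for i in range(8)])
        t1 = _table(counts)
        scaled = counts.copy()
        scaled[3] = scaled[3] * factor  # same composition, larger library
        t2 = _table(scaled)
        z1 = cruise_composition(t1, meta, lo=0.0, hi=1.0).z
        z2 = cruise_composition(t2, meta, lo=0.0, hi=1.0).z
        # scale change only perturbs the zero-imputation shrinkage, which is
        # O(s/n); compositional information is unchanged
        assert np.allclose(np.log(z1), np.log(z2), atol=0.15)

    def test_exact_invariance_without_zeros(self):
        counts = np.array([[4, 6, 10], [8, 12, 20], [5, 5, 10], [2, 8, 10]])
        meta = pd.DataFrame({
            "cruise": ["c1", "c1", "c2", "c2"], "transect": "t1",
            "station": list("abab"), "depth": ["surface"] * 4,
        }, index=[f"s{i}" for i in range(4)])
        z1 = cruise_composition(_table(counts), meta, lo=0.0, hi=1.0).z
        z2 = cruise_composition(_table(counts * 7), meta, lo=0.0, hi=1.0).z
        assert np.allclose(z1, z2, atol=1e-12)
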