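"""Plug-in estimators: conventions, symmetries, and brute-force oracles."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra import numpy as hnp

import hoconn
from hoconn import (
    DegenerateSignalError,
    RegionTimeSeries,
    cokurtosis,
    correlation2,
    coskewness,
    edge_connectivity_corrected,
    edge_connectivity_raw,
    edge_connectivity_redundant,
    sample_moment,
    standardize,
)
from hoconn import generative as g

from conftest import (
    oracle_cokurtosis,
    oracle_edge_raw,
    oracle_edge_redundant,
    oracle_moment,
    rows_of,
)


class TestStandardize:
    def test_row_1234_has_zero_mean_unit_variance(self):
        ts = standardize(RegionTimeSeries(np.array([[1.0, 2.0, 3.0, 4.0]]), ["A"]))
        assert abs(ts.data.mean()) < 1e-12
        assert abs((ts.data**2).sum() / 3 - 1.0) < 1e-12
        assert ts.standardized

    def test_idempotent(self, small_ts):
        again = standardize(small_ts)
        np.testing.assert_allclose(again.data, small_ts.data, atol=1e-12)

    def test_constant_row_raises_naming_region(self):
        ts = RegionTimeSeries(np.array([[1.0, 2.0, 3.0], [5.0, 5.0, 5.0]]), ["A", "B"])
        with pytest.raises(DegenerateSignalError, match="B"):
            standardize(ts)


class TestSampleMoment:
    def test_self_pair_is_biased_by_convention(self, small_ts):
        # 1/T moments on 1/(T-1)-variance rows give (T-1)/T, not 1
        T = small_ts.n_timepoints
        assert sample_moment(small_ts, ("A", "A")) == pytest.approx((T - 1) / T, abs=1e-12)

    def test_identical_rows_match_self_moment(self):
        row = np.array([0.3, -1.2, 2.0, -0.7, 1.1])
        ts = standardize(RegionTimeSeries(np.vstack([row, row]), ["A", "B"]))
        assert sample_moment(ts, ("A", "B")) == pytest.approx(
            sample_moment(ts, ("A", "A")), abs=1e-12
        )

    def test_matches_hand_loop_on_toy_matrix(self):
        ts = standardize(
            RegionTimeSeries(np.array([[1.0, 2, 3, 4], [4.0, 3, 2, 1]]), ["A", "B"])
        )
        rows = rows_of(ts)
        for idx in [("A", "B"), ("A", "A", "B"), ("A", "B", "A", "B")]:
            assert sample_moment(ts, idx) == pytest.approx(oracle_moment(rows, idx), abs=1e-12)

    def test_unknown_label_raises(self, small_ts):
        with pytest.raises(KeyError, match="Z"):
            sample_moment(small_ts, ("A", "Z"))


class TestCorrelation:
    def test_identical_and_antiequal_rows(self, rng):
        row = rng.standard_normal(50)
        ts = standardize(RegionTimeSeries(np.vstack([row, row, -row]), ["A", "B", "C"]))
        T = 50
        assert correlation2(ts, "A", "B").value == pytest.approx((T - 1) / T, abs=1e-12)
        assert correlation2(ts, "A", "C").value == pytest.approx(-(T - 1) / T, abs=1e-12)

    def test_independent_noise_near_zero(self, rng):
        T = 20_000
        ts = RegionTimeSeries(rng.standard_normal((2, T)), ["A", "B"])
        assert abs(correlation2(ts, "A", "B").value) < 3 / np.sqrt(T)

    def test_self_pair_warns(self, small_ts):
        with pytest.warns(UserWarning, match="self-pair"):
            est = correlation2(small_ts, "A", "A")
        assert est.value == pytest.approx(19 / 20, abs=1e-12)


class TestCoskewness:
    def test_reduces_to_univariate_skewness(self, rng):
        row = rng.standard_normal(200) ** 3  # skewed signal
        ts = standardize(RegionTimeSeries(np.vstack([row] * 3), ["A", "B", "C"]))
        x = ts.data[0]
        skew_1t = np.mean(x**3)  # third 1/T moment of the z-scored signal
        assert coskewness(ts, "A", "B", "C").value == pytest.approx(skew_1t, abs=1e-12)

    def test_gaussian_null_bound(self, rng):
        T = 100_000
        ts = RegionTimeSeries(rng.standard_normal((3, T)), ["A", "B", "C"])
        assert abs(coskewness(ts, "A", "B", "C").value) < 3 * np.sqrt(6 / T)

    def test_repeated_index_rejected(self, small_ts):
        with pytest.raises(ValueError, match="distinct"):
            coskewness(small_ts, "A", "A", "B")

    def test_closed_form_recovery(self):
        p = g.ARParams(n=3, psi=1.0, innovation=g.SkewNormalSpec(3.0), tau=2.0, r=0.4)
        ts = g.simulate(p, 1_000_000, seed=7)
        est = coskewness(ts, "R1", "R2", "R3").value
        # MC SE of the plug-in at this length is ~5e-3 * sqrt(1200/1e6)
        assert est == pytest.approx(g.true_coskewness(p), abs=0.006)


class TestCokurtosis:
    def test_univariate_reduction_is_excess_kurtosis(self, rng):
        row = rng.standard_t(6, 300)
        ts = standardize(RegionTimeSeries(np.vstack([row] * 4), ["A", "B", "C", "D"]))
        x = ts.data[0]
        m2, m4 = np.mean(x**2), np.mean(x**4)
        assert cokurtosis(ts, "A", "B", "C", "D").value == pytest.approx(
            m4 - 3 * m2**2, abs=1e-12
        )

    def test_gaussian_null_bound(self, rng):
        T = 100_000
        ts = RegionTimeSeries(rng.standard_normal((4, T)), ["A", "B", "C", "D"])
        assert abs(cokurtosis(ts, "A", "B", "C", "D").value) < 3 * np.sqrt(24 / T)

    def test_closed_form_recovery(self):
        p = g.ARParams(n=4, psi=1.0, innovation=g.StudentTSpec(8), tau=2.0, r=0.4)
        ts = g.simulate(p, 2_000_000, seed=8)
        est = cokurtosis(ts, "R1", "R2", "R3", "R4").value
        assert est == pytest.approx(g.true_cokurtosis(p), rel=0.1)


class TestEdgeConnectivity:
    def test_self_edge_raw_is_one(self, small_ts):
        est = edge_connectivity_raw(small_ts, ("A", "B"), ("A", "B"))
        assert est.value == pytest.approx(1.0, abs=1e-12)

    def test_raw_bounded(self, small_ts):
        for e2 in [("C", "D"), ("A", "C")]:
            assert abs(edge_connectivity_raw(small_ts, ("A", "B"), e2).value) <= 1.0

    def test_matches_product_signal_oracle(self, small_ts):
        rows = rows_of(small_ts)
        e1, e2 = ("A", "B"), ("C", "D")
        assert edge_connectivity_raw(small_ts, e1, e2).value == pytest.approx(
            oracle_edge_raw(rows, e1, e2), abs=1e-12
        )

    def test_redundant_matches_hand_evaluation_on_toy_matrix(self, rng):
        ts = standardize(RegionTimeSeries(rng.standard_normal((4, 6)), list("ABCD")))
        rows = rows_of(ts)
        assert edge_connectivity_redundant(ts, ("A", "B"), ("C", "D")).value == pytest.approx(
            oracle_edge_redundant(rows, ("A", "B"), ("C", "D")), abs=1e-12
        )

    def test_self_edge_redundant_is_one_and_corrected_consistent(self, small_ts):
        # for edge2 == edge1 the redundant expression is self-normalized
        red = edge_connectivity_redundant(small_ts, ("A", "B"), ("A", "B")).value
        assert red == pytest.approx(1.0, abs=1e-12)
        corr = edge_connectivity_corrected(small_ts, ("A", "B"), ("A", "B")).value
        rows = rows_of(small_ts)
        assert corr == pytest.approx(
            oracle_edge_raw(rows, ("A", "B"), ("A", "B"))
            - oracle_edge_redundant(rows, ("A", "B"), ("A", "B")),
            abs=1e-12,
        )

    def test_gaussian_data_raw_equals_redundant(self):
        p = g.ARParams(n=4, psi=0.0, innovation=g.StudentTSpec(8), tau=2.0, r=0.4)
        ts = g.simulate(p, 500_000, seed=9)
        raw = edge_connectivity_raw(ts, ("R1", "R2"), ("R3", "R4")).value
        red = edge_connectivity_redundant(ts, ("R1", "R2"), ("R3", "R4")).value
        assert raw - red == pytest.approx(0.0, abs=0.01)

    def test_independent_signals_redundant_vanishes(self, rng):
        T = 200_000
        ts = RegionTimeSeries(rng.standard_normal((4, T)), list("ABCD"))
        assert abs(
            edge_connectivity_redundant(ts, ("A", "B"), ("C", "D")).value
        ) < 5 / np.sqrt(T)

    def test_tracks_cokurtosis_on_heavy_tailed_data(self):
        # across independent heavy-tailed realizations the two fourth-order
        # measures capture the same sample features
        p = g.ARParams(n=4, psi=1.0, innovation=g.StudentTSpec(5), tau=2.0, r=0.4)
        rng = np.random.default_rng(42)
        ck, ec = [], []
        for _ in range(200):
            ts = g.simulate(p, 1200, seed=rng).standardize()
            ck.append(cokurtosis(ts, "R1", "R2", "R3", "R4").value)
            ec.append(edge_connectivity_corrected(ts, ("R1", "R2"), ("R3", "R4")).value)
        assert np.corrcoef(ck, ec)[0, 1] > 0.8


class TestSymmetries:
    def test_permutation_invariance_all_measures(self, small_ts):
        base3 = coskewness(small_ts, "A", "B", "C").value
        for perm in itertools.permutations("ABC"):
            assert coskewness(small_ts, *perm).value == pytest.approx(base3, abs=1e-12)
        base4 = cokurtosis(small_ts, "A", "B", "C", "D").value
        for perm in itertools.permutations("ABCD"):
            assert cokurtosis(small_ts, *perm).value == pytest.approx(base4, abs=1e-12)
        raw = edge_connectivity_raw(small_ts, ("A", "B"), ("C", "D")).value
        assert edge_connectivity_raw(small_ts, ("C", "D"), ("A", "B")).value == pytest.approx(
            raw, abs=1e-12
        )

    @settings(max_examples=25, deadline=None)
    @given(
        data=hnp.arrays(
            np.float64,
            (4, 12),
            elements=st.floats(-5, 5, allow_nan=False),
        )
    )
    def test_sign_symmetries_on_random_matrices(self, data):
        # rows must be non-constant to standardize
        data = data + np.linspace(0, 1, 12) * np.arange(1, 5)[:, None]
        try:
            ts = standardize(RegionTimeSeries(data, list("ABCD")))
        except DegenerateSignalError:
            return
        flipped_all = ts.with_data(-ts.data)
        assert coskewness(flipped_all, "A", "B", "C").value == pytest.approx(
            -coskewness(ts, "A", "B", "C").value, abs=1e-10
        )
        two_flip = ts.data.copy()
        two_flip[0] *= -1
        two_flip[1] *= -1
        ts2 = ts.with_data(two_flip)
        assert cokurtosis(ts2, "A", "B", "C", "D").value == pytest.approx(
            cokurtosis(ts, "A", "B", "C", "D").value, abs=1e-10
        )

    def test_all_measures_match_oracle_on_4x20(self, small_ts):
        rows = rows_of(small_ts)
        assert coskewness(small_ts, "A", "B", "C").value == pytest.approx(
            oracle_moment(rows, ("A", "B", "C")), abs=1e-12
        )
        assert cokurtosis(small_ts, "A", "B", "C", "D").value == pytest.approx(
            oracle_cokurtosis(rows, "A", "B", "C", "D"), abs=1e-12
        )
        e1, e2 = ("A", "B"), ("C", "D")
        assert edge_connectivity_corrected(small_ts, e1, e2).value == pytest.approx(
            oracle_edge_raw(rows, e1, e2) - oracle_edge_redundant(rows, e1, e2), abs=1e-12
        )


def test_estimate_dispatch_and_statistic(small_ts):
    est = hoconn.estimate(small_ts, "coskewness", ("A", "B", "C"))
    assert est.measure == "coskewness" and est.order == 3
    stat = hoconn.measure_statistic("edge_corrected", ("A", "B", "C", "D"))
    assert stat(small_ts) == pytest.approx(
        edge_connectivity_corrected(small_ts, ("A", "B"), ("C", "D")).value
    )
    with pytest.raises(ValueError, match="unknown measure"):
        hoconn.estimate(small_ts, "nope", ("A", "B"))
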