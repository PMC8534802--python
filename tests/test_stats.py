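"""Bland–Altman agreement and the assumption-checked Student's test."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from aortoflow.stats import bland_altman, percent_difference, students_test


class TestBlandAltman:
    def test_identity_series(self):
        a = np.array([1.0, 2.0, 3.0, 4.0])
        res = bland_altman(a, a)
        assert res.bias == 0.0 and res.sd_diff == 0.0
        assert res.loa_low == 0.0 and res.loa_high == 0.0
        assert res.diff_span == 0.0

    def test_three_point_hand_oracle(self):
        """Worked example: d = [-0.05, 0.1, -0.1]."""
        res = bland_altman([1.0, 1.1, 0.9], [1.05, 1.0, 1.0])
        assert res.bias == pytest.approx(-0.05 / 3.0, abs=1e-15)
        # sample SD with n-1: sqrt(((d - mean)^2).sum() / 2)
        d = np.array([-0.05, 0.1, -0.1])
        sd = float(np.sqrt(((d - d.mean()) ** 2).sum() / 2.0))
        assert res.sd_diff == pytest.approx(sd, abs=1e-15)
        assert res.sd_diff == pytest.approx(0.10408, abs=1e-5)
        assert res.loa_low == pytest.approx(-0.2207, abs=1e-4)
        assert res.loa_high == pytest.approx(0.1873, abs=1e-4)

    def test_planted_bias_recovery(self):
        from aortoflow.synthetic import generate_paired_flows

        a, b = generate_paired_flows(1000, true_bias=0.05, sd=0.02, seed=3)
        res = bland_altman(b, a)
        assert res.bias == pytest.approx(0.05, abs=0.002)

    def test_limits_cover_95_percent(self):
        rng = np.random.default_rng(11)
        a = rng.normal(2.0, 0.5, 10_000)
        b = a + rng.normal(0.1, 0.05, 10_000)
        res = bland_altman(a, b)
        d = a - b
        inside = np.mean((d >= res.loa_low) & (d <= res.loa_high))
        assert inside == pytest.approx(0.95, abs=0.01)

    @settings(derandomize=True, max_examples=30)
    @given(
        st.lists(st.floats(-10, 10), min_size=3, max_size=20),
        st.integers(0, 2**31 - 1),
    )
    def test_antisymmetric_in_arguments(self, xs, seed):
        rng = np.random.default_rng(seed)
        a = np.asarray(xs)
        b = a + rng.normal(0, 1, a.size)
        r1, r2 = bland_altman(a, b), bland_altman(b, a)
        assert r1.bias == pytest.approx(-r2.bias, abs=1e-12)
        assert r1.loa_low == pytest.approx(-r2.loa_high, abs=1e-12)
        assert r1.loa_high == pytest.approx(-r2.loa_low, abs=1e-12)
        assert r1.mean_span == r2.mean_span

    def test_length_mismatch_and_short_series_rejected(self):
        with pytest.raises(ValueError):
            bland_altman([1.0, 2.0], [1.0, 2.0, 3.0])
        with pytest.raises(ValueError):
            bland_altman([1.0, 2.0], [1.0, 2.0])


class TestStudentsTest:
    def test_identical_samples(self):
        x = np.array([1.0, 2.0, 3.0, 4.0, 5.0])
        rep = students_test(x, x)
        assert rep.statistic == 0.0
        assert rep.p_value == pytest.approx(1.0)
        assert rep.variant == "pooled"

    def test_separated_gaussians_reject(self):
        rng = np.random.default_rng(0)
        x = rng.normal(0.0, 1.0, 50)
        y = rng.normal(1.0, 1.0, 50)
        rep = students_test(x, y)
        assert rep.p_value < 1e-3

    def test_matches_permutation_oracle(self):
        """p-value agrees with a 10^4-permutation oracle within MC error."""
        from scipy.stats import permutation_test

        rng = np.random.default_rng(5)
        x = rng.normal(0.0, 1.0, 12)
        y = rng.normal(0.8, 1.0, 12)
        rep = students_test(x, y)

        def statistic(a, b, axis):
            return np.mean(a, axis=axis) - np.mean(b, axis=axis)

        oracle = permutation_test(
            (x, y),
            statistic,
            n_resamples=10_000,
            alternative="two-sided",
            random_state=1,
        )
        mc_sigma = np.sqrt(oracle.pvalue * (1 - oracle.pvalue) / 10_000)
        assert rep.p_value == pytest.approx(oracle.pvalue, abs=max(5 * mc_sigma, 0.02))

    def test_constant_series_degrades_to_welch(self):
        x = np.full(10, 3.0)
        y = np.array([1.0, 2.0, 3.0, 4.0, 2.5, 3.5, 1.5, 2.8, 3.2, 2.2])
        rep = students_test(x, y)
        assert rep.variant == "welch"
        assert "constant" in rep.notes

    def test_unequal_variances_pick_welch(self):
        rng = np.random.default_rng(2)
        x = rng.normal(0.0, 1.0, 60)
        y = rng.normal(0.0, 5.0, 60)
        rep = students_test(x, y)
        assert rep.variant == "welch"
        assert rep.variance_p < 0.05


class TestPercentDifference:
    def test_reporting_convention(self):
        assert percent_difference(1.0, 0.76) == pytest.approx(24.0)

    def test_no_change(self):
        assert percent_difference(3.7, 3.7) == 0.0

    def test_increase_is_negative(self):
        assert percent_difference(2.0, 2.5) == pytest.approx(-25.0)

    def test_zero_reference_rejected(self):
        with pytest.raises(ValueError):
            percent_difference(0.0, 1.0)
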