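"""Magnitude-based inference engine: chance triples, scale, labels."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy import stats

from hiecod.mbi import (chance_triple, classify_comparison, compare_paired,
                        log_transform, qualify_probability,
                        smallest_worthwhile_change)


def mc_chance_triple(mean_diff, sd_diff, n, swc, n_draws=200_000, seed=0):
    """Independent Monte-Carlo oracle: t-distributed true-value draws."""
    rng = np.random.default_rng(seed)
    true_vals = mean_diff + (sd_diff / np.sqrt(n)) * rng.standard_t(n - 1, n_draws)
    return ((true_vals > swc).mean(),
            ((true_vals >= -swc) & (true_vals <= swc)).mean(),
            (true_vals < -swc).mean())


class TestLogTransform:
    def test_unit_maps_to_zero_and_round_trip(self):
        assert log_transform(np.array([1.0]))[0] == 0.0
        x = np.array([0.5, 2.0, 37.3])
        assert np.allclose(np.exp(log_transform(x)), x, atol=1e-12)

    def test_percent_back_transformation(self):
        d = np.log(1.097)
        assert 100 * (np.exp(d) - 1) == pytest.approx(9.7)

    def test_nonpositive_rejected(self):
        with pytest.raises(ValueError):
            log_transform(np.array([1.0, 0.0]))


class TestSmallestWorthwhileChange:
    def test_values(self):
        assert smallest_worthwhile_change(0.0) == 0.0
        assert smallest_worthwhile_change(0.05) == pytest.approx(0.01)

    @given(st.floats(0, 10))
    def test_linearity(self, sd):
        assert smallest_worthwhile_change(2 * sd) == pytest.approx(
            2 * smallest_worthwhile_change(sd))


class TestChanceTriple:
    def test_zero_mean_is_symmetric(self):
        pg, ps, pl = chance_triple(0.0, 1.0, 11, 0.5)
        assert pg == pytest.approx(pl)
        assert pg + ps + pl == pytest.approx(1.0, abs=1e-12)

    def test_zero_swc_splits_mass(self):
        pg, ps, pl = chance_triple(0.0, 1.0, 11, 0.0)
        assert (pg, ps, pl) == pytest.approx((0.5, 0.0, 0.5))

    def test_matches_monte_carlo_oracle(self):
        triple = chance_triple(1.0, 1.5, 11, 0.5)
        oracle = mc_chance_triple(1.0, 1.5, 11, 0.5)
        assert np.allclose(triple, oracle, atol=0.005)

    def test_degenerate_se_gives_indicators(self):
        assert chance_triple(1.0, 0.0, 11, 0.5) == (1.0, 0.0, 0.0)
        assert chance_triple(-1.0, 0.0, 11, 0.5) == (0.0, 0.0, 1.0)
        assert chance_triple(0.2, 0.0, 11, 0.5) == (0.0, 1.0, 0.0)

    @given(mean=st.floats(-5, 5), sd=st.floats(0, 5), n=st.integers(2, 50),
           swc=st.floats(0, 2))
    def test_sums_to_one_and_in_range(self, mean, sd, n, swc):
        triple = chance_triple(mean, sd, n, swc)
        assert abs(sum(triple) - 1.0) < 1e-9
        assert all(0.0 <= p <= 1.0 for p in triple)

    @given(sd=st.floats(0.1, 3), swc=st.floats(0, 1),
           means=st.tuples(st.floats(-3, 3), st.floats(-3, 3)))
    def test_monotone_in_mean_difference(self, sd, swc, means):
        lo, hi = sorted(means)
        assert chance_triple(hi, sd, 11, swc)[0] >= chance_triple(lo, sd, 11, swc)[0]

    def test_large_n_limit(self):
        pg, _, _ = chance_triple(1.0, 1.0, 100_000, 0.5)
        assert pg > 0.999

    def test_small_n_rejected(self):
        with pytest.raises(ValueError):
            chance_triple(0.0, 1.0, 1, 0.5)


class TestQualitativeScale:
    @pytest.mark.parametrize("p,label", [
        (0.004, "almost certainly not"),
        (0.01, "almost certainly not"),
        (0.03, "very unlikely"),
        (0.25, "unlikely"),
        (0.50, "possible"),
        (0.75, "possible"),
        (0.90, "likely"),
        (0.96, "very likely"),
        (0.996, "almost certain"),
        (1.0, "almost certain"),
    ])
    def test_bins(self, p, label):
        assert qualify_probability(p) == label

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            qualify_probability(1.5)


class TestClassifyComparison:
    @pytest.mark.parametrize("triple,label", [
        ((0.57, 0.42, 0.00), "possibly higher"),
        ((0.02, 0.13, 0.85), "likely lower"),
        ((0.30, 0.40, 0.30), "unclear"),
        ((0.02, 0.96, 0.02), "very likely similar"),
        ((1.00, 0.00, 0.00), "almost certainly higher"),
    ])
    def test_labels(self, triple, label):
        assert classify_comparison(triple) == label


class TestComparePaired:
    def test_identical_vectors(self, rng):
        a = rng.uniform(5, 10, size=11)
        res = compare_paired(a, a.copy())
        assert res.mean_diff_pct == pytest.approx(0.0, abs=1e-9)
        assert "higher" not in res.label or res.label.startswith("possibly")

    def test_exact_ten_percent_shift(self, rng):
        a = rng.uniform(5, 10, size=11)
        res = compare_paired(a, 1.10 * a)
        assert res.mean_diff_pct == pytest.approx(10.0, abs=1e-9)
        assert res.label == "almost certainly higher"  # SE -> 0 limit
        assert res.chances == pytest.approx((1.0, 0.0, 0.0), abs=1e-12)

    def test_raw_scale_for_signed_outcomes(self, rng):
        a = rng.normal(-5, 2, size=11)
        res = compare_paired(a, a - 1.0, log_scale=False)
        assert res.mean_diff_pct == pytest.approx(-1.0, abs=1e-9)

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            compare_paired(np.ones(5), np.ones(6))

    def test_chances_consistent_with_label(self, rng):
        a = rng.uniform(5, 10, size=11)
        b = a * np.exp(rng.normal(0.05, 0.1, size=11))
        res = compare_paired(a, b)
        triple = res.chances
        assert classify_comparison(triple) == res.label
        assert sum(triple) == pytest.approx(1.0, abs=1e-9)
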