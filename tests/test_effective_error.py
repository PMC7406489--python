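"""Closed-form effective errors: printed anchors, limits, and linear-algebra oracles."""

import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from lgcdesign import (
    Formula,
    Target,
    TimeCoding,
    TimeGrid,
    effective_se,
    intercept_ee_finite,
    intercept_ee_wald,
    pattern_ee,
    slope_ee_finite,
    slope_ee_wald,
    variance_of_times,
)

# strictly-increasing time sets for property tests; integer-valued times keep
# the centered sums of squares away from catastrophic cancellation
times_strategy = st.lists(
    st.integers(min_value=-50, max_value=50), min_size=2, max_size=8, unique=True,
).map(lambda xs: [float(x) for x in sorted(xs)])


class TestSlopeWald:
    @pytest.mark.parametrize("times,expected", [
        ([1, 2, 3], 15.0), ([1, 2, 4], 6.43), ([1, 2, 5], 3.46),
        ([1, 3, 4], 6.43), ([1, 3, 5], 3.75), ([1, 4, 5], 3.46),
        ([2, 3, 4], 15.0), ([2, 3, 5], 6.43), ([2, 4, 5], 6.43),
        ([3, 4, 5], 15.0),
    ])
    def test_three_of_five_patterns(self, times, expected):
        """All ten 3-of-5 complete designs at residual variance 30."""
        assert slope_ee_wald(times, 30.0) == pytest.approx(expected, abs=0.005)

    @pytest.mark.parametrize("times,expected", [
        ([1, 2], 60.0), ([1, 2, 3], 15.0), ([1, 2, 3, 4], 6.0),
        ([1, 2, 3, 4, 5], 3.0), ([1, 4], 30 / 4.5),
    ])
    def test_nested_patterns(self, times, expected):
        assert slope_ee_wald(times, 30.0) == pytest.approx(expected, rel=1e-12)

    def test_single_occasion_is_infinite(self):
        assert slope_ee_wald([3], 30.0) == math.inf

    def test_equals_profiled_gls_information_oracle(self, rng):
        """1/EE equals the slope entry of the inverted OLS information matrix."""
        for _ in range(30):
            m = rng.integers(2, 8)
            t = np.sort(rng.uniform(0, 10, size=m))
            var_e = rng.uniform(0.5, 50)
            lam = np.column_stack([np.ones(m), t])
            info = lam.T @ lam / var_e
            slope_var_entry = np.linalg.inv(info)[1, 1]
            assert slope_ee_wald(t, var_e) == pytest.approx(slope_var_entry, rel=1e-9)

    @given(times=times_strategy, shift=st.floats(-100, 100, allow_nan=False))
    def test_translation_invariance(self, times, shift):
        base = slope_ee_wald(times, 30.0)
        shifted = slope_ee_wald([t + shift for t in times], 30.0)
        if math.isinf(base):
            assert math.isinf(shifted)
        else:
            assert shifted == pytest.approx(base, rel=1e-6)

    @given(times=times_strategy, lam=st.floats(0.1, 10, allow_nan=False))
    def test_scale_law(self, times, lam):
        base = slope_ee_wald(times, 30.0)
        scaled = slope_ee_wald([lam * t for t in times], 30.0)
        if math.isinf(base):
            assert math.isinf(scaled)
        else:
            assert scaled == pytest.approx(base / lam**2, rel=1e-6)

    @given(times=times_strategy, extra=st.floats(-60, 60, allow_nan=False))
    def test_adding_an_occasion_never_hurts(self, times, extra):
        if extra in times:
            return
        augmented = sorted(times + [extra])
        assert slope_ee_wald(augmented, 30.0) <= slope_ee_wald(times, 30.0) * (1 + 1e-9)

    @given(times=times_strategy)
    def test_denominator_identity(self, times):
        """Centered sum of squares equals (M-1) * Var(t)."""
        ee = slope_ee_wald(times, 30.0)
        var_t = variance_of_times(times)
        if var_t == 0:
            assert math.isinf(ee)
        else:
            assert ee == pytest.approx(30.0 / ((len(times) - 1) * var_t), rel=1e-9)


class TestSlopeFinite:
    def test_in_text_anchors(self):
        """Two-occasion follow-up precision with the intercept as a nuisance."""
        ee_12 = slope_ee_finite([1, 2], 30.0, 28.78)
        ee_14 = slope_ee_finite([1, 4], 30.0, 28.78)
        assert ee_12 == pytest.approx(14.7, abs=0.05)
        assert ee_14 == pytest.approx(3.4, abs=0.05)
        assert ee_12 / ee_14 == pytest.approx(4.3, abs=0.05)

    def test_converges_to_wald_limit(self):
        for times in ([1, 2], [1, 2, 5], [1, 3, 4, 5]):
            finite = slope_ee_finite(times, 30.0, 1e9)
            wald = slope_ee_wald(times, 30.0)
            assert finite == pytest.approx(wald, rel=1e-6)

    def test_rejects_nonpositive_intercept_var(self):
        with pytest.raises(ValueError, match="intercept_var"):
            slope_ee_finite([1, 2], 30.0, 0.0)

    def test_equals_random_intercept_information_oracle(self, rng):
        """1/EE equals t' V^{-1} t with V = var_i * J + var_e * I."""
        for _ in range(30):
            m = int(rng.integers(2, 7))
            t = np.sort(rng.uniform(1, 10, size=m))
            var_e = rng.uniform(0.5, 50)
            var_i = rng.uniform(0.5, 80)
            v = var_i * np.ones((m, m)) + var_e * np.eye(m)
            info = t @ np.linalg.inv(v) @ t
            assert slope_ee_finite(t, var_e, var_i) == pytest.approx(1 / info, rel=1e-9)


class TestInterceptWald:
    @pytest.mark.parametrize("times,expected", [
        ([0, 1, 4], 19.62),   # occasions {1,2,5}
        ([0, 2, 4], 25.00),   # occasions {1,3,5}
        ([0, 3, 4], 28.85),   # occasions {1,4,5}
    ])
    def test_three_occasion_patterns(self, times, expected):
        assert intercept_ee_wald(times, 30.0) == pytest.approx(expected, abs=0.005)

    def test_singleton_at_anchor(self):
        assert intercept_ee_wald([0], 30.0) == pytest.approx(30.0)

    @given(times=st.lists(st.integers(0, 50), min_size=2, max_size=8, unique=True)
           .map(lambda xs: [float(x) for x in sorted(xs)]),
           lam=st.floats(0.1, 10, allow_nan=False))
    def test_time_scale_invariance(self, times, lam):
        """Prolonging the study does not sharpen the intercept."""
        base = intercept_ee_wald(times, 30.0)
        scaled = intercept_ee_wald([lam * t for t in times], 30.0)
        if math.isinf(base):
            assert math.isinf(scaled)
        else:
            assert scaled == pytest.approx(base, rel=1e-6)


class TestInterceptFinite:
    def test_value_and_fisher_oracle(self):
        """EE for times {0,1,4} with slope nuisance variance 8.20."""
        got = intercept_ee_finite([0, 1, 4], 30.0, 8.20)
        assert got == pytest.approx(16.76, abs=0.005)
        # independent oracle: 1' V^{-1} 1 with V = var_s * tt' + var_e * I
        t = np.array([0.0, 1.0, 4.0])
        v = 8.20 * np.outer(t, t) + 30.0 * np.eye(3)
        info = np.ones(3) @ np.linalg.inv(v) @ np.ones(3)
        assert got == pytest.approx(1 / info, rel=1e-9)

    def test_random_draws_match_oracle(self, rng):
        for _ in range(30):
            m = int(rng.integers(1, 7))
            t = np.sort(rng.uniform(0, 10, size=m))
            t[0] = 0.0
            var_e = rng.uniform(0.5, 50)
            var_s = rng.uniform(0.5, 30)
            v = var_s * np.outer(t, t) + var_e * np.eye(m)
            info = np.ones(m) @ np.linalg.inv(v) @ np.ones(m)
            assert intercept_ee_finite(t, var_e, var_s) == pytest.approx(1 / info, rel=1e-9)

    def test_converges_to_wald_limit(self):
        for times in ([0, 1, 4], [0, 3, 4], [0, 1, 2, 3, 4]):
            finite = intercept_ee_finite(times, 30.0, 1e9)
            wald = intercept_ee_wald(times, 30.0)
            assert finite == pytest.approx(wald, rel=1e-6)

    def test_anchor_singleton(self):
        assert intercept_ee_finite([0], 30.0, 8.2) == pytest.approx(30.0)

    def test_rejects_nonpositive_slope_var(self):
        with pytest.raises(ValueError, match="slope_var"):
            intercept_ee_finite([0, 1], 30.0, -1.0)


class TestEffectiveSE:
    @pytest.mark.parametrize("ee,n,expected", [
        (3.0, 1000, 0.50), (3.0, 1250, 0.45), (30 / 8.75, 1250, 0.47),
        (45 / 13, 1666, 0.40), (3.75, 1666, 0.41),
    ])
    def test_reproduces_printed_column(self, ee, n, expected):
        assert effective_se(ee, 8.20, n) == pytest.approx(expected, abs=0.005)

    def test_zero_effective_error(self):
        assert effective_se(0.0, 5.0, 101) == pytest.approx(math.sqrt(2 / 100) * 5.0)

    def test_decreasing_in_n(self):
        values = [effective_se(3.0, 8.2, n) for n in (100, 500, 2000)]
        assert values == sorted(values, reverse=True)

    def test_small_n_rejected(self):
        with pytest.raises(ValueError, match="n must be"):
            effective_se(3.0, 8.2, 1)


class TestVarianceOfTimes:
    @pytest.mark.parametrize("times,expected", [
        ([1, 2, 5], 4.33), ([1, 2, 3], 1.0), ([1, 3, 5], 4.0), ([1, 2, 4], 2.33),
    ])
    def test_printed_values(self, times, expected):
        assert variance_of_times(times) == pytest.approx(expected, abs=0.005)

    def test_requires_two_times(self):
        with pytest.raises(ValueError):
            variance_of_times([3])


class TestPatternEEDispatch:
    def test_slope_uses_one_based_times(self, params, grid):
        got = pattern_ee([1, 2, 5], grid, params, Target.slope_var, Formula.wald_limit)
        assert got.value == pytest.approx(45 / 13)

    def test_intercept_uses_zero_anchored_times(self, params, grid):
        got = pattern_ee([1, 2, 5], grid, params, Target.intercept_var)
        assert got.value == pytest.approx(19.62, abs=0.005)

    def test_mean_targets_alias_variance_targets(self, params, grid):
        for occ in ([1, 2, 5], [1, 3, 5]):
            assert (pattern_ee(occ, grid, params, Target.slope_mean).value
                    == pattern_ee(occ, grid, params, Target.slope_var).value)
            assert (pattern_ee(occ, grid, params, Target.intercept_mean).value
                    == pattern_ee(occ, grid, params, Target.intercept_var).value)

    def test_accepts_grid_in_either_coding(self, params):
        one = TimeGrid([1, 2, 3, 4, 5], TimeCoding.one_based)
        zero = TimeGrid([0, 1, 2, 3, 4], TimeCoding.zero_anchored)
        for target in Target:
            assert (pattern_ee([1, 4, 5], one, params, target).value
                    == pytest.approx(pattern_ee([1, 4, 5], zero, params, target).value))
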