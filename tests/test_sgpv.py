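import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import assume, given, settings
from hypothesis import strategies as st
from scipy import stats

from phedas.errors import ConfigError, DegenerateIntervalError
from phedas.sgpv import NullInterval, SgpvRanker, classify, ppv, sgpv, sgpv_power

NULL = NullInterval.from_or(0.3, 1.5)

or_bound = st.floats(min_value=0.05, max_value=40.0, allow_nan=False)


def log_interval(or_lo, or_hi):
    return (math.log(or_lo), math.log(or_hi))


class TestNullInterval:
    def test_or_scale_bounds_are_log_transformed(self):
        assert NULL.lo == pytest.approx(math.log(0.3))
        assert NULL.hi == pytest.approx(math.log(1.5))

    def test_reversed_bounds_rejected(self):
        with pytest.raises(ConfigError):
            NullInterval.from_or(1.5, 0.3)

    def test_null_not_containing_one_warns(self):
        with pytest.warns(UserWarning, match="OR=1"):
            NullInterval.from_or(2.0, 3.0)


class TestSgpv:
    def test_disjoint_interval_scores_zero(self):
        assert sgpv(log_interval(1.62, 9.90), NULL) == 0.0

    def test_identical_intervals_score_one(self):
        assert sgpv((NULL.lo, NULL.hi), NULL) == 1.0

    def test_partial_overlap_hand_value(self):
        # overlap on the log scale is [0, ln 1.5]; |I| = ln 2 <= 2|N|
        expected = math.log(1.5) / math.log(2.0)
        assert sgpv(log_interval(1.0, 2.0), NULL) == pytest.approx(expected, abs=1e-12)

    def test_wide_interval_small_sample_correction(self):
        # interval 3x wider than the null, fully covering it
        wide = (NULL.lo - NULL.width, NULL.hi + NULL.width)
        expected = (NULL.width / (3 * NULL.width)) * (3 * NULL.width / (2 * NULL.width))
        assert sgpv(wide, NULL) == pytest.approx(expected)  # = 1/2

    def test_zero_width_interval_rejected(self):
        with pytest.raises(DegenerateIntervalError):
            sgpv((0.5, 0.5), NULL)

    @given(lo=or_bound, hi=or_bound)
    @settings(derandomize=True, max_examples=200)
    def test_zero_iff_disjoint_and_bounds(self, lo, hi):
        assume(lo < hi * 0.999)
        p = sgpv(log_interval(lo, hi), NULL)
        assert 0.0 <= p <= 1.0
        disjoint = hi <= 0.3 or lo >= 1.5
        assert (p == 0.0) == disjoint

    @given(lo=or_bound, hi=or_bound)
    @settings(derandomize=True, max_examples=200)
    def test_scale_equivariance_of_significance_calls(self, lo, hi):
        """The p=0 call set is identical for OR-scale and log-scale input."""
        assume(lo < hi * 0.999)
        p_log = sgpv(log_interval(lo, hi), NULL)
        import warnings

        with warnings.catch_warnings():
            # bounds deliberately interpreted as raw interval ends here
            warnings.simplefilter("ignore", UserWarning)
            null_or_scale = NullInterval(0.3, 1.5)
        p_or = sgpv((lo, hi), null_or_scale)
        assert (p_log == 0.0) == (p_or == 0.0)

    def test_classification_matches_p_delta(self):
        assert classify(0.0) == "significant"
        assert classify(1.0) == "confirmed_null"
        assert classify(0.3) == "inconclusive"


class TestSgpvPower:
    def test_deep_alternative_has_power_one(self):
        se = 0.2
        theta = NULL.hi + 10 * se
        assert sgpv_power(theta, se, NULL) == pytest.approx(1.0, abs=1e-6)

    def test_midpoint_of_wide_null_has_power_zero(self):
        se = 0.1
        wide = NullInterval(-5 * se, 5 * se)
        assert sgpv_power(0.0, se, wide) == pytest.approx(0.0, abs=1e-4)

    def test_symmetry_about_null_midpoint(self):
        null = NullInterval(-0.5, 0.5)
        for theta in (0.2, 0.9, 1.7):
            assert sgpv_power(theta, 0.3, null) == pytest.approx(
                sgpv_power(-theta, 0.3, null)
            )

    @pytest.mark.parametrize("theta,se", [(0.8, 0.2), (0.2, 0.3), (-1.6, 0.25)])
    def test_matches_monte_carlo_frequency(self, theta, se):
        rng = np.random.default_rng(42)
        n = 100_000
        z = stats.norm.ppf(0.975)
        draws = rng.normal(theta, se, n)
        emp = np.mean((draws - z * se > NULL.hi) | (draws + z * se < NULL.lo))
        ana = sgpv_power(theta, se, NULL)
        tol = 3 * math.sqrt(max(ana * (1 - ana), 1e-8) / n)
        assert abs(ana - emp) <= tol

    def test_requires_positive_se(self):
        with pytest.raises(ValueError):
            sgpv_power(0.5, 0.0, NULL)


class TestPpv:
    def test_prior_limits(self):
        interval = (0.5, 1.3)
        assert ppv(interval, NULL, pi0=1.0) == 0.0
        assert ppv(interval, NULL, pi0=0.0) == 1.0

    def test_symmetric_case_is_half(self):
        # f1 == f0 makes the averaged powers equal, so PPV = 1 - 1/2
        z = stats.norm.ppf(0.975)
        se = NULL.width / (2 * z)
        assert ppv((NULL.lo, NULL.hi), NULL, pi0=0.5, se=se) == pytest.approx(0.5)

    def test_monotone_decreasing_in_pi0(self):
        interval = (0.6, 1.5)
        values = [ppv(interval, NULL, pi0=p) for p in (0.1, 0.3, 0.5, 0.7, 0.9)]
        assert all(a > b for a, b in zip(values, values[1:]))

    def test_quadrature_matches_monte_carlo(self):
        rng = np.random.default_rng(7)
        n = 500_000
        for lo, hi in [(0.5, 1.3), (0.7, 2.0), (-0.1, 0.9)]:
            z = stats.norm.ppf(0.975)
            se = (hi - lo) / (2 * z)
            alpha = sgpv_power(rng.uniform(NULL.lo, NULL.hi, n), se, NULL).mean()
            pwr = sgpv_power(rng.uniform(lo, hi, n), se, NULL).mean()
            mc = 1 - 1 / (1 + pwr / alpha)
            assert ppv((lo, hi), NULL) == pytest.approx(mc, abs=0.005)

    def test_bad_pi0_rejected(self):
        with pytest.raises(ConfigError):
            ppv((0.5, 1.3), NULL, pi0=1.2)


class TestSgpvRanker:
    def _results(self):
        return pd.DataFrame(
            {
                "phecode": ["a", "b", "c", "d"],
                "theta": [1.4, 0.1, -2.0, 5.0],
                "se": [0.2, 0.2, 0.3, 10.0],
                "ci_lo": [1.0, -0.3, -2.6, -15.0],
                "ci_hi": [1.8, 0.5, -1.4, 25.0],
                "converged": [True, True, True, False],
                "separation": [False, False, False, True],
            }
        )

    def test_transform_adds_sgpv_ppv_classification(self):
        out = SgpvRanker(null_or=(0.3, 1.5)).transform(self._results())
        assert out.loc[0, "sgpv"] == 0.0
        assert out.loc[0, "classification"] == "significant"
        assert 0.0 < out.loc[0, "ppv"] <= 1.0
        assert out.loc[1, "classification"] in ("inconclusive", "confirmed_null")
        assert np.isnan(out.loc[1, "ppv"])  # PPV only defined at p_delta = 0

    def test_negative_direction_flag_not_a_p_change(self):
        out = SgpvRanker(null_or=(0.3, 1.5)).transform(self._results())
        assert out.loc[2, "sgpv"] == 0.0 and out.loc[2, "negative_direction"]
        assert not out.loc[0, "negative_direction"]

    def test_unconverged_rows_not_evaluated(self):
        out = SgpvRanker().transform(self._results())
        assert out.loc[3, "classification"] == "not_evaluated"
        assert np.isnan(out.loc[3, "sgpv"])

    def test_type_one_error_shrinks_with_information(self):
        """With theta at the point null, p=0 calls vanish as se shrinks."""
        rng = np.random.default_rng(3)
        z = stats.norm.ppf(0.975)
        rates = []
        for se in (0.4, 0.2, 0.1):  # shrinking se plays the role of growing n
            draws = rng.normal(0.0, se, 20_000)
            rates.append(
                np.mean((draws - z * se > NULL.hi) | (draws + z * se < NULL.lo))
            )
        assert rates[0] >= rates[1] >= rates[2]
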