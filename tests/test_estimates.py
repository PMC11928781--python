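"""Core ratio-estimate machinery: SE recovery, p-value functions, curves."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.stats import norm

from compatint import (
    AsymmetryWarning,
    RatioEstimate,
    ci_at_level,
    consonance_curve,
    min_level_to_exclude,
    p_value,
    se_from_ci,
)
from compatint.errors import (
    InvalidEstimateError,
    InvalidGridError,
    InvalidLevelError,
    InvalidNullError,
)
from compatint.sim import random_estimate

Q95 = norm.ppf(0.975)


def phi_erf(x):
    """Independent standard normal CDF via the error function."""
    return 0.5 * (1.0 + math.erf(x / math.sqrt(2.0)))


def symmetric_estimate(theta, se, level=0.95, label="sym"):
    q = norm.ppf(0.5 * (1 + level))
    return RatioEstimate(
        label, math.exp(theta), math.exp(theta - q * se), math.exp(theta + q * se), level
    )


class TestSeFromCi:
    @pytest.mark.parametrize(
        "lo, hi, level, expected, tol",
        [
            (0.40, 1.87, 0.95, 0.393433, 1e-5),  # bleeding CI
            (0.76, 0.96, 0.95, 0.059597, 1e-5),  # primary-endpoint CI
            (math.exp(-Q95), math.exp(Q95), 0.95, 1.0, 1e-12),  # unit-SE construction
        ],
    )
    def test_known_values(self, lo, hi, level, expected, tol):
        assert se_from_ci(lo, hi, level) == pytest.approx(expected, abs=tol)

    @pytest.mark.parametrize(
        "lo, hi, level, exc",
        [
            (1.87, 0.40, 0.95, InvalidEstimateError),  # inverted
            (-0.1, 1.0, 0.95, InvalidEstimateError),
            (0.0, 1.0, 0.95, InvalidEstimateError),
            (0.4, 1.87, 0.0, InvalidLevelError),
            (0.4, 1.87, 1.0, InvalidLevelError),
            (0.4, 1.87, 1.2, InvalidLevelError),
        ],
    )
    def test_invalid_inputs_rejected(self, lo, hi, level, exc):
        with pytest.raises(exc):
            se_from_ci(lo, hi, level)


class TestRatioEstimate:
    def test_point_outside_ci_rejected(self):
        with pytest.raises(InvalidEstimateError):
            RatioEstimate("bad", 2.0, 0.5, 1.5)

    def test_asymmetric_reported_ci_warns(self):
        # printed VOYAGER values are rounded, so ln(0.86) is not the exact
        # midpoint of (ln 0.40, ln 1.87)
        with pytest.warns(AsymmetryWarning):
            RatioEstimate("bleeding", 0.86, 0.40, 1.87)

    def test_symmetric_ci_does_not_warn(self, recwarn):
        symmetric_estimate(-0.2, 0.3)
        assert not [w for w in recwarn if issubclass(w.category, AsymmetryWarning)]

    def test_log_view_round_trips(self):
        est = symmetric_estimate(0.4, 0.25, level=0.9)
        log = est.to_log()
        assert math.exp(log.theta_hat) == pytest.approx(est.point, rel=1e-12)
        lo, hi = log.ci()
        assert lo == pytest.approx(est.ci_lower, rel=1e-10)
        assert hi == pytest.approx(est.ci_upper, rel=1e-10)


class TestPValue:
    def test_primary_vs_null_reproduces_published_p(self, primary):
        assert round(p_value(primary, 1.0).p, 3) == 0.006

    def test_bleeding_one_sided_vs_margin(self, bleeding):
        # H0: HR >= 1.25; evidence that the ratio lies below the margin
        assert p_value(bleeding, 1.25, "less").p == pytest.approx(0.17, abs=0.005)

    def test_p_is_one_at_the_point_estimate(self, bleeding):
        assert p_value(bleeding, bleeding.point).p == pytest.approx(1.0, abs=1e-12)

    def test_invalid_null_rejected(self, bleeding):
        with pytest.raises(InvalidNullError):
            p_value(bleeding, -1.0)
        with pytest.raises(InvalidNullError):
            p_value(bleeding, 0.0)
        with pytest.raises(InvalidNullError):
            p_value(bleeding, 1.0, "both")

    def test_agrees_with_independent_erf_cdf(self, rng):
        """Brute-force oracle: normal CDF via math.erf on 100 random cases."""
        for _ in range(100):
            est = random_estimate(rng)
            theta0 = float(np.exp(rng.normal(0.0, 0.7)))
            z = (est.theta_hat - math.log(theta0)) / est.se
            assert p_value(est, theta0, "two_sided").p == pytest.approx(
                2.0 * (1.0 - phi_erf(abs(z))), abs=1e-9
            )
            assert p_value(est, theta0, "less").p == pytest.approx(
                phi_erf(z), abs=1e-9
            )
            assert p_value(est, theta0, "greater").p == pytest.approx(
                1.0 - phi_erf(z), abs=1e-9
            )

    def test_two_sided_doubles_the_smaller_tail(self, rng):
        for _ in range(50):
            est = random_estimate(rng)
            theta0 = float(np.exp(rng.normal(0.0, 0.7)))
            p_two = p_value(est, theta0, "two_sided").p
            p_less = p_value(est, theta0, "less").p
            p_greater = p_value(est, theta0, "greater").p
            assert p_two == pytest.approx(2.0 * min(p_less, p_greater), rel=1e-12)

    def test_p_decreases_as_null_moves_away(self):
        est = symmetric_estimate(0.0, 0.3)
        nulls = np.exp(np.linspace(0.0, 2.0, 20))
        ps = [p_value(est, float(t)).p for t in nulls]
        assert all(a > b for a, b in zip(ps, ps[1:]))


class TestCiAtLevel:
    def test_reproduces_source_interval(self):
        est = symmetric_estimate(-0.3, 0.4)
        lo, hi = ci_at_level(est, 0.95)
        assert lo == pytest.approx(est.ci_lower, rel=1e-10)
        assert hi == pytest.approx(est.ci_upper, rel=1e-10)

    def test_shrinks_to_point_as_level_vanishes(self, bleeding):
        lo, hi = ci_at_level(bleeding, 1e-12)
        assert lo == pytest.approx(bleeding.point, rel=1e-6)
        assert hi == pytest.approx(bleeding.point, rel=1e-6)

    def test_level_bounds_enforced(self, bleeding):
        for level in (0.0, 1.0, -0.5, 2.0):
            with pytest.raises(InvalidLevelError):
                ci_at_level(bleeding, level)

    def test_interval_nests_with_level(self, bleeding):
        lo66, hi66 = ci_at_level(bleeding, 0.66)
        lo95, hi95 = ci_at_level(bleeding, 0.95)
        assert lo95 < lo66 < hi66 < hi95


class TestMinLevelToExclude:
    def test_margin_excluded_only_from_66_percent(self, bleeding):
        """The wide bleeding CI rules out 1.25 only at ~66% confidence."""
        assert round(min_level_to_exclude(bleeding, 1.25), 2) == 0.66

    def test_zero_at_the_point_estimate(self, bleeding):
        assert min_level_to_exclude(bleeding, bleeding.point) == pytest.approx(
            0.0, abs=1e-12
        )

    def test_primary_excludes_null_at_994(self, primary):
        assert min_level_to_exclude(primary, 1.0) == pytest.approx(0.994, abs=5e-4)

    def test_threshold_separates_inclusion_from_exclusion(self, bleeding):
        level = min_level_to_exclude(bleeding, 1.25)
        below = ci_at_level(bleeding, level - 1e-6)
        above = ci_at_level(bleeding, level + 1e-6)
        assert below[1] < 1.25 < above[1]

    def test_complement_of_two_sided_p(self, rng):
        for _ in range(50):
            est = random_estimate(rng)
            theta = float(np.exp(rng.normal(0.0, 0.7)))
            p = p_value(est, theta).p
            assert min_level_to_exclude(est, theta) + p == pytest.approx(
                1.0, abs=1e-15
            )


class TestConsonanceCurve:
    def test_default_grid_shape_and_identity(self, bleeding):
        curve = consonance_curve(bleeding)
        assert curve.thetas.size == 400
        np.testing.assert_allclose(
            curve.min_excluding_level, 1.0 - curve.p_values, atol=0
        )

    def test_peak_at_grid_point_nearest_point_estimate(self, bleeding):
        curve = consonance_curve(bleeding)
        nearest = np.argmin(np.abs(np.log(curve.thetas) - bleeding.theta_hat))
        assert np.argmax(curve.p_values) == nearest
        assert curve.p_values[nearest] > 0.99

    def test_value_at_margin_matches_min_level(self, bleeding):
        grid = np.array([0.5, 1.0, 1.25, 2.0])
        curve = consonance_curve(bleeding, grid)
        assert curve.min_excluding_level[2] == pytest.approx(
            min_level_to_exclude(bleeding, 1.25), abs=1e-12
        )

    def test_single_point_grid_at_point_estimate(self, bleeding):
        curve = consonance_curve(bleeding, np.array([bleeding.point]))
        assert curve.p_values[0] == pytest.approx(1.0, abs=1e-12)

    def test_symmetric_grid_gives_symmetric_p(self):
        est = symmetric_estimate(0.1, 0.3)
        offsets = np.linspace(-1.0, 1.0, 21)
        curve = consonance_curve(est, np.exp(est.theta_hat + offsets))
        np.testing.assert_allclose(curve.p_values, curve.p_values[::-1], atol=1e-12)

    def test_monotone_decay_away_from_point(self):
        est = symmetric_estimate(0.0, 0.25)
        curve = consonance_curve(est, np.exp(np.linspace(0.0, 1.5, 30)))
        assert np.all(np.diff(curve.p_values) < 0)

    @pytest.mark.parametrize(
        "grid",
        [np.array([]), np.array([-1.0, 1.0]), np.array([0.0, 1.0]), np.array([2.0, 1.0])],
    )
    def test_bad_grids_rejected(self, bleeding, grid):
        with pytest.raises(InvalidGridError):
            consonance_curve(bleeding, grid)


class TestRoundTripProperty:
    @settings(max_examples=200, derandomize=True)
    @given(
        theta=st.floats(-2.0, 2.0),
        se=st.floats(0.01, 1.5),
        level=st.floats(0.05, 0.995),
    )
    def test_se_then_ci_reproduces_interval(self, theta, se, level):
        """se_from_ci and ci_at_level are mutually inverse at the source level."""
        est = symmetric_estimate(theta, se, level)
        assert est.se == pytest.approx(se, rel=1e-10)
        lo, hi = ci_at_level(est, level)
        assert lo == pytest.approx(est.ci_lower, rel=1e-10)
        assert hi == pytest.approx(est.ci_upper, rel=1e-10)
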