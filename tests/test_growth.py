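"""Gompertz growth, intake curves and endpoint fitting."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from pigemit.growth import (
    FEED_DEFAULTS,
    WEIGHT_DEFAULTS,
    GompertzParams,
    build_trajectory,
    daily_series,
    fit_endpoints,
    fit_total,
    gompertz_value,
    invert_gompertz,
)


def eval_gompertz(A, M, B, ts, t):
    """Independent one-line evaluation of the cumulative curve."""
    return A + M * math.exp(-math.exp(-B * (t - ts)))


class TestGompertzValue:
    def test_value_at_inflection_is_asymptote_over_e(self):
        # at t = t_star the double exponent collapses to exp(-1)
        assert gompertz_value(WEIGHT_DEFAULTS, 110.4) == pytest.approx(
            164.2 / math.e, abs=1e-9
        )
        assert gompertz_value(WEIGHT_DEFAULTS, 110.4) == pytest.approx(60.41, abs=0.01)

    @pytest.mark.parametrize(
        "params",
        [WEIGHT_DEFAULTS, FEED_DEFAULTS, GompertzParams(3.0, 50.0, 0.05, 80.0)],
    )
    def test_inflection_identity_all_parameter_sets(self, params):
        expected = params.offset_A + params.asymptote_M / math.e
        assert gompertz_value(params, params.t_star) == pytest.approx(expected)

    def test_far_past_limit_is_offset(self):
        assert gompertz_value(FEED_DEFAULTS, -1e5) == pytest.approx(
            FEED_DEFAULTS.offset_A, abs=1e-9
        )

    def test_matches_independent_evaluation(self):
        expected = eval_gompertz(0.0, 164.2, 0.0146, 110.4, 60.0)
        assert gompertz_value(WEIGHT_DEFAULTS, 60.0) == pytest.approx(
            expected, rel=1e-12
        )

    def test_cumulative_strictly_increasing(self):
        t = np.linspace(-50.0, 400.0, 500)
        vals = gompertz_value(WEIGHT_DEFAULTS, t)
        assert np.all(np.diff(vals) > 0)

    def test_invalid_params_rejected(self):
        with pytest.raises(ValueError):
            GompertzParams(0.0, 164.2, -0.01, 110.4)


def grid_search_fit(defaults, start, end, length):
    """Brute-force oracle: refine a 2-D grid over (asymptote, entry age)."""
    m_lo, m_hi = end * 1.0001, 10.0 * end
    t_lo, t_hi = 1.0, 365.0
    for _ in range(6):
        ms = np.linspace(m_lo, m_hi, 200)
        t0s = np.linspace(t_lo, t_hi, 200)
        mm, tt = np.meshgrid(ms, t0s, indexing="ij")
        a, b, ts = defaults.offset_A, defaults.rate_B, defaults.t_star
        w0 = a + mm * np.exp(-np.exp(-b * (tt - ts)))
        w1 = a + mm * np.exp(-np.exp(-b * (tt + length - ts)))
        err = (w0 - start) ** 2 + (w1 - end) ** 2
        i, j = np.unravel_index(np.argmin(err), err.shape)
        dm, dt = (m_hi - m_lo) / 199, (t_hi - t_lo) / 199
        m_lo, m_hi = ms[i] - 2 * dm, ms[i] + 2 * dm
        t_lo, t_hi = t0s[j] - 2 * dt, t0s[j] + 2 * dt
    return ms[i], t0s[j]


class TestFitEndpoints:
    def test_self_consistency_recovers_defaults(self):
        start = gompertz_value(WEIGHT_DEFAULTS, 70.0)
        end = gompertz_value(WEIGHT_DEFAULTS, 166.0)
        m, t0 = fit_endpoints(WEIGHT_DEFAULTS, start, end, 96.0)
        assert m == pytest.approx(164.2, rel=1e-6)
        assert t0 == pytest.approx(70.0, abs=1e-6)

    def test_matches_grid_search_oracle(self):
        m, t0 = fit_endpoints(WEIGHT_DEFAULTS, 23.6, 115.6, 96.0)
        m_ref, t0_ref = grid_search_fit(WEIGHT_DEFAULTS, 23.6, 115.6, 96.0)
        assert m == pytest.approx(m_ref, rel=1e-3)
        assert t0 == pytest.approx(t0_ref, rel=1e-3)
        # the fit reproduces the endpoints to the stated tolerance
        p = WEIGHT_DEFAULTS.replace(asymptote_M=m)
        assert gompertz_value(p, t0) == pytest.approx(23.6, rel=1e-6)
        assert gompertz_value(p, t0 + 96.0) == pytest.approx(115.6, rel=1e-6)

    def test_unreachable_end_weight_raises(self):
        with pytest.raises(ValueError, match="not reachable"):
            fit_endpoints(WEIGHT_DEFAULTS, 23.6, 400.0, 96.0)

    def test_invalid_endpoints_rejected(self):
        with pytest.raises(ValueError):
            fit_endpoints(WEIGHT_DEFAULTS, 100.0, 50.0, 96.0)

    @settings(deadline=None, max_examples=30, derandomize=True)
    @given(
        m=st.floats(140.0, 400.0),
        t0=st.floats(40.0, 100.0),
    )
    def test_round_trip_recovers_asymptote_and_entry(self, m, t0):
        p = WEIGHT_DEFAULTS.replace(asymptote_M=m)
        start = gompertz_value(p, t0)
        end = gompertz_value(p, t0 + 96.0)
        m_fit, t0_fit = fit_endpoints(WEIGHT_DEFAULTS, start, end, 96.0)
        assert m_fit == pytest.approx(m, rel=1e-4)
        assert t0_fit == pytest.approx(t0, rel=1e-4)


class TestDailySeries:
    def test_telescoping_sum(self):
        s = daily_series(WEIGHT_DEFAULTS, 70.0, 96)
        expected = gompertz_value(WEIGHT_DEFAULTS, 166.0) - gompertz_value(
            WEIGHT_DEFAULTS, 70.0
        )
        assert s.sum() == pytest.approx(expected, rel=1e-12)
        assert len(s) == 96

    def test_near_constant_curve_gives_near_zero_days(self):
        p = GompertzParams(5.0, 10.0, 1e-9, 100.0)
        s = daily_series(p, 70.0, 30)
        assert np.all(np.abs(s) < 1e-7)

    def test_feed_day_matches_independent_evaluation(self):
        s = daily_series(FEED_DEFAULTS, 70.0, 60)
        d = 30
        expected = eval_gompertz(-41.9, 608.0, 0.0111, 154.7, 70.0 + d) - eval_gompertz(
            -41.9, 608.0, 0.0111, 154.7, 70.0 + d - 1
        )
        assert s[d - 1] == pytest.approx(expected, rel=1e-12)

    def test_invert_round_trip(self):
        t = invert_gompertz(WEIGHT_DEFAULTS, 90.0)
        assert gompertz_value(WEIGHT_DEFAULTS, t) == pytest.approx(90.0, rel=1e-12)


class TestTrajectory:
    def test_totals_and_monotonicity(self):
        traj = build_trajectory(23.6, 115.6, 96, 240.0, 560.0)
        assert traj.daily_feed.sum() == pytest.approx(240.0, rel=1e-3)
        assert traj.daily_water.sum() == pytest.approx(560.0, rel=1e-3)
        assert np.all(np.diff(traj.daily_weight) > 0)
        assert np.all(traj.daily_feed >= 0)
        assert np.all(traj.daily_water >= 0)
        assert traj.daily_weight[-1] == pytest.approx(115.6, rel=1e-6)

    def test_fit_total_linear_in_total(self):
        m1 = fit_total(FEED_DEFAULTS, 240.0, 65.0, 96.0)
        m2 = fit_total(FEED_DEFAULTS, 480.0, 65.0, 96.0)
        assert m2 == pytest.approx(2.0 * m1, rel=1e-12)
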