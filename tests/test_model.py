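"""Core model: half-life algebra, concentration, thresholding, TAT scores."""

import math

import numpy as np
import pytest
from hypothesis import given, strategies as st

import tatscore as ts
from tatscore.model import _concentration_values

from conftest import brute_force_concentration

LN2 = math.log(2.0)


class TestHalfLifeAlgebra:
    @pytest.mark.parametrize(
        "half_life, rate, tol",
        [
            (1.0, LN2, 1e-12),
            (12.4, 0.0559, 5e-5),   # fitted AE-rate decay constant
            (11.18, 0.062, 5e-5),   # fitted peak-flow decay constant
        ],
    )
    def test_rate_from_half_life(self, half_life, rate, tol):
        assert ts.rate_from_half_life(half_life) == pytest.approx(rate, abs=tol)

    @pytest.mark.parametrize(
        "rate, half_life",
        [(0.062, 11.2), (0.056, 12.4), (LN2, 1.0)],
    )
    def test_half_life_from_rate(self, rate, half_life):
        assert ts.half_life_from_rate(rate) == pytest.approx(half_life, abs=0.05)

    @given(st.floats(min_value=0.01, max_value=1000.0))
    def test_round_trip(self, half_life):
        assert ts.half_life_from_rate(
            ts.rate_from_half_life(half_life)
        ) == pytest.approx(half_life, rel=1e-12)

    @pytest.mark.parametrize("bad", [0.0, -1.0])
    def test_non_positive_rejected(self, bad):
        with pytest.raises(ValueError):
            ts.rate_from_half_life(bad)
        with pytest.raises(ValueError):
            ts.half_life_from_rate(bad)


class TestConcentration:
    def test_no_events_is_zero(self):
        curve = ts.concentration([], 0.1, np.linspace(0, 48, 10))
        assert np.all(curve.values == 0)

    def test_half_life_decay(self):
        curve = ts.concentration([ts.DoseEvent(0.0)], LN2 / 12, np.array([0.0, 12.0]))
        assert curve.values == pytest.approx([1.0, 0.5])

    def test_two_dose_superposition(self):
        events = [ts.DoseEvent(0.0), ts.DoseEvent(12.0)]
        curve = ts.concentration(events, LN2 / 12, np.array([24.0]))
        assert curve.values[0] == pytest.approx(0.75)

    def test_unsorted_grid_rejected(self):
        with pytest.raises(ValueError):
            ts.concentration([], 0.1, np.array([0.0, 2.0, 1.0]))

    def test_negative_delta_rejected(self):
        with pytest.raises(ValueError):
            ts.DoseEvent(0.0, delta=-0.1)

    @given(
        st.lists(
            st.tuples(
                st.floats(min_value=0.0, max_value=500.0),
                st.floats(min_value=0.0, max_value=1.0),
            ),
            max_size=12,
        ),
        st.floats(min_value=0.01, max_value=0.3),
    )
    def test_matches_brute_force_and_additivity(self, raw, alpha):
        events = [ts.DoseEvent(t, d) for t, d in raw]
        grid = np.linspace(0.0, 600.0, 431)
        fast = ts.concentration(events, alpha, grid).values
        slow = brute_force_concentration(events, alpha, grid)
        np.testing.assert_allclose(fast, slow, rtol=1e-9, atol=1e-12)
        # additivity in events
        half = len(events) // 2
        left = ts.concentration(events[:half], alpha, grid).values
        right = ts.concentration(events[half:], alpha, grid).values
        np.testing.assert_allclose(fast, left + right, rtol=1e-9, atol=1e-12)

    def test_chunked_recurrence_spans_chunk_boundaries(self):
        # grid longer than the internal chunk, events on both sides
        events = [ts.DoseEvent(float(t)) for t in range(0, 5000, 7)]
        grid = np.linspace(0.0, 5000.0, 9001)
        alpha = 0.05
        fast = _concentration_values(
            np.array([e.time for e in events]),
            np.ones(len(events)),
            alpha,
            grid,
            chunk=512,
        )
        slow = brute_force_concentration(events, alpha, grid)
        np.testing.assert_allclose(fast, slow, rtol=1e-9, atol=1e-10)


class TestThresholdResponse:
    def test_half_at_threshold(self):
        assert ts.threshold_response(np.array([0.69]), 73.0, 0.69)[0] == 0.5

    def test_closed_form_value(self):
        sigma = ts.threshold_response(np.array([0.66]), 73.0, 0.56)
        assert sigma[0] == pytest.approx(1.0 / (1.0 + math.exp(-7.3)), rel=1e-12)

    def test_saturation_without_overflow(self):
        with np.errstate(over="raise"):
            sigma = ts.threshold_response(np.array([-10.0, 0.0, 1e6]), 73.0, 0.0)
        assert sigma[0] == 0.0
        assert sigma[2] == 1.0

    def test_monotone_in_concentration(self):
        c = np.linspace(0, 2, 50)
        sigma = ts.threshold_response(c, 63.0, 0.56)
        assert np.all(np.diff(sigma) >= 0)
        interior = (sigma > 1e-12) & (sigma < 1 - 1e-12)
        assert np.all(np.diff(sigma[interior]) > 0)


class TestTimeAboveThreshold:
    def test_no_events_scores_zero(self, ae_params):
        score = ts.time_above_threshold([], ae_params, ts.ObservationWindow(0, 720))
        assert score.value < 1e-3

    def test_perfect_regimen_near_one(self):
        params = ts.ModelParams(LN2 / 12, 73.0, 0.56)
        events = [ts.DoseEvent(t) for t in np.arange(0.0, 720.0, 12.0)]
        window = ts.ObservationWindow(72.0, 720.0)  # days 3-30
        assert ts.time_above_threshold(events, params, window).value > 0.99

    def test_single_dose_half_life_crossing(self):
        # near-step threshold at 0.5: above threshold for exactly one half-life
        params = ts.ModelParams(LN2 / 12, 1e6, 0.5)
        score = ts.time_above_threshold(
            [ts.DoseEvent(0.0)], params, ts.ObservationWindow(0, 24), grid_step=0.01
        )
        assert score.value == pytest.approx(0.5, abs=1e-3)

    @given(
        st.lists(
            st.tuples(
                st.floats(min_value=0.0, max_value=700.0),
                st.floats(min_value=0.0, max_value=1.0),
            ),
            min_size=1,
            max_size=10,
        ),
        st.floats(min_value=0.1, max_value=1.0),
    )
    def test_bounds_and_monotonicity(self, raw, theta):
        params = ts.ModelParams(LN2 / 12, 73.0, theta)
        window = ts.ObservationWindow(0.0, 720.0)
        events = [ts.DoseEvent(t, d) for t, d in raw]
        a = ts.time_above_threshold(events, params, window, grid_step=0.5).value
        assert 0.0 <= a <= 1.0
        # raising one technique score never lowers the score
        boosted = list(events)
        boosted[0] = ts.DoseEvent(events[0].time, 1.0)
        a_boost = ts.time_above_threshold(boosted, params, window, grid_step=0.5).value
        assert a_boost >= a - 1e-12
        # raising the threshold never raises the score
        higher = ts.ModelParams(LN2 / 12, 73.0, theta + 0.2)
        a_high = ts.time_above_threshold(events, higher, window, grid_step=0.5).value
        assert a_high <= a + 1e-12

    def test_time_translation_invariance(self, ae_params):
        events = [ts.DoseEvent(t) for t in (5.0, 30.0, 47.5)]
        shifted = [ts.DoseEvent(e.time + 100.0) for e in events]
        a0 = ts.time_above_threshold(events, ae_params, ts.ObservationWindow(0, 96))
        a1 = ts.time_above_threshold(
            shifted, ae_params, ts.ObservationWindow(100, 196)
        )
        assert a0.value == pytest.approx(a1.value, abs=1e-12)

    def test_grid_refinement_stability(self, ae_params, perfect_patient):
        window = ts.ObservationWindow(0.0, 720.0)
        coarse = ts.time_above_threshold(
            perfect_patient.events, ae_params, window, grid_step=0.1
        ).value
        fine = ts.time_above_threshold(
            perfect_patient.events, ae_params, window, grid_step=0.05
        ).value
        assert abs(coarse - fine) < 1e-4


class TestWindowedScores:
    def _record(self, events, span_hours):
        return ts.PatientRecord(
            "p", events, ts.ObservationWindow(0.0, span_hours)
        )

    def test_partition_count(self, ae_params):
        rec = self._record([ts.DoseEvent(10.0)], 2160.0)
        assert len(ts.windowed_scores(rec, ae_params, grid_step=0.5)) == 3

    def test_final_partial_window_flagged(self, ae_params):
        rec = self._record([ts.DoseEvent(10.0)], 2400.0)  # 100 days
        scores = ts.windowed_scores(rec, ae_params, grid_step=0.5)
        assert len(scores) == 4
        assert [s.partial for s in scores] == [False, False, False, True]

    def test_translation_invariance_across_windows(self, ae_params):
        # periodic pattern: months 2 and 3 see identical boundary
        # concentrations (month 1 carries the cold start and is excluded)
        pattern = np.arange(0.0, 2160.0, 12.0)
        rec = self._record([ts.DoseEvent(t) for t in pattern], 2160.0)
        s = ts.windowed_scores(rec, ae_params, grid_step=0.1)
        assert s[1].value == pytest.approx(s[2].value, abs=1e-6)

    def test_decay_after_events_stop(self, ae_params):
        events = [ts.DoseEvent(t) for t in np.arange(0.0, 720.0, 12.0)]
        rec = self._record(events, 2160.0)
        s = ts.windowed_scores(rec, ae_params, grid_step=0.5)
        assert s[2].value < s[0].value

    def test_invalid_window_length(self, ae_params, perfect_patient):
        with pytest.raises(ValueError):
            ts.windowed_scores(perfect_patient, ae_params, window_length=0.0)


class TestLaggedDailyScores:
    def test_zero_tau_is_identity(self):
        x = np.array([0.1, 0.9, 0.4, 0.4, 0.7])
        np.testing.assert_array_equal(ts.exponential_moving_average(x, 0.0), x)

    def test_constant_series_unchanged(self):
        x = np.full(30, 0.42)
        np.testing.assert_allclose(ts.exponential_moving_average(x, 18.2), x)

    def test_matches_direct_convolution(self):
        # step change smoothed at the fitted peak-flow lag
        raw = np.concatenate([np.full(15, 0.9), np.full(15, 0.2)])
        tau = 18.2
        smoothed = ts.exponential_moving_average(raw, tau)
        lam = math.exp(-24.0 / tau)
        oracle = np.empty_like(raw)
        for t in range(raw.size):
            w = lam ** np.arange(t + 1)
            oracle[t] = np.sum(w * raw[t::-1]) / np.sum(w)
        np.testing.assert_allclose(smoothed, oracle, rtol=1e-10)
        # the smoothed transition lags the step
        assert smoothed[15] > raw[15]

    def test_daily_scores_from_record(self, asthma_params, perfect_patient):
        daily = ts.lagged_daily_scores(perfect_patient, asthma_params, grid_step=0.25)
        assert daily.raw.shape == (30,)
        assert np.all((daily.raw >= 0) & (daily.raw <= 1))
        # perfect dosing: every day after the first is fully above threshold
        assert np.all(daily.raw[1:] > 0.99)

    def test_negative_tau_rejected(self):
        with pytest.raises(ValueError):
            ts.exponential_moving_average(np.ones(5), -1.0)
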