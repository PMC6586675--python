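"""Isotonic trajectory fitting, rate estimation and onset detection."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from ribotrace.elongation_analysis import (arrival_time, detect_onset,
                                           elongation_rate, fit_monotone,
                                           measure_delay)
from ribotrace.trace import ForceTrace


def brute_force_monotone(y):
    """Exhaustive optimal non-decreasing fit: enumerate all partitions of
    the index range into consecutive blocks, each at its mean, keep the
    partitions with non-decreasing block means, pick the least SSE."""
    y = np.asarray(y, dtype=float)
    n = y.size
    best_fit, best_sse = None, np.inf
    for cuts in itertools.product([0, 1], repeat=n - 1):
        edges = [0] + [i + 1 for i, c in enumerate(cuts) if c] + [n]
        means = [y[a:b].mean() for a, b in zip(edges, edges[1:])]
        if any(means[i] > means[i + 1] + 1e-12 for i in range(len(means) - 1)):
            continue
        fit = np.concatenate([np.full(b - a, mu) for (a, b), mu in
                              zip(zip(edges, edges[1:]), means)])
        sse = float(np.sum((y - fit) ** 2))
        if sse < best_sse - 1e-12:
            best_fit, best_sse = fit, sse
    return best_fit


class TestFitMonotone:
    def test_monotone_input_returned_unchanged(self):
        t = np.arange(30.0)
        y = np.sort(np.linspace(0, 25, 30))
        fit = fit_monotone(t, y)
        np.testing.assert_allclose(fit.fitted_position, y, atol=1e-12)

    @given(st.lists(st.floats(-5, 5), min_size=3, max_size=8))
    @settings(max_examples=60, deadline=None, derandomize=True)
    def test_matches_exhaustive_oracle_on_tiny_inputs(self, ys):
        t = np.arange(len(ys), dtype=float)
        fit = fit_monotone(t, np.array(ys), min_samples=2)
        oracle = brute_force_monotone(ys)
        np.testing.assert_allclose(fit.fitted_position, oracle, atol=1e-9)

    def test_noisy_ramp_slope_recovered(self, rng):
        t = np.arange(0, 200, 0.05)
        y = t * 1.0 + rng.normal(0, 5.0, t.size)
        fit = fit_monotone(t, y)
        # avoid the end blocks of the isotonic fit, which are noise-biased
        inner = (t >= 20) & (t <= 180)
        ti, yi = t[inner], fit.fitted_position[inner]
        slope = (yi[-1] - yi[0]) / (ti[-1] - ti[0])
        assert slope == pytest.approx(1.0, rel=0.05)

    def test_nan_positions_dropped(self):
        t = np.arange(40.0)
        y = t.copy()
        y[5] = np.nan
        fit = fit_monotone(t, y)
        assert fit.time.size == 39


class TestElongationRate:
    def test_exact_ramp_gives_exact_rate(self):
        t = np.arange(0, 100, 0.1)
        fit = fit_monotone(t, t * 1.0)
        rate, spread = elongation_rate(fit)
        assert rate == pytest.approx(1.0, rel=1e-9)
        assert spread == pytest.approx(0.0, abs=1e-9)

    def test_too_few_windows_rejected(self):
        t = np.arange(0, 1.5, 0.05)
        fit = fit_monotone(t, t * 10.0)  # spans only 15 aa -> 1 window
        with pytest.raises(ValueError):
            elongation_rate(fit)

    def test_median_robust_to_single_pause(self):
        """A long pause moves the median crossing time by far less than the
        pause itself."""
        t = np.arange(0, 300, 0.1)
        pause = 50.0
        y = np.where(t < 100, t, np.where(t < 100 + pause, 100.0,
                                          t - pause))
        fit = fit_monotone(t, y)
        rate, _ = elongation_rate(fit)
        n_windows = fit.window_crossing_times.size
        # rate from median: 10/median(T); the pause corrupts one window only
        assert 10.0 / rate - 10.0 < pause / n_windows + 1e-6


class TestArrivalTime:
    def test_exact_ramp_arrival(self):
        t = np.arange(0, 300, 0.1)
        fit = fit_monotone(t, t * 1.0)
        assert arrival_time(fit, 167.0) == pytest.approx(167.0, abs=0.2)

    def test_step_function_arrival_at_jump(self):
        t = np.arange(0, 100, 0.5)
        y = np.where(t < 40, 10.0, 200.0)
        fit = fit_monotone(t, y)
        assert arrival_time(fit, 167.0) == pytest.approx(40.0, abs=0.6)

    def test_unreached_codon_returns_none(self):
        t = np.arange(0, 50, 0.5)
        fit = fit_monotone(t, t * 0.1)
        assert arrival_time(fit, 167.0) is None


class TestDetectOnset:
    FS = 1333.0

    def _noise_trace(self, rng, seconds=30.0, sd=0.25, level=4.0):
        n = int(seconds * self.FS)
        return ForceTrace(np.arange(n) / self.FS,
                          level + rng.normal(0, sd, n), self.FS)

    def test_quiet_baseline_has_no_event(self, rng):
        trace = self._noise_trace(rng, seconds=5.0)
        assert detect_onset(trace, 0.0) is None

    def test_injected_spike_detected_by_cdf_method(self, rng):
        trace = self._noise_trace(rng, seconds=5.0)
        sd_down = 0.25 / np.sqrt(10)
        # one full downsampling block (~8 ms) inside the third 1-s window
        i0 = 2 * int(self.FS) + 660
        trace.force[i0:i0 + 10] += 6 * sd_down
        ev = detect_onset(trace, 0.0)
        assert ev is not None and ev.method == "cdf_outlier"
        assert ev.time == pytest.approx(i0 / self.FS, abs=0.05)

    def test_persistent_hopping_flagged_by_sd_method(self, rng):
        trace = self._noise_trace(rng, seconds=5.0, sd=0.05)
        n = len(trace)
        hop = 0.4 * ((np.arange(n) // int(0.2 * self.FS)) % 2)
        trace.force[n // 2:] += hop[n // 2:]
        ev = detect_onset(trace, 0.0)
        assert ev is not None
        assert ev.method == "sd_flag"
        assert ev.time >= len(trace) / self.FS / 2 - 1.0

    def test_short_span_rejected(self, rng):
        with pytest.raises(ValueError):
            detect_onset(self._noise_trace(rng, seconds=0.5), 0.0)


class TestMeasureDelay:
    def _trace_with_onset(self, rng, onset_s, seconds=60.0, fs=1333.0):
        n = int(seconds * fs)
        t = np.arange(n) / fs
        f = 4.0 + rng.normal(0, 0.1, n)
        hop = 0.5 * ((t > onset_s) & (((t - onset_s) // 0.5) % 2 == 0))
        return ForceTrace(t, f + hop, fs)

    def test_onset_at_arrival_gives_zero_tau(self, rng):
        trace = self._trace_with_onset(rng, onset_s=10.0)
        fit = fit_monotone(trace.time, trace.time * 10.0)  # arrival ~ 10 s
        obs = measure_delay(trace, fit, 100.0, tau_unfold_equilibrium=1.5)
        assert obs.tau < 2.0
        assert obs.onset_kind == "equilibrium_like"

    def test_time_translation_invariance(self, rng):
        rng2 = np.random.default_rng(77)
        trace = self._trace_with_onset(rng2, onset_s=30.0)
        fit = fit_monotone(trace.time, trace.time * 10.0)
        obs = measure_delay(trace, fit, 100.0)

        shifted = ForceTrace(trace.time + 500.0, trace.force, trace.fs)
        fit_s = fit_monotone(shifted.time, (shifted.time - 500.0) * 10.0)
        obs_s = measure_delay(shifted, fit_s, 100.0)
        assert obs_s.tau == pytest.approx(obs.tau, abs=1e-6)

    def test_no_onset_is_right_censored(self, rng):
        n = int(20 * 1333)
        trace = ForceTrace(np.arange(n) / 1333.0,
                           4.0 + rng.normal(0, 0.1, n), 1333.0)
        fit = fit_monotone(trace.time, trace.time * 20.0)
        obs = measure_delay(trace, fit, 100.0)
        assert obs.censored and obs.onset_kind is None
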