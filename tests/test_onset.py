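"""Onset detectors: AGLR change-point, sustained-SD fallback, arbitration,
and H-reflex latency estimation, all checked against generator truth or
independent brute-force oracles."""

import numpy as np
import pytest

from srtkit.onset import (
    AGLRSpec,
    DegenerateBaselineError,
    LatencyUnmeasurableError,
    OnsetResult,
    aglr_statistic,
    detect_onset_aglr,
    detect_onset_sustained_sd,
    estimate_hreflex_latency,
    reconcile_onsets,
)
from srtkit.signal import bandpass
from srtkit.synth import SimulationConfig, _band_noise, generate_hreflex, generate_trial

FS = 2000.0


def _alternating_step(n_pre: int, n_post: int, sd0: float, sd1: float) -> np.ndarray:
    """Deterministic +-amplitude signal with an exact variance step."""
    x = np.empty(n_pre + n_post)
    x[::2], x[1::2] = 1.0, -1.0
    x[:n_pre] *= sd0
    x[n_pre:] *= sd1
    return x


def _exhaustive_change_point(x: np.ndarray, sigma0_sq: float) -> int:
    """Independent oracle: brute-force single-change-point ML scan over the
    whole trace with known baseline variance."""
    best_j, best_ll = 0, -np.inf
    c = np.concatenate(([0.0], np.cumsum(x**2)))
    n = x.size
    for j in range(0, n - 3):
        m = n - j
        r = (c[n] - c[j]) / (m * sigma0_sq)
        ll = 0.5 * m * (r - np.log(r) - 1.0) if r > 1.0 else 0.0
        if ll > best_ll:
            best_j, best_ll = j, ll
    return best_j


class TestAGLRStatistic:
    def test_nonnegative_and_zero_iff_matched_variance(self):
        x = np.ones(400)  # exact variance 1 in every window
        c = np.concatenate(([0.0], np.cumsum(x**2)))
        g = aglr_statistic(c, 1.0, 50)
        assert np.all(g == 0.0)
        g2 = aglr_statistic(c, 0.5, 50)  # variance ratio 2 everywhere
        assert np.all(g2 > 0.0)

    def test_grows_with_window_length(self):
        x = np.full(400, 2.0)
        c = np.concatenate(([0.0], np.cumsum(x**2)))
        g_small = aglr_statistic(c, 1.0, 20)[0]
        g_large = aglr_statistic(c, 1.0, 80)[0]
        assert g_large > g_small


class TestAGLRDetector:
    def test_step_matches_exhaustive_search(self):
        """On noiseless step-variance inputs the detector's ML refinement
        equals the brute-force change-point scan within one sample."""
        for s0 in (1200, 1400, 1700):
            x = np.concatenate(
                [_alternating_step(1000, 0, 1.0, 1.0),
                 _alternating_step(s0 - 1000, 3000 - s0, 1.0, 5.0)]
            )
            res = detect_onset_aglr(x, FS, 0.5)
            j_oracle = _exhaustive_change_point(x[1000:], 1.0) + 1000
            assert res.detected
            assert abs(res.onset_time * FS - j_oracle) <= 1

    def test_synthetic_burst_recovered_within_5ms(self, rng):
        """Median onset error over simulated bursts at the default gain is
        below 5 ms (tolerance from detector bias on repeated simulation)."""
        cfg = SimulationConfig()
        errs = []
        for _ in range(50):
            tr = generate_trial(cfg, 210.0, rng)
            x = bandpass(tr.emg["sol"], FS)
            res = detect_onset_aglr(x, FS, tr.stretch_onset_time)
            assert res.detected
            errs.append(abs(res.onset_time - tr.truth.true_emg_onset_time["sol"]))
        assert np.median(errs) <= 0.005

    def test_pure_noise_gives_no_onset(self, noise_rng):
        x = bandpass(_band_noise(int(1.5 * FS), FS, noise_rng), FS)
        res = detect_onset_aglr(x, FS, 0.5)
        assert not res.detected and "no_onset" in res.flags

    def test_degenerate_baseline_errors(self):
        x = np.zeros(3000)
        x[1500:] = 1.0
        with pytest.raises(DegenerateBaselineError):
            detect_onset_aglr(x, FS, 0.5)

    def test_detection_error_decreases_with_gain(self):
        """Detection accuracy improves (stochastically) with burst gain."""
        errs = {}
        for gain in (3.0, 8.0):
            cfg = SimulationConfig(burst_gain=gain)
            rng = np.random.default_rng(99)
            e = []
            for _ in range(100):
                tr = generate_trial(cfg, 210.0, rng)
                x = bandpass(tr.emg["sol"], FS)
                res = detect_onset_aglr(x, FS, tr.stretch_onset_time)
                if res.detected:
                    e.append(abs(res.onset_time - tr.truth.true_emg_onset_time["sol"]))
            errs[gain] = np.median(e)
        assert errs[8.0] <= errs[3.0]

    def test_false_alarm_tuning_sweep(self, noise_rng):
        """Threshold tuning procedure: the default decision threshold keeps
        the per-trace false-alarm rate on band-limited noise below 1%,
        while a white-noise-calibrated threshold of 10 does not."""
        n = int(1.6 * FS)
        peaks = []
        for _ in range(1000):
            x = bandpass(_band_noise(n, FS, noise_rng), FS)
            res = detect_onset_aglr(x, FS, 0.5, AGLRSpec(decision_threshold=1e9))
            peaks.append(res.statistic_peak)
        peaks = np.asarray(peaks)
        default = AGLRSpec().decision_threshold
        assert (peaks > default).mean() < 0.01
        assert (peaks > 10.0).mean() > 0.5


class TestSustainedSD:
    def _burst_trace(self, dur: float, rng, gain: float = 5.0) -> tuple[np.ndarray, float]:
        n = int(1.5 * FS)
        x = _band_noise(n, FS, rng)
        onset = 0.8
        i0, i1 = int(onset * FS), int((onset + dur) * FS)
        x[i0:i1] += _band_noise(i1 - i0, FS, rng) * gain
        return bandpass(x, FS), onset

    def test_sustained_burst_recovered_within_10ms(self, rng):
        errs = []
        for _ in range(20):
            x, onset = self._burst_trace(0.150, rng)
            res = detect_onset_sustained_sd(x, FS, 0.6)
            assert res.detected
            errs.append(abs(res.onset_time - onset))
        assert np.median(errs) <= 0.010

    def test_short_burst_fails_hold(self, rng):
        """A 50 ms burst cannot satisfy the 100 ms hold criterion."""
        for _ in range(5):
            x, _ = self._burst_trace(0.050, rng)
            res = detect_onset_sustained_sd(x, FS, 0.6)
            assert not res.detected

    def test_zero_threshold_degenerates_to_first_sample(self, rng):
        x, _ = self._burst_trace(0.150, rng)
        res = detect_onset_sustained_sd(x, FS, 0.6, k_sd=0.0)
        assert res.onset_time == pytest.approx(0.6, abs=1 / FS)


class TestReconcile:
    A = OnsetResult(0.700, "aglr", 120.0)

    def test_agreement_returns_primary(self):
        out = reconcile_onsets(self.A, OnsetResult(0.705, "sustained_sd"))
        assert out.method == "aglr" and out.onset_time == 0.700
        assert "review" not in out.flags

    def test_primary_missing_falls_back_flagged(self):
        out = reconcile_onsets(
            OnsetResult(None, "aglr", 1.0, {"no_onset"}),
            OnsetResult(0.710, "sustained_sd"),
        )
        assert out.onset_time == 0.710 and "review" in out.flags

    def test_large_disagreement_prefers_fallback_flagged(self):
        out = reconcile_onsets(
            self.A, OnsetResult(0.740, "sustained_sd"), max_disagreement=0.020
        )
        assert out.method == "sustained_sd" and out.onset_time == 0.740
        assert "review" in out.flags

    def test_unconfirmed_primary_is_no_onset(self):
        out = reconcile_onsets(
            self.A, OnsetResult(None, "sustained_sd", 0.0, {"no_onset"})
        )
        assert not out.detected and "review" in out.flags


class TestHReflexLatency:
    @pytest.mark.parametrize("latency", [0.023, 0.028, 0.035])
    def test_latency_recovered_within_1ms(self, noise_rng, latency):
        for _ in range(10):
            h = generate_hreflex(latency, noise_rng)
            est = estimate_hreflex_latency(h)
            assert est == pytest.approx(latency, abs=0.001)

    def test_flat_noise_trace_errors(self, noise_rng):
        h = generate_hreflex(0.028, noise_rng, h_amplitude=0.0)
        with pytest.raises(LatencyUnmeasurableError):
            estimate_hreflex_latency(h)
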