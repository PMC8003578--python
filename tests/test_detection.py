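"""Baseline/noise estimation and threshold-crossing signal pickup."""

import numpy as np
import pytest

from nanogapid.detection import (
    DetectorConfig,
    detect_signals,
    estimate_baseline,
    estimate_noise_level,
    match_to_truth,
    signal_frequency,
)
from nanogapid.synthetic import NoiseModel, SpeciesProfile, simulate_trace

QUIET = NoiseModel(baseline_pa=0.0, drift_amplitude_pa=0.0, noise_sd_pa=0.0, sampling_rate_hz=10_000.0)


def _pulse_trace(rng, n_pulses=30, amp=10.0, noise_sd=1.0, gap=4000, width=10):
    """Noise trace with well-separated rectangular pulses; returns (trace, truth)."""
    n = 12_000 + n_pulses * gap
    x = rng.normal(0.0, noise_sd, n)
    truth = []
    for i in range(n_pulses):
        s = 12_000 + i * gap
        x[s : s + width] += amp
        truth.append((s, s + width, "pulse"))
    return x, truth


class TestBaseline:
    def test_constant_window(self):
        assert estimate_baseline(np.full(2000, 5.0)) == 5.0

    def test_mode_ignores_transient_pulses(self):
        window = np.concatenate([np.zeros(1900), np.full(100, 50.0)])
        assert abs(estimate_baseline(window)) <= 0.25  # within half a bin of 0

    def test_gaussian_window_mode_near_mean(self, rng):
        window = rng.normal(0.0, 1.0, 2000)
        assert abs(estimate_baseline(window, bin_width_pa=0.5)) <= 0.5

    def test_empty_window_rejected(self):
        with pytest.raises(ValueError):
            estimate_baseline([])


class TestNoiseLevel:
    def test_zero_noise_trace(self):
        assert estimate_noise_level(np.full(10_000, 3.0)) == 0.0

    def test_iid_gaussian_sd_recovered(self, rng):
        window = rng.normal(0.0, 1.0, 10_000)
        assert estimate_noise_level(window) == pytest.approx(1.0, abs=0.2)

    def test_mode_robust_to_pulse_contaminated_chunks(self, rng):
        # 45 quiet chunks (sd 1) + 5 pulse chunks (sd ~10): mode stays near 1
        window = rng.normal(0.0, 1.0, 10_000)
        for c in (3, 11, 25, 33, 47):
            window[c * 200 : (c + 1) * 200] += 10.0 * (rng.random(200) > 0.5)
        est = estimate_noise_level(window)
        assert est == pytest.approx(1.0, abs=0.3)

    def test_short_window_rejected(self):
        with pytest.raises(ValueError):
            estimate_noise_level(np.zeros(300), chunk=200)


class TestDetect:
    def test_single_rectangular_pulse_recovered(self, rng):
        # noisy warm-up seeds the noise level; the pulse itself is clean
        x = np.concatenate([rng.normal(0, 0.5, 12_000), np.zeros(3000)])
        x[12_500:12_510] += 10.0
        result = detect_signals(x, DetectorConfig())
        assert len(result) == 1
        seg = result[0]
        assert seg.start_idx == 12_500
        assert abs((seg.end_idx - seg.start_idx) - 10) <= 1
        assert seg.samples.max() >= 6 * seg.noise_level_pa

    def test_pure_noise_trace_yields_no_detections(self, rng):
        x = rng.normal(0.0, 1.0, 300_000)
        assert len(detect_signals(x, DetectorConfig())) == 0

    def test_recall_on_injected_pulses(self, rng):
        x, truth = _pulse_trace(rng, n_pulses=30, amp=10.0, noise_sd=1.0)
        result = detect_signals(x, DetectorConfig())
        _, recall, fp = match_to_truth(result.segments, truth)
        assert recall >= 0.95
        assert fp <= 1

    def test_offset_invariance(self, rng):
        x, _ = _pulse_trace(rng, n_pulses=10)
        r1 = detect_signals(x, DetectorConfig())
        r2 = detect_signals(x + 7.5, DetectorConfig())  # shift by whole histogram bins
        assert [(s.start_idx, s.end_idx) for s in r1] == [(s.start_idx, s.end_idx) for s in r2]
        for a, b in zip(r1, r2):
            np.testing.assert_allclose(a.samples, b.samples, atol=1e-9)

    def test_recall_monotone_in_threshold_multiplier(self, rng):
        x, truth = _pulse_trace(rng, n_pulses=40, amp=8.0)
        recalls = []
        for mult in (4.0, 6.0, 12.0):
            res = detect_signals(x, DetectorConfig(start_threshold=mult))
            _, recall, _ = match_to_truth(res.segments, truth)
            recalls.append(recall)
        assert recalls == sorted(recalls, reverse=True)

    def test_segments_ordered_and_disjoint(self, rng):
        x, _ = _pulse_trace(rng, n_pulses=25, amp=12.0, gap=2000)
        result = detect_signals(x, DetectorConfig())
        spans = [(s.start_idx, s.end_idx) for s in result]
        assert spans == sorted(spans)
        assert all(e1 <= s2 for (_, e1), (s2, _) in zip(spans, spans[1:]))

    def test_short_trace_rejected(self):
        with pytest.raises(ValueError):
            detect_signals(np.zeros(5000), DetectorConfig())

    def test_detection_on_simulated_recording(self):
        profile = SpeciesProfile("mol", 40.0, 5.0, 4.0, 1.0, "rectangular", {"jitter": 0.05})
        trace = simulate_trace([profile], [3.0], NoiseModel(), 20.0, seed=21, blank_profile=None)
        config = DetectorConfig()
        result = detect_signals(trace.samples, config)
        # events inside the warm-up window are undetectable by design
        scoreable = [t for t in trace.truth if t[0] >= config.noise_window]
        _, recall, fp = match_to_truth(result.segments, scoreable)
        assert recall >= 0.9
        assert fp <= 2


class TestFrequency:
    def test_values_and_validation(self):
        assert signal_frequency([], 10.0) == 0.0
        assert signal_frequency(list(range(30)), 60.0) == 0.5
        with pytest.raises(ValueError):
            signal_frequency([], 0.0)

    def test_molecule_recording_busier_than_blank(self):
        noise = NoiseModel()
        blank = simulate_trace([], [], noise, 20.0, seed=31, blank_rate_hz=1.0)
        profile = SpeciesProfile("mol", 40.0, 8.0, 4.0, 1.0, "rectangular")
        spiked = simulate_trace([profile], [4.0], noise, 20.0, seed=32, blank_rate_hz=1.0)
        f_blank = signal_frequency(detect_signals(blank.samples), blank.duration_s)
        f_mol = signal_frequency(detect_signals(spiked.samples), spiked.duration_s)
        assert f_mol > f_blank
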