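"""Synthetic trace/feature generator: construction, statistics, determinism."""

import numpy as np
import pandas as pd
import pytest

from nanogapid.synthetic import (
    BLANK_PROFILE,
    DEFAULT_PROFILES,
    NoiseModel,
    SpeciesProfile,
    _truncated_normal,
    contaminated_benchmark,
    generate_labeled_feature_dataset,
    read_truth_annotations,
    render_pulse,
    simulate_trace,
    write_truth_annotations,
)

QUIET = NoiseModel(baseline_pa=0.0, drift_amplitude_pa=0.0, noise_sd_pa=0.0, sampling_rate_hz=10_000.0)
RECT = SpeciesProfile("rect", 10.0, 0.0, 1.0, 0.0, "rectangular", {"jitter": 0.0})


def test_noiseless_rectangular_pulse_construction():
    # 10 pA for 1 ms at 10 kHz on a flat baseline: exactly 10 elevated samples
    trace = simulate_trace([RECT], [0.5], QUIET, 2.0, seed=3, blank_profile=None, poisson_counts=False)
    assert len(trace.truth) == 1
    start, end, label = trace.truth[0]
    assert label == "rect" and end - start == 10
    assert np.sum(trace.samples == 10.0) == 10
    assert np.all(trace.samples[:start] == 0.0) and np.all(trace.samples[end:] == 0.0)


def test_blank_profile_matches_reported_control_statistics():
    assert BLANK_PROFILE.amp_mean_pa == 18.0
    assert BLANK_PROFILE.dur_mean_ms == pytest.approx(0.3)


def test_default_species_statistics():
    stats = {p.name: (p.amp_mean_pa, p.amp_sd_pa, p.dur_mean_ms) for p in DEFAULT_PROFILES}
    assert stats["cAMP"] == (32.0, 18.0, 4.6)
    assert stats["AMP"] == (27.0, 13.0, 4.6)
    assert stats["ADP"] == (41.0, 21.0, 4.1)
    assert stats["ATP"] == (36.0, 15.0, 5.3)


def test_trace_determinism_under_seed():
    noise = NoiseModel()
    kw = dict(profiles=list(DEFAULT_PROFILES), rates_hz=[2.0] * 4, noise=noise, duration_s=5.0)
    t1 = simulate_trace(seed=42, **kw)
    t2 = simulate_trace(seed=42, **kw)
    t3 = simulate_trace(seed=43, **kw)
    np.testing.assert_array_equal(t1.samples, t2.samples)
    assert t1.truth == t2.truth
    assert not np.array_equal(t1.samples, t3.samples)


def test_truth_annotations_are_ordered_disjoint_and_in_bounds():
    trace = simulate_trace(list(DEFAULT_PROFILES), [3.0] * 4, NoiseModel(), 10.0, seed=9)
    spans = [(s, e) for s, e, _ in trace.truth]
    assert spans == sorted(spans)
    for (s1, e1), (s2, e2) in zip(spans, spans[1:]):
        assert e1 <= s2
    assert all(0 <= s < e <= trace.samples.size for s, e in spans)
    assert len(trace.truth) > 0


def test_injected_amplitudes_match_profile_statistics(rng):
    # law-of-large-numbers check on the generator's own draws (n = 1000)
    n = 1000
    draws = _truncated_normal(rng, 32.0, 18.0, 0.0, n)
    # moments of a zero-truncated Gaussian (numerical oracle via dense grid)
    x = np.linspace(0.0, 32.0 + 8 * 18.0, 400_001)
    pdf = np.exp(-0.5 * ((x - 32.0) / 18.0) ** 2)
    pdf /= np.trapezoid(pdf, x)
    mean_true = np.trapezoid(x * pdf, x)
    sd_true = np.sqrt(np.trapezoid((x - mean_true) ** 2 * pdf, x))
    assert abs(draws.mean() - mean_true) < 3 * sd_true / np.sqrt(n)


def test_noiseless_event_peaks_equal_drawn_amplitudes():
    profile = SpeciesProfile("p", 50.0, 5.0, 5.0, 1.0, "rectangular", {"jitter": 0.0})
    trace = simulate_trace([profile], [2.0], QUIET, 20.0, seed=5, blank_profile=None)
    peaks = np.array([trace.samples[s:e].max() for s, e, _ in trace.truth])
    assert len(peaks) > 10
    assert abs(peaks.mean() - 50.0) < 3 * 5.0 / np.sqrt(len(peaks)) + 1.0


def test_overcrowded_trace_fails_with_clear_message():
    busy = SpeciesProfile("busy", 10.0, 0.0, 50.0, 0.0, "rectangular")
    with pytest.raises(RuntimeError, match="overlap"):
        simulate_trace([busy], [50.0], QUIET, 1.0, seed=1, blank_profile=None, max_retries=3)


def test_event_longer_than_trace_rejected():
    long = SpeciesProfile("long", 10.0, 0.0, 3000.0, 0.0, "rectangular")
    with pytest.raises(ValueError, match="longer than the trace"):
        simulate_trace([long], [1.0], QUIET, 2.0, seed=1, blank_profile=None, poisson_counts=False)


@pytest.mark.parametrize("shape", ["rectangular", "ramp", "exp_decay", "noisy_plateau"])
def test_pulse_archetypes_peak_near_amplitude(shape, rng):
    pulse = render_pulse(shape, 40, 20.0, rng, {"jitter": 0.0})
    assert pulse.shape == (40,)
    assert 0 < pulse.max() <= 20.0 + 1e-9
    assert pulse.min() >= 0.0


def test_unknown_shape_rejected():
    with pytest.raises(ValueError):
        SpeciesProfile("x", 1.0, 0.0, 1.0, 0.0, "triangle")


def test_profile_invariants_enforced():
    with pytest.raises(ValueError):
        SpeciesProfile("x", -1.0, 0.0, 1.0, 0.0)
    with pytest.raises(ValueError):
        SpeciesProfile("x", 1.0, -0.1, 1.0, 0.0)


def test_feature_dataset_determinism_and_validation():
    d1 = generate_labeled_feature_dataset(DEFAULT_PROFILES, 20, seed=2)
    d2 = generate_labeled_feature_dataset(DEFAULT_PROFILES, 20, seed=2)
    pd.testing.assert_frame_equal(d1, d2)
    assert sorted(d1["label"].unique()) == ["ADP", "AMP", "ATP", "cAMP"]
    assert len(d1) == 80
    with pytest.raises(ValueError):
        generate_labeled_feature_dataset(DEFAULT_PROFILES, 0, seed=2)


def test_contaminated_benchmark_composition():
    positive, contaminated = contaminated_benchmark(
        n_mol_per_class=30, n_blank_per_class=10, n_positive=50, seed=1
    )
    assert len(positive) == 50 and "label" not in positive.columns
    assert len(contaminated) == 4 * 40
    per_label = contaminated.groupby("label")["is_blank"].agg(["size", "sum"])
    assert (per_label["size"] == 40).all() and (per_label["sum"] == 10).all()


def test_truth_annotation_roundtrip(tmp_path):
    trace = simulate_trace(list(DEFAULT_PROFILES), [2.0] * 4, NoiseModel(), 5.0, seed=13)
    path = tmp_path / "truth.csv"
    write_truth_annotations(trace, path)
    assert read_truth_annotations(path) == trace.truth

    trace.truth = []
    write_truth_annotations(trace, path)
    assert read_truth_annotations(path) == []
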