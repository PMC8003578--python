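"""Synthetic nanogap current-trace and feature-dataset generation.

No recordings from the original experiments are publicly deposited, so
every downstream stage is exercised on synthetic traces that reproduce the
statistical structure the analysis assumes: a near-zero baseline with slow
wander and Gaussian noise, sparse pulse-like molecular signals whose
amplitude and duration statistics match the published per-species values,
and small, short "blank" signals (electrode-atom migration, contamination)
that contaminate every recording, including pure-solvent controls.

Default per-species statistics (peak current mean +/- SD in pA, mean
duration in ms) follow the published single-molecule measurements at
100 mV bias: cAMP 32+/-18 / 4.6, AMP 27+/-13 / 4.6, ADP 41+/-21 / 4.1,
ATP 36+/-15 / 5.3; blanks ~18 pA and ~0.3 ms.  Duration SDs are not
published; they default to half the mean, giving the broad right-skewed
spread typical of translocation-time histograms.

The per-species waveform *shapes* are not published either — only that
shape factors discriminate — so each species is assigned a configurable
pulse archetype (rectangular, rising ramp, front-loaded exponential decay,
noisy plateau) so that shape factors carry class signal.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .features import FEATURE_NAMES, featurize_dataset

__all__ = [
    "SpeciesProfile",
    "NoiseModel",
    "SimulatedTrace",
    "DEFAULT_PROFILES",
    "BLANK_PROFILE",
    "render_pulse",
    "simulate_trace",
    "generate_labeled_feature_dataset",
    "contaminated_benchmark",
    "write_truth_annotations",
    "read_truth_annotations",
]

PULSE_SHAPES = ("rectangular", "ramp", "exp_decay", "noisy_plateau")


@dataclass(frozen=True)
class SpeciesProfile:
    """Signal statistics and waveform archetype for one molecular species.

    Amplitudes and durations of individual events are drawn from Gaussians
    truncated at zero (amplitude) and at two sample intervals (duration);
    only means and SDs of the real signals are known.
    """

    name: str
    amp_mean_pa: float
    amp_sd_pa: float
    dur_mean_ms: float
    dur_sd_ms: float
    shape: str = "rectangular"
    shape_params: Mapping[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.amp_mean_pa <= 0 or self.dur_mean_ms <= 0:
            raise ValueError("amplitude and duration means must be positive")
        if self.amp_sd_pa < 0 or self.dur_sd_ms < 0:
            raise ValueError("SDs must be non-negative")
        if self.shape not in PULSE_SHAPES:
            raise ValueError(f"unknown pulse shape {self.shape!r}; choose from {PULSE_SHAPES}")


@dataclass(frozen=True)
class NoiseModel:
    """Baseline, wander and white-noise model of the current amplifier chain."""

    baseline_pa: float = 0.0
    drift_amplitude_pa: float = 2.0
    drift_timescale_s: float = 5.0
    noise_sd_pa: float = 1.5
    sampling_rate_hz: float = 10_000.0

    def __post_init__(self) -> None:
        if self.noise_sd_pa < 0:
            raise ValueError("noise SD must be non-negative")
        if self.sampling_rate_hz <= 0:
            raise ValueError("sampling rate must be positive")


@dataclass
class SimulatedTrace:
    """A simulated current-time recording with ground-truth annotations.

    ``truth`` holds (start_idx, end_idx, label) tuples with 0-based
    half-open sample spans, ordered and non-overlapping.
    """

    samples: np.ndarray  # current, pA
    noise: NoiseModel
    bias_mv: float
    seed: int
    truth: list[tuple[int, int, str]]
    trace_id: str = "sim"

    @property
    def duration_s(self) -> float:
        return self.samples.size / self.noise.sampling_rate_hz

    @property
    def times_s(self) -> np.ndarray:
        return np.arange(self.samples.size) / self.noise.sampling_rate_hz


#: Published per-species signal statistics at 100 mV bias; shapes are this
#: package's archetypes (the real waveforms are not published).
DEFAULT_PROFILES: tuple[SpeciesProfile, ...] = (
    SpeciesProfile("cAMP", 32.0, 18.0, 4.6, 2.3, "exp_decay", {"decay": 1.5, "jitter": 0.10}),
    SpeciesProfile("AMP", 27.0, 13.0, 4.6, 2.3, "ramp", {"floor": 0.15, "jitter": 0.10}),
    SpeciesProfile("ADP", 41.0, 21.0, 4.1, 2.0, "rectangular", {"jitter": 0.10}),
    SpeciesProfile("ATP", 36.0, 15.0, 5.3, 2.6, "noisy_plateau", {"jitter": 0.30}),
)

#: Blank signals: small short pulses present in every recording.
BLANK_PROFILE = SpeciesProfile("blank", 18.0, 6.0, 0.3, 0.1, "rectangular", {"jitter": 0.15})


def _truncated_normal(rng: np.random.Generator, mean: float, sd: float, low: float, n: int) -> np.ndarray:
    """Gaussian draws conditioned on > low, by resampling (vector rejection)."""
    if sd == 0:
        if mean <= low:
            raise ValueError("degenerate draw entirely below truncation point")
        return np.full(n, mean)
    out = rng.normal(mean, sd, size=n)
    bad = out <= low
    for _ in range(1000):
        if not bad.any():
            return out
        out[bad] = rng.normal(mean, sd, size=int(bad.sum()))
        bad = out <= low
    raise RuntimeError("truncated-normal sampling failed to converge")


def render_pulse(
    shape: str,
    n_samples: int,
    amplitude_pa: float,
    rng: np.random.Generator,
    shape_params: Mapping[str, float] | None = None,
) -> np.ndarray:
    """Render one pulse waveform of ``n_samples`` points peaking near ``amplitude_pa``.

    Archetypes:

    - ``rectangular``: flat top with multiplicative jitter;
    - ``ramp``: linear rise from a small floor to the full amplitude;
    - ``exp_decay``: front-loaded, jumps to the peak then decays;
    - ``noisy_plateau``: flat top with strong within-pulse fluctuation.
    """
    if n_samples < 1:
        raise ValueError("pulse needs at least one sample")
    p = dict(shape_params or {})
    jitter = float(p.get("jitter", 0.0))
    t = np.linspace(0.0, 1.0, n_samples) if n_samples > 1 else np.zeros(1)
    if shape == "rectangular" or shape == "noisy_plateau":
        base = np.ones(n_samples)
    elif shape == "ramp":
        floor = float(p.get("floor", 0.1))
        base = floor + (1.0 - floor) * t
    elif shape == "exp_decay":
        decay = float(p.get("decay", 1.5))
        base = np.exp(-decay * t)
    else:
        raise ValueError(f"unknown pulse shape {shape!r}")
    pulse = amplitude_pa * base
    if jitter > 0:
        pulse = pulse * (1.0 + jitter * rng.standard_normal(n_samples))
    return np.maximum(pulse, 0.0)


def _draw_events(
    profiles: Sequence[SpeciesProfile],
    rates_hz: Sequence[float],
    noise: NoiseModel,
    duration_s: float,
    rng: np.random.Generator,
    max_retries: int,
    poisson_counts: bool = True,
) -> list[tuple[int, int, SpeciesProfile, float]]:
    """Poisson event placement with overlap rejection.

    Returns ordered (start, end, profile, amplitude) tuples.  Raises if an
    event cannot be placed without overlap after ``max_retries`` attempts —
    the generator models sparse translocations, not pile-up.
    """
    n_total = int(round(duration_s * noise.sampling_rate_hz))
    placed: list[tuple[int, int, SpeciesProfile, float]] = []
    occupied: list[tuple[int, int]] = []
    for profile, rate in zip(profiles, rates_hz):
        n_events = rng.poisson(rate * duration_s) if poisson_counts else int(round(rate * duration_s))
        if n_events == 0:
            continue
        amps = _truncated_normal(rng, profile.amp_mean_pa, profile.amp_sd_pa, 0.0, n_events)
        durs_ms = _truncated_normal(
            rng, profile.dur_mean_ms, profile.dur_sd_ms, 2.0 / noise.sampling_rate_hz * 1e3, n_events
        )
        lengths = np.maximum(2, np.round(durs_ms * 1e-3 * noise.sampling_rate_hz).astype(int))
        for amp, length in zip(amps, lengths):
            if length >= n_total:
                raise ValueError("event longer than the trace; lower durations or raise duration_s")
            for attempt in range(max_retries + 1):
                start = int(rng.integers(0, n_total - length))
                end = start + int(length)
                if all(end <= s or start >= e for s, e in occupied):
                    occupied.append((start, end))
                    placed.append((start, end, profile, float(amp)))
                    break
            else:
                raise RuntimeError(
                    f"could not place a {profile.name} event without overlap after "
                    f"{max_retries} retries; the trace is too crowded (lower rates or "
                    f"increase duration)"
                )
    placed.sort(key=lambda ev: ev[0])
    return placed


def simulate_trace(
    profiles: Sequence[SpeciesProfile],
    rates_hz: Sequence[float],
    noise: NoiseModel,
    duration_s: float,
    seed: int,
    blank_profile: SpeciesProfile | None = BLANK_PROFILE,
    blank_rate_hz: float = 1.0,
    bias_mv: float = 100.0,
    trace_id: str = "sim",
    max_retries: int = 200,
    poisson_counts: bool = True,
) -> SimulatedTrace:
    """Simulate one current-time recording with ground-truth annotations.

    Molecular pulses drawn per ``profiles``/``rates_hz`` plus blank signals
    (``blank_profile`` at ``blank_rate_hz``; pass ``blank_profile=None``
    only to build idealized test traces — real recordings always contain
    blanks) are superposed on baseline + drift + Gaussian noise.  The same
    seed and configuration reproduce the trace bit for bit.
    """
    if duration_s <= 0:
        raise ValueError("duration must be positive")
    if len(profiles) != len(rates_hz):
        raise ValueError("one event rate per species profile is required")
    rng = np.random.default_rng(seed)
    all_profiles = list(profiles)
    all_rates = list(rates_hz)
    if blank_profile is not None:
        all_profiles.append(blank_profile)
        all_rates.append(blank_rate_hz)
    events = _draw_events(
        all_profiles, all_rates, noise, duration_s, rng, max_retries, poisson_counts=poisson_counts
    )

    n_total = int(round(duration_s * noise.sampling_rate_hz))
    t = np.arange(n_total) / noise.sampling_rate_hz
    x = np.full(n_total, noise.baseline_pa, dtype=float)
    if noise.drift_amplitude_pa > 0:
        phase = rng.uniform(0.0, 2.0 * np.pi)
        x += noise.drift_amplitude_pa * np.sin(2.0 * np.pi * t / noise.drift_timescale_s + phase)
        # slow random walk of comparable total excursion
        step = noise.drift_amplitude_pa / np.sqrt(n_total)
        x += np.cumsum(rng.normal(0.0, step, size=n_total))
    if noise.noise_sd_pa > 0:
        x += rng.normal(0.0, noise.noise_sd_pa, size=n_total)

    truth: list[tuple[int, int, str]] = []
    for start, end, profile, amp in events:
        x[start:end] += render_pulse(profile.shape, end - start, amp, rng, profile.shape_params)
        truth.append((start, end, profile.name))
    return SimulatedTrace(samples=x, noise=noise, bias_mv=bias_mv, seed=seed, truth=truth, trace_id=trace_id)


def generate_labeled_feature_dataset(
    profiles: Sequence[SpeciesProfile],
    n_per_class: int,
    seed: int,
    sampling_rate_hz: float = 10_000.0,
    noise_sd_pa: float = 1.5,
) -> pd.DataFrame:
    """Draw a labeled 13-feature table directly, one class per profile.

    Each row is produced by rendering a single pulse from the profile's
    archetype, adding measurement noise, and running the standard feature
    extraction — i.e. the features are distributed as trace simulation +
    detection + extraction would give, without paying for full traces.
    Deterministic under ``seed``.
    """
    if n_per_class < 1:
        raise ValueError("n_per_class must be >= 1")
    rng = np.random.default_rng(seed)
    segments: list[np.ndarray] = []
    labels: list[str] = []
    for profile in profiles:
        amps = _truncated_normal(rng, profile.amp_mean_pa, profile.amp_sd_pa, 0.0, n_per_class)
        durs = _truncated_normal(
            rng, profile.dur_mean_ms, profile.dur_sd_ms, 2.0 / sampling_rate_hz * 1e3, n_per_class
        )
        lengths = np.maximum(2, np.round(durs * 1e-3 * sampling_rate_hz).astype(int))
        for amp, length in zip(amps, lengths):
            pulse = render_pulse(profile.shape, int(length), amp, rng, profile.shape_params)
            if noise_sd_pa > 0:
                pulse = pulse + rng.normal(0.0, noise_sd_pa, size=pulse.size)
            # guard the (rare) all-negative short pulse after noise
            if pulse.max() <= 0:
                pulse = pulse - pulse.max() + 0.1 * profile.amp_mean_pa
            segments.append(pulse)
            labels.append(profile.name)
    return featurize_dataset(segments, sampling_rate_hz, labels=labels)


def contaminated_benchmark(
    profiles: Sequence[SpeciesProfile] = DEFAULT_PROFILES,
    blank_profile: SpeciesProfile = BLANK_PROFILE,
    n_mol_per_class: int = 250,
    n_blank_per_class: int = 100,
    n_positive: int = 400,
    seed: int = 0,
    sampling_rate_hz: float = 10_000.0,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Blank-contaminated multi-class benchmark at the feature level.

    Emulates the experimental labeling situation: each species recording
    contributes its molecular signals *plus* blank signals that carry the
    recording's species label (nobody can tell them apart a priori), while
    a separate blank-solution control contributes the labeled positives.

    Returns ``(positive, contaminated)``: ``positive`` is an unlabeled
    feature table of control-recording blanks; ``contaminated`` has the
    13 features, a ``label`` column (the recording species) and an
    ``is_blank`` column (ground truth, for evaluation only — drop it
    before fitting anything).
    """
    if n_mol_per_class < 1 or n_blank_per_class < 0 or n_positive < 1:
        raise ValueError("benchmark sizes must be positive")
    positive = generate_labeled_feature_dataset(
        [blank_profile], n_positive, seed=seed, sampling_rate_hz=sampling_rate_hz
    ).drop(columns=["label"])
    parts = []
    for i, profile in enumerate(profiles):
        mols = generate_labeled_feature_dataset(
            [profile], n_mol_per_class, seed=seed + 1000 + i, sampling_rate_hz=sampling_rate_hz
        )
        mols["is_blank"] = False
        parts.append(mols)
        if n_blank_per_class:
            blanks = generate_labeled_feature_dataset(
                [blank_profile], n_blank_per_class, seed=seed + 2000 + i, sampling_rate_hz=sampling_rate_hz
            )
            blanks["label"] = profile.name  # blanks inherit the recording's label
            blanks["is_blank"] = True
            parts.append(blanks)
    contaminated = pd.concat(parts, ignore_index=True)
    return positive, contaminated


def write_truth_annotations(trace: SimulatedTrace, path) -> None:
    """Write ground-truth annotations as CSV (start_idx, end_idx, label)."""
    table = pd.DataFrame(trace.truth, columns=["start_idx", "end_idx", "label"])
    table.to_csv(path, index=False)


def read_truth_annotations(path) -> list[tuple[int, int, str]]:
    """Read annotations written by :func:`write_truth_annotations`."""
    table = pd.read_csv(path, dtype={"start_idx": int, "end_idx": int, "label": str})
    return [(int(r.start_idx), int(r.end_idx), str(r.label)) for r in table.itertuples()]
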