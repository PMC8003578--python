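"""Streaming baseline/noise estimation and threshold-crossing signal pickup.

The detector mimics how pulse signals are picked out of a raw nanogap
current trace:

- the *baseline* at any instant is the mode of a histogram of the last
  2000 samples (the mode, unlike the mean, ignores the sparse pulses);
- the *noise level* is the mode of the standard deviations of 50 disjoint
  200-sample chunks of the last 10,000 samples — again a mode, so a
  minority of pulse-containing chunks cannot inflate it;
- a signal *starts* at the first sample exceeding baseline + 6x noise
  level, and *ends* at the first subsequent sample that falls back below
  baseline + noise level.

Baseline and noise estimates are frozen while a signal is in progress (so
the signal cannot poison its own threshold) and refreshed on a fixed
stride while the trace is quiet.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterator, Sequence

import numpy as np

__all__ = [
    "DetectorConfig",
    "SignalSegment",
    "DetectionResult",
    "estimate_baseline",
    "estimate_noise_level",
    "detect_signals",
    "signal_frequency",
    "match_to_truth",
]


@dataclass(frozen=True)
class DetectorConfig:
    """Windows and thresholds of the signal pickup.

    ``baseline_bin_pa`` bins the raw-current histogram for the baseline
    mode; ``noise_bin_pa`` bins the chunk-SD histogram for the noise-level
    mode and is finer because chunk SDs concentrate tightly around the
    true noise SD.  Ties between equally populated bins break toward the
    lower bin.  ``update_stride`` is how often (in samples) the estimates
    are refreshed while the trace is quiet.
    """

    baseline_window: int = 2000
    noise_window: int = 10_000
    noise_chunk: int = 200
    start_threshold: float = 6.0
    baseline_bin_pa: float = 0.5
    noise_bin_pa: float = 0.1
    min_signal_samples: int = 2
    update_stride: int = 200

    def __post_init__(self) -> None:
        if not (self.baseline_window >= 2 and self.noise_window >= 2 * self.noise_chunk >= 4):
            raise ValueError("windows must cover at least two chunks of >= 2 samples")
        if self.start_threshold <= 0:
            raise ValueError("start threshold multiplier must be positive")
        if self.baseline_bin_pa <= 0 or self.noise_bin_pa <= 0:
            raise ValueError("histogram bin widths must be positive")


@dataclass
class SignalSegment:
    """One detected pulse: half-open sample span and baseline-subtracted samples."""

    start_idx: int
    end_idx: int
    samples: np.ndarray  # baseline-subtracted, pA
    baseline_pa: float
    noise_level_pa: float
    trace_id: str | None = None

    @property
    def i_p_pa(self) -> float:
        return float(self.samples.max())

    def t_d_ms(self, sampling_rate_hz: float) -> float:
        return self.samples.size / sampling_rate_hz * 1e3


@dataclass
class DetectionResult:
    """Detected segments plus bookkeeping counts; iterates over segments."""

    segments: list[SignalSegment] = field(default_factory=list)
    n_too_short: int = 0
    n_truncated: int = 0

    def __iter__(self) -> Iterator[SignalSegment]:
        return iter(self.segments)

    def __len__(self) -> int:
        return len(self.segments)

    def __getitem__(self, i):
        return self.segments[i]


def _histogram_mode(values: np.ndarray, bin_width: float) -> float:
    """Center of the most populated bin; constant input returns that constant.

    Bin edges are anchored at multiples of ``bin_width`` so the estimate is
    equivariant under shifts by whole bins; ties break toward the lower bin
    (``argmax`` returns the first maximum).
    """
    values = np.asarray(values, dtype=float)
    lo, hi = float(values.min()), float(values.max())
    if hi - lo < 1e-12:
        return lo
    first = np.floor(lo / bin_width)
    n_bins = int(np.ceil(hi / bin_width) - first) + 1
    edges = (first + np.arange(n_bins + 1)) * bin_width
    counts, _ = np.histogram(values, bins=edges)
    k = int(np.argmax(counts))
    return float((edges[k] + edges[k + 1]) / 2.0)


def estimate_baseline(window: Sequence[float], bin_width_pa: float = 0.5) -> float:
    """Baseline = mode of the histogram of the trailing window (pA)."""
    window = np.asarray(window, dtype=float)
    if window.size == 0:
        raise ValueError("empty baseline window")
    return _histogram_mode(window, bin_width_pa)


def estimate_noise_level(
    window: Sequence[float], chunk: int = 200, bin_width_pa: float = 0.1
) -> float:
    """Noise level = mode of per-chunk sample SDs over the trailing window (pA).

    The window is cut into disjoint ``chunk``-sample pieces (a partial tail
    chunk is dropped); each piece contributes its SD, and the mode of those
    SDs is returned.  Chunks that happen to contain a pulse have inflated
    SDs but remain a minority, so the mode tracks the quiet-trace noise.
    """
    window = np.asarray(window, dtype=float)
    n_chunks = window.size // chunk
    if n_chunks < 2:
        raise ValueError("noise window must span at least two chunks")
    sds = window[: n_chunks * chunk].reshape(n_chunks, chunk).std(axis=1, ddof=1)
    return _histogram_mode(sds, bin_width_pa)


def detect_signals(
    samples: Sequence[float],
    config: DetectorConfig = DetectorConfig(),
    trace_id: str | None = None,
) -> DetectionResult:
    """Pick pulse signals out of a raw current trace.

    A signal starts at the first sample with current - baseline above
    ``start_threshold`` x noise level and ends at the first later sample
    below baseline + noise level.  Detection begins only once
    ``noise_window`` samples have accrued (warm-up), estimates are frozen
    inside a signal, segments shorter than ``min_signal_samples`` are
    dropped (counted in ``n_too_short``), and a signal still open at the
    end of the trace is dropped (counted in ``n_truncated``).
    """
    x = np.asarray(samples, dtype=float)
    result = DetectionResult()
    if x.size <= config.noise_window:
        raise ValueError("trace shorter than the noise warm-up window")
    pos = config.noise_window
    while pos < x.size:
        baseline = estimate_baseline(x[pos - config.baseline_window : pos], config.baseline_bin_pa)
        noise = estimate_noise_level(
            x[pos - config.noise_window : pos], config.noise_chunk, config.noise_bin_pa
        )
        block_end = min(pos + config.update_stride, x.size)
        above = x[pos:block_end] - baseline > config.start_threshold * noise
        if not above.any():
            pos = block_end
            continue
        start = pos + int(np.argmax(above))
        below = x[start + 1 :] - baseline < noise
        if not below.any():
            result.n_truncated += 1
            break
        end = start + 1 + int(np.argmax(below))
        if end - start >= config.min_signal_samples:
            result.segments.append(
                SignalSegment(
                    start_idx=start,
                    end_idx=end,
                    samples=x[start:end] - baseline,
                    baseline_pa=baseline,
                    noise_level_pa=noise,
                    trace_id=trace_id,
                )
            )
        else:
            result.n_too_short += 1
        pos = end + 1
    return result


def signal_frequency(segments: Sequence, duration_s: float) -> float:
    """Detected events per second."""
    if duration_s <= 0:
        raise ValueError("duration must be positive")
    return len(segments) / duration_s


def match_to_truth(
    segments: Sequence[SignalSegment],
    truth: Sequence[tuple[int, int, str]],
    min_overlap: int = 1,
) -> tuple[list[str | None], float, int]:
    """Match detections to ground-truth events by sample overlap.

    Returns (per-segment labels, recall over truth events, false-positive
    count).  A detection overlapping no truth event by at least
    ``min_overlap`` samples is a false positive (label ``None``); a truth
    event is recalled if some detection overlaps it.
    """
    labels: list[str | None] = []
    hit = [False] * len(truth)
    fp = 0
    for seg in segments:
        best, best_ov = None, 0
        for j, (ts, te, lab) in enumerate(truth):
            ov = min(seg.end_idx, te) - max(seg.start_idx, ts)
            if ov > best_ov:
                best, best_ov = j, ov
        if best is not None and best_ov >= min_overlap:
            labels.append(truth[best][2])
            hit[best] = True
        else:
            labels.append(None)
            fp += 1
    recall = sum(hit) / len(truth) if truth else float("nan")
    return labels, recall, fp
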