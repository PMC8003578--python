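"""Trace, segment and feature-table file formats, and pipeline configuration.

Traces travel as two-column CSV (time_s, current_pA) with an optional JSON
sidecar (``<stem>.meta.json``) holding the sampling rate, bias and
generator provenance; segment and feature tables are plain CSV.  A single
YAML config plus its per-stage seeds fully determines every number the
pipeline emits.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .classify import ClassifierSpec
from .detection import DetectorConfig, SignalSegment
from .puc import PUCConfig
from .synthetic import BLANK_PROFILE, DEFAULT_PROFILES, NoiseModel, SimulatedTrace, SpeciesProfile
from .voting import VoteModel

__all__ = [
    "Trace",
    "read_trace",
    "write_trace",
    "write_segments",
    "read_segments",
    "PipelineConfig",
    "load_config",
]

#: Allowed relative jitter of the sample spacing in a trace file.
_MAX_REL_JITTER = 1e-6


@dataclass
class Trace:
    """A uniformly sampled current trace in pA with acquisition metadata."""

    samples: np.ndarray
    sampling_rate_hz: float
    bias_mv: float = 100.0
    trace_id: str = "trace"
    meta: dict = field(default_factory=dict)

    @property
    def duration_s(self) -> float:
        return self.samples.size / self.sampling_rate_hz


def write_trace(trace: Trace | SimulatedTrace, path) -> Path:
    """Write a trace as (time_s, current_pA) CSV plus a JSON metadata sidecar."""
    path = Path(path)
    if isinstance(trace, SimulatedTrace):
        rate = trace.noise.sampling_rate_hz
        meta = {
            "sampling_rate_hz": rate,
            "bias_mv": trace.bias_mv,
            "trace_id": trace.trace_id,
            "seed": trace.seed,
            "noise_model": dataclasses.asdict(trace.noise),
        }
        samples = trace.samples
    else:
        rate = trace.sampling_rate_hz
        meta = {"sampling_rate_hz": rate, "bias_mv": trace.bias_mv, "trace_id": trace.trace_id, **trace.meta}
        samples = trace.samples
    t = np.arange(samples.size) / rate
    pd.DataFrame({"time_s": t, "current_pA": samples}).to_csv(path, index=False)
    path.with_suffix(".meta.json").write_text(json.dumps(meta, indent=2))
    return path


def read_trace(path) -> Trace:
    """Read a trace CSV, validating uniform and monotone sampling.

    The sampling rate comes from the sidecar when present, otherwise it is
    inferred from the median sample spacing.  A single-column file
    (current only) requires the sidecar.  Raises on non-monotone time or
    spacing jitter above 1e-6 relative.
    """
    path = Path(path)
    table = pd.read_csv(path)
    meta = {}
    sidecar = path.with_suffix(".meta.json")
    if sidecar.exists():
        meta = json.loads(sidecar.read_text())
    if "current_pA" not in table.columns:
        raise ValueError(f"{path}: expected a 'current_pA' column")
    samples = table["current_pA"].to_numpy(dtype=float)
    if "time_s" in table.columns:
        t = table["time_s"].to_numpy(dtype=float)
        dt = np.diff(t)
        if len(dt) and dt.min() <= 0:
            raise ValueError(f"{path}: time column is not strictly increasing")
        if len(dt) and (dt.max() - dt.min()) > _MAX_REL_JITTER * np.median(dt):
            raise ValueError(f"{path}: non-uniform sampling (jitter above tolerance)")
        rate = float(meta.get("sampling_rate_hz", 1.0 / np.median(dt)))
    else:
        if "sampling_rate_hz" not in meta:
            raise ValueError(f"{path}: no time column and no sampling rate in sidecar")
        rate = float(meta["sampling_rate_hz"])
    return Trace(
        samples=samples,
        sampling_rate_hz=rate,
        bias_mv=float(meta.get("bias_mv", 100.0)),
        trace_id=str(meta.get("trace_id", path.stem)),
        meta=meta,
    )


def write_segments(segments, sampling_rate_hz: float, path) -> Path:
    """Write a detected-segment summary table as CSV."""
    rows = [
        {
            "trace_id": seg.trace_id,
            "start_idx": seg.start_idx,
            "end_idx": seg.end_idx,
            "i_p_pA": seg.i_p_pa,
            "t_d_ms": seg.t_d_ms(sampling_rate_hz),
            "baseline_pA": seg.baseline_pa,
            "noise_pA": seg.noise_level_pa,
        }
        for seg in segments
    ]
    path = Path(path)
    pd.DataFrame(
        rows,
        columns=["trace_id", "start_idx", "end_idx", "i_p_pA", "t_d_ms", "baseline_pA", "noise_pA"],
    ).to_csv(path, index=False)
    return path


def read_segments(path, trace: Trace) -> list[SignalSegment]:
    """Rehydrate segments from a summary CSV by re-slicing the source trace."""
    table = pd.read_csv(path)
    segments = []
    for row in table.itertuples():
        s, e = int(row.start_idx), int(row.end_idx)
        segments.append(
            SignalSegment(
                start_idx=s,
                end_idx=e,
                samples=trace.samples[s:e] - float(row.baseline_pA),
                baseline_pa=float(row.baseline_pA),
                noise_level_pa=float(row.noise_pA),
                trace_id=str(row.trace_id),
            )
        )
    return segments


@dataclass
class PipelineConfig:
    """Everything the end-to-end pipeline needs, with per-stage seeds."""

    duration_s: float = 30.0
    noise: NoiseModel = field(default_factory=NoiseModel)
    profiles: tuple[SpeciesProfile, ...] = DEFAULT_PROFILES
    blank_profile: SpeciesProfile = BLANK_PROFILE
    species_rate_hz: float = 5.0
    blank_rate_hz: float = 1.5
    blank_solution_rate_hz: float = 2.5
    detector: DetectorConfig = field(default_factory=DetectorConfig)
    puc: PUCConfig = field(default_factory=PUCConfig)
    classifier: ClassifierSpec = field(default_factory=ClassifierSpec)
    vote: VoteModel = field(default_factory=VoteModel)
    folds: int = 10
    vote_n_max: int = 20
    seed: int = 0

    def stage_seed(self, stage: str) -> int:
        """Stable per-stage seed derived from the master seed."""
        order = ("simulate", "puc", "classify", "vote")
        if stage not in order:
            raise KeyError(stage)
        child = np.random.SeedSequence(self.seed, spawn_key=(order.index(stage),))
        return int(child.generate_state(1)[0] % (2**31))


def load_config(path_or_dict) -> PipelineConfig:
    """Build a :class:`PipelineConfig` from a YAML file or a plain dict.

    Unknown keys are rejected so typos fail loudly; nested sections mirror
    the dataclass fields (``noise``, ``detector``, ``puc``, ``classifier``,
    ``vote``, ``profiles``, ``blank_profile``).
    """
    if isinstance(path_or_dict, (str, Path)):
        raw = yaml.safe_load(Path(path_or_dict).read_text()) or {}
    else:
        raw = dict(path_or_dict)
    cfg: dict = {}
    nested = {
        "noise": NoiseModel,
        "detector": DetectorConfig,
        "puc": PUCConfig,
        "classifier": ClassifierSpec,
        "vote": VoteModel,
        "blank_profile": SpeciesProfile,
    }
    allowed = {f.name for f in dataclasses.fields(PipelineConfig)}
    for key, value in raw.items():
        if key not in allowed:
            raise ValueError(f"unknown config key {key!r}")
        if key in nested and isinstance(value, dict):
            cfg[key] = nested[key](**value)
        elif key == "profiles":
            cfg[key] = tuple(SpeciesProfile(**p) for p in value)
        else:
            cfg[key] = value
    return PipelineConfig(**cfg)
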