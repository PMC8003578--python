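"""End-to-end pipeline: simulate -> detect -> featurize -> PU-filter -> classify.

Mirrors the experimental workflow: one blank-solution control recording
plus one recording per sample species (each contaminated by blanks), signal
pickup and featurization per recording, blank removal learned from the
control recording's signals, cross-validated species classification of the
retained signals, and the plurality-vote accuracy curve evaluated at the
measured per-signal accuracy.  Every intermediate table is persisted and
every stage is seeded, so one config reproduces every emitted number.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from contextlib import contextmanager
from pathlib import Path

import pandas as pd

from . import detection, io, puc, synthetic, voting
from .classify import cross_validate, feature_importance
from .features import featurize_dataset
from .io import PipelineConfig

__all__ = ["run_pipeline", "render_report", "PipelineError"]

log = logging.getLogger("nanogapid.pipeline")


class PipelineError(RuntimeError):
    """A stage failure, wrapped with the stage name for context."""


@contextmanager
def _stage(name: str):
    try:
        log.info("stage %s", name)
        yield
    except PipelineError:
        raise
    except Exception as exc:
        raise PipelineError(f"pipeline stage {name!r} failed: {exc}") from exc


def run_pipeline(config: PipelineConfig, outdir) -> dict:
    """Run the full analysis on synthetic recordings; return the report bundle.

    Writes, under ``outdir``: the simulated traces with truth annotations,
    per-recording segment tables, the pooled feature tables before/after
    blank removal, the PU report, the cross-validated confusion matrix and
    metrics (with and without blank removal, so the effect of the filter
    is visible), feature importances, the vote-accuracy curve, a JSON log
    and the report bundle itself.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    events: list[dict] = []

    def note(stage: str, **info):
        events.append({"stage": stage, **info})
        log.info("%s: %s", stage, info)

    rate = config.noise.sampling_rate_hz
    sim_seed = config.stage_seed("simulate")

    with _stage("simulate"):
        traces = {
            "blank_solution": synthetic.simulate_trace(
                profiles=[],
                rates_hz=[],
                noise=config.noise,
                duration_s=config.duration_s,
                seed=sim_seed,
                blank_profile=config.blank_profile,
                blank_rate_hz=config.blank_solution_rate_hz,
                trace_id="blank_solution",
            )
        }
        for i, profile in enumerate(config.profiles):
            traces[profile.name] = synthetic.simulate_trace(
                profiles=[profile],
                rates_hz=[config.species_rate_hz],
                noise=config.noise,
                duration_s=config.duration_s,
                seed=sim_seed + 1 + i,
                blank_profile=config.blank_profile,
                blank_rate_hz=config.blank_rate_hz,
                trace_id=profile.name,
            )
        for name, trace in traces.items():
            io.write_trace(trace, outdir / f"trace_{name}.csv")
            synthetic.write_truth_annotations(trace, outdir / f"truth_{name}.csv")
        note("simulate", n_traces=len(traces), seed=sim_seed, duration_s=config.duration_s)

    with _stage("detect"):
        feature_tables = {}
        for name, trace in traces.items():
            result = detection.detect_signals(trace.samples, config.detector, trace_id=name)
            io.write_segments(result.segments, rate, outdir / f"segments_{name}.csv")
            feature_tables[name] = featurize_dataset(result.segments, rate, labels=[name] * len(result))
            note(
                "detect",
                trace=name,
                n_segments=len(result),
                n_too_short=result.n_too_short,
                frequency_hz=detection.signal_frequency(result, trace.duration_s),
            )
            if len(result) == 0:
                log.warning("trace %s: zero events detected", name)
        positive = feature_tables["blank_solution"].drop(columns=["label"])
        unlabeled = pd.concat([feature_tables[p.name] for p in config.profiles], ignore_index=True)
        positive.to_csv(outdir / "features_blank_solution.csv", index=False)
        unlabeled.to_csv(outdir / "features_samples.csv", index=False)

    with _stage("puc"):
        puc_cfg = dataclasses.replace(config.puc, seed=config.stage_seed("puc"))
        model = puc.fit_puc(positive, unlabeled.drop(columns=["label"]), puc_cfg)
        retained, removed, pu_report = puc.filter_blanks(model, unlabeled)
        retained.to_csv(outdir / "features_retained.csv", index=False)
        removed.to_csv(outdir / "features_removed.csv", index=False)
        note("puc", **pu_report)

    with _stage("classify"):
        spec = dataclasses.replace(config.classifier, seed=config.stage_seed("classify"))
        cm_raw, metrics_raw = cross_validate(unlabeled, spec=spec, k=config.folds)
        cm, metrics = cross_validate(retained, spec=spec, k=config.folds)
        cm.to_frame().to_csv(outdir / "confusion_matrix.csv")
        cm_raw.to_frame().to_csv(outdir / "confusion_matrix_unfiltered.csv")
        importances = feature_importance(retained, spec=spec)
        importances.rename("importance").to_csv(outdir / "feature_importance.csv")
        note(
            "classify",
            macro_f=metrics.macro_f,
            macro_f_unfiltered=metrics_raw.macro_f,
            folds=config.folds,
        )

    with _stage("vote"):
        vote_model = voting.VoteModel(k=len(cm.labels), p=metrics.macro_f)
        curve = voting.vote_curve(
            vote_model, range(1, config.vote_n_max + 1), seed=config.stage_seed("vote")
        )
        curve.to_csv(outdir / "vote_curve.csv", index=False)
        note("vote", k=vote_model.k, p=vote_model.p, n_max=config.vote_n_max)

    bundle = {
        "config": {
            "seed": config.seed,
            "stage_seeds": {s: config.stage_seed(s) for s in ("simulate", "puc", "classify", "vote")},
            "duration_s": config.duration_s,
            "sampling_rate_hz": rate,
            "folds": config.folds,
            "classifier": config.classifier.algorithm,
            "vote_model": {
                "k": vote_model.k,
                "p": vote_model.p,
                "error_model": "uniform over wrong classes",
                "tie_rule": "uniform among tied top classes",
            },
        },
        "detection": {name: int(len(feature_tables[name])) for name in feature_tables},
        "puc": pu_report,
        "classification": {
            "labels": cm.labels,
            "confusion": cm.ratios.tolist(),
            "confusion_unfiltered": cm_raw.ratios.tolist(),
            "per_class_f": metrics.per_class_f,
            "macro_f": metrics.macro_f,
            "macro_f_unfiltered": metrics_raw.macro_f,
            "n_folds": metrics.n_folds,
        },
        "feature_importance": importances.to_dict(),
        "vote_curve": curve.to_dict(orient="records"),
        "log": events,
    }
    (outdir / "report.json").write_text(json.dumps(bundle, indent=2))
    (outdir / "log.json").write_text(json.dumps(events, indent=2))
    return bundle


def render_report(bundle: dict) -> str:
    """Human-readable summary of a pipeline report bundle."""
    lines: list[str] = []
    cfg = bundle["config"]
    lines.append("nanogap single-molecule identification report")
    lines.append(f"  master seed: {cfg['seed']}; stage seeds: {cfg['stage_seeds']}")
    lines.append(f"  sampling rate: {cfg['sampling_rate_hz']:.0f} Hz, duration {cfg['duration_s']} s/trace")
    lines.append("detected signals per recording:")
    total = 0
    for name, n in bundle["detection"].items():
        lines.append(f"  {name}: {n}")
        total += n
    if total == 0:
        lines.append("  (zero events detected in every recording)")
    pu = bundle["puc"]
    lines.append(
        f"blank removal: c = {pu['c']:.3f}, removed {pu['n_removed']}/{pu['n_input']}"
        f" (retention {pu['retention_fraction']:.2f}, threshold {pu['threshold']})"
    )
    cls = bundle["classification"]
    lines.append(
        f"classification ({cfg['classifier']}, {cls['n_folds']}-fold CV): "
        f"macro F = {cls['macro_f']:.3f} after blank removal "
        f"(vs {cls['macro_f_unfiltered']:.3f} without)"
    )
    lines.append("confusion matrix (rows = true class, row-normalized):")
    lines.append("        " + "  ".join(f"{l:>8s}" for l in cls["labels"]))
    for label, row in zip(cls["labels"], cls["confusion"]):
        lines.append(f"  {label:>6s} " + "  ".join(f"{v:8.3f}" for v in row))
    imp = sorted(bundle["feature_importance"].items(), key=lambda kv: -kv[1])
    lines.append("top features: " + ", ".join(f"{k} ({v:.3f})" for k, v in imp[:5]))
    vm = cfg["vote_model"]
    curve = bundle["vote_curve"]
    lines.append(
        f"plurality vote (k={vm['k']}, p={vm['p']:.3f}, errors {vm['error_model']}, "
        f"ties {vm['tie_rule']}):"
    )
    for row in curve:
        if row["n"] in (1, 5, 11, curve[-1]["n"]):
            lines.append(f"  n={row['n']:>3d}: accuracy {row['accuracy']:.3f} ({row['method']})")
    return "\n".join(lines)
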