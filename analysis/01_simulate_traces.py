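"""Simulate the benchmark recordings: one blank-solution control and one
contaminated recording per nucleotide species.

Writes traces, truth annotations and a summary table under results/traces/,
and reports the headline finding of this step: molecule-spiked recordings
show a markedly higher signal-event rate than the blank control.
"""

import argparse
import dataclasses
from pathlib import Path

import pandas as pd

from nanogapid import io, synthetic

RESULTS = Path(__file__).resolve().parents[1] / "results"


def main(seed: int = 0) -> None:
    cfg = io.load_config({"seed": seed})
    outdir = RESULTS / "traces"
    outdir.mkdir(parents=True, exist_ok=True)
    sim_seed = cfg.stage_seed("simulate")

    recordings = [("blank_solution", [], [], cfg.blank_solution_rate_hz)] + [
        (p.name, [p], [cfg.species_rate_hz], cfg.blank_rate_hz) for p in cfg.profiles
    ]
    rows = []
    for i, (name, profiles, rates, blank_rate) in enumerate(recordings):
        trace = synthetic.simulate_trace(
            profiles=profiles,
            rates_hz=rates,
            noise=cfg.noise,
            duration_s=cfg.duration_s,
            seed=sim_seed + i,
            blank_profile=cfg.blank_profile,
            blank_rate_hz=blank_rate,
            trace_id=name,
        )
        io.write_trace(trace, outdir / f"trace_{name}.csv")
        synthetic.write_truth_annotations(trace, outdir / f"truth_{name}.csv")
        n_blank = sum(1 for *_, lab in trace.truth if lab == "blank")
        rows.append(
            {
                "recording": name,
                "n_events": len(trace.truth),
                "n_blank_events": n_blank,
                "event_rate_hz": len(trace.truth) / trace.duration_s,
                "duration_s": trace.duration_s,
                "seed": sim_seed + i,
            }
        )
    summary = pd.DataFrame(rows)
    summary.to_csv(outdir / "summary.csv", index=False)
    print(summary.to_string(index=False))
    blank_rate = summary.loc[summary.recording == "blank_solution", "event_rate_hz"].item()
    mol_rate = summary.loc[summary.recording != "blank_solution", "event_rate_hz"].mean()
    print(
        f"\nFinding: sample recordings carry {mol_rate:.1f} events/s vs "
        f"{blank_rate:.1f} events/s in the blank control — molecular signals "
        f"dominate, but every recording contains blanks."
    )


if __name__ == "__main__":
    parser = argparse.ArgumentParser()
    parser.add_argument("--seed", type=int, default=0)
    main(**vars(parser.parse_args()))
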