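#!/usr/bin/env python
"""Generate the demo dataset: phase-coupled synthetic EEG for 8 listeners.

Writes the recordings, per-trial envelopes and the full ground-truth table
to scratch/run/data (HDF5 + TSV) and a per-participant condition summary to
results/.  Downstream scripts pick the data up from scratch/run.
"""

import dataclasses
from pathlib import Path

import numpy as np

from deltaseg import io
from deltaseg.pipeline import RunConfig, _stage_seeds
from deltaseg.simulate import generate_dataset

ROOT = Path(__file__).resolve().parents[1]


def main():
    cfg = RunConfig.from_yaml(ROOT / "analysis" / "config.yaml")
    sim = dataclasses.replace(cfg.simulation,
                              seed=_stage_seeds(cfg.seed)["simulation"])
    ds = generate_dataset(sim)

    data_dir = ROOT / "scratch" / "run" / "data"
    io.save_dataset(data_dir, ds)
    (ROOT / "results").mkdir(exist_ok=True)
    summary = (
        ds.ground_truth.groupby(["participant", "rate_cond", "boundary"])
        .agg(n_trials=("trial", "size"),
             mean_amp=("true_evoked_amplitude", "mean"),
             sd_amp=("true_evoked_amplitude", "std"),
             mean_pause_s=("pause_s", "mean"))
        .round(4)
        .reset_index()
    )
    summary.to_csv(ROOT / "results" / "ground_truth_summary.tsv", sep="\t",
                   index=False)

    gt = ds.ground_truth
    print(f"simulated {len(ds.recordings)} participants, "
          f"{len(gt)} trials total, {sim.n_channels} channels "
          f"at {sim.sampling_rate:.0f} Hz -> {data_dir}")
    print(f"evoked amplitude: mean {gt.true_evoked_amplitude.mean():.2f} uV "
          f"(beta0 {sim.baseline_amplitude} + rate effect {sim.rate_effect} "
          f"x P(FAST) + kappa {sim.kappa} x cos(phase - {sim.phi0:.3f}))")
    resultant = np.abs(np.exp(1j * gt.true_phase_at_segpoint).mean())
    print(f"segmentation-point phases: resultant length {resultant:.3f} "
          "(uniform by construction; ~0 expected)")


if __name__ == "__main__":
    main()
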