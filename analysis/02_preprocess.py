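#!/usr/bin/env python
"""Preprocess the demo dataset into the two epoch streams.

ERP stream: verb-locked epochs −0.5..1.5 s, baseline 0–150 ms into the
verb (the simulated potentials are already in a reference-free, REST-like
frame, so no re-referencing is applied).  Phase stream: 4-Hz two-pass 10th-order
Butterworth low-pass on the continuous signal, downsample to 100 Hz, wide
−3..3 s epochs around the segmentation point.  Epochs land in
scratch/run/epochs (HDF5 + TSV trial tables).
"""

from pathlib import Path

from deltaseg import io
from deltaseg.pipeline import RunConfig, prep_participant

ROOT = Path(__file__).resolve().parents[1]


def main():
    cfg = RunConfig.from_yaml(ROOT / "analysis" / "config.yaml")
    recs = io.load_recordings(ROOT / "scratch" / "run" / "data")
    prepped = [prep_participant(r, cfg.prep) for r in recs]

    out = ROOT / "scratch" / "run" / "epochs"
    io.save_epochs(out / "verb_epochs.h5",
                   {p.participant: p.verb for p in prepped})
    io.save_epochs(out / "seg_epochs.h5",
                   {p.participant: p.seg for p in prepped})

    v, s = prepped[0].verb, prepped[0].seg
    print(f"preprocessed {len(prepped)} participants -> {out}")
    print(f"verb epochs: {v.n_trials} trials x {v.n_channels} ch x "
          f"{v.n_samples} samples ({v.tmin}..{v.times[-1]:.2f} s at "
          f"{v.rate:.0f} Hz, baseline {cfg.prep.baseline} s)")
    print(f"segmentation epochs: {s.n_samples} samples "
          f"({s.tmin}..{s.times[-1]:.2f} s at {s.rate:.0f} Hz, "
          f"<= {cfg.prep.lowpass_hz} Hz)")


if __name__ == "__main__":
    main()
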