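"""HDF5 containers and TSV tables.

Layout of a dataset file (one group per participant)::

    /P00/data            (channels, samples) float64, microvolts
    /P00/rate            scalar attr on the group
    /P00/ch_names        string dataset
    /P00/events          written separately as TSV (events.tsv)
    /P00/env/<trial>     per-trial envelope signal (attrs: t0, rate)

Epoch files mirror this with (trials, channels, samples) arrays plus the
epoch time origin; trial tables ride along as TSV so they stay greppable.
"""

from __future__ import annotations

import json
from pathlib import Path

import h5py
import numpy as np
import pandas as pd

from .containers import ContinuousRecording, EpochSet
from .simulate import SimulatedDataset, TrialEnvelope

__all__ = [
    "save_dataset",
    "load_recordings",
    "load_envelopes",
    "save_epochs",
    "load_epochs",
    "write_json",
]


def save_dataset(out_dir: str | Path, ds: SimulatedDataset) -> None:
    """Write recordings + envelopes (HDF5), event/ground-truth tables (TSV)."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    with h5py.File(out / "recordings.h5", "w") as f:
        for rec in ds.recordings:
            g = f.create_group(rec.participant)
            g.create_dataset("data", data=rec.data, compression="gzip")
            g.attrs["rate"] = rec.rate
            g.create_dataset("ch_names", data=list(rec.ch_names))
            g.create_dataset("positions", data=ds.layout.positions)
        env_root = f.create_group("envelopes")
        for env in ds.envelopes:
            g = env_root.create_group(f"{env.participant}/{env.trial:04d}")
            g.create_dataset("signal", data=env.signal)
            g.attrs["t0"] = env.t0
            g.attrs["rate"] = env.rate
    events = pd.concat(
        [rec.events.assign(participant=rec.participant) for rec in ds.recordings],
        ignore_index=True,
    )
    events.to_csv(out / "events.tsv", sep="\t", index=False)
    ds.ground_truth.to_csv(out / "ground_truth.tsv", sep="\t", index=False)


def load_recordings(out_dir: str | Path) -> list[ContinuousRecording]:
    out = Path(out_dir)
    events = pd.read_csv(out / "events.tsv", sep="\t")
    recs = []
    with h5py.File(out / "recordings.h5", "r") as f:
        for pid in sorted(k for k in f.keys() if k != "envelopes"):
            g = f[pid]
            names = tuple(n.decode() if isinstance(n, bytes) else str(n)
                          for n in g["ch_names"][()])
            recs.append(
                ContinuousRecording(
                    data=g["data"][()],
                    rate=float(g.attrs["rate"]),
                    ch_names=names,
                    events=events[events["participant"] == pid].drop(
                        columns="participant"
                    ).reset_index(drop=True),
                    participant=pid,
                )
            )
    return recs


def load_envelopes(out_dir: str | Path) -> list[TrialEnvelope]:
    envs = []
    with h5py.File(Path(out_dir) / "recordings.h5", "r") as f:
        root = f["envelopes"]
        for pid in sorted(root.keys()):
            for tkey in sorted(root[pid].keys()):
                g = root[pid][tkey]
                envs.append(
                    TrialEnvelope(
                        participant=pid,
                        trial=int(tkey),
                        t0=float(g.attrs["t0"]),
                        rate=float(g.attrs["rate"]),
                        signal=g["signal"][()],
                    )
                )
    return envs


def save_epochs(path: str | Path, epochs_by_participant: dict[str, EpochSet]) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with h5py.File(path, "w") as f:
        for pid, ep in epochs_by_participant.items():
            g = f.create_group(pid)
            g.create_dataset("data", data=ep.data, compression="gzip")
            g.attrs["rate"] = ep.rate
            g.attrs["tmin"] = ep.tmin
            g.attrs["event"] = ep.event
            g.create_dataset("ch_names", data=list(ep.ch_names))
    tables = pd.concat(
        [ep.trials.assign(participant=pid) for pid, ep in epochs_by_participant.items()],
        ignore_index=True,
    )
    tables.to_csv(path.with_suffix(".trials.tsv"), sep="\t", index=False)


def load_epochs(path: str | Path) -> dict[str, EpochSet]:
    path = Path(path)
    tables = pd.read_csv(path.with_suffix(".trials.tsv"), sep="\t")
    out = {}
    with h5py.File(path, "r") as f:
        for pid in sorted(f.keys()):
            g = f[pid]
            names = tuple(n.decode() if isinstance(n, bytes) else str(n)
                          for n in g["ch_names"][()])
            out[pid] = EpochSet(
                data=g["data"][()],
                rate=float(g.attrs["rate"]),
                tmin=float(g.attrs["tmin"]),
                ch_names=names,
                trials=tables[tables["participant"] == pid].reset_index(drop=True),
                event=str(g.attrs["event"]),
            )
    return out


class _NumpyEncoder(json.JSONEncoder):
    def default(self, obj):
        if isinstance(obj, (np.integer,)):
            return int(obj)
        if isinstance(obj, (np.floating,)):
            return float(obj)
        if isinstance(obj, np.ndarray):
            return obj.tolist()
        if isinstance(obj, np.bool_):
            return bool(obj)
        return super().default(obj)


def write_json(path: str | Path, payload: dict) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    path.write_text(json.dumps(payload, indent=2, sort_keys=True, cls=_NumpyEncoder))
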