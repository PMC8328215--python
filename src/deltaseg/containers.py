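"""In-memory containers shared by every analysis stage.

Voltages are microvolts throughout; times are seconds; event latencies are
stored in seconds and converted to sample indices only at the point of use
(nearest-sample rounding), which keeps them exact under resampling.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

__all__ = [
    "SensorLayout",
    "ContinuousRecording",
    "EpochSet",
]


@dataclass(frozen=True)
class SensorLayout:
    """Channel names plus 2-D positions on the unit disc."""

    names: tuple[str, ...]
    positions: np.ndarray  # (n_channels, 2)

    def __post_init__(self):
        pos = np.asarray(self.positions, dtype=float)
        if pos.ndim != 2 or pos.shape[1] != 2:
            raise ValueError("positions must be an (n, 2) array")
        if len(self.names) != pos.shape[0]:
            raise ValueError("names and positions disagree in length")
        if len(set(self.names)) != len(self.names):
            raise ValueError("channel names must be unique")
        object.__setattr__(self, "positions", pos)

    @property
    def n_channels(self) -> int:
        return len(self.names)

    def index(self, name: str) -> int:
        try:
            return self.names.index(name)
        except ValueError:
            raise KeyError(f"unknown channel {name!r}") from None


@dataclass
class ContinuousRecording:
    """A channels x samples voltage array with an event table.

    ``events`` is a DataFrame with at least columns ``label`` and ``time_s``
    (absolute seconds from the start of the recording); any further columns
    (trial id, condition labels) are carried into epochs cut from it.
    """

    data: np.ndarray  # (n_channels, n_samples), microvolts
    rate: float  # Hz
    ch_names: tuple[str, ...]
    events: pd.DataFrame
    participant: str = "P00"

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise ValueError("data must be (channels, samples)")
        if self.data.shape[0] != len(self.ch_names):
            raise ValueError("channel count mismatch")
        if np.isnan(self.data).any():
            raise ValueError("recording contains NaN")
        dur = self.data.shape[1] / self.rate
        if len(self.events) and (
            (self.events["time_s"] < 0).any() or (self.events["time_s"] > dur).any()
        ):
            raise ValueError("event latencies outside the recording")

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration(self) -> float:
        return self.n_samples / self.rate


@dataclass
class EpochSet:
    """Trials x channels x samples around a locking event.

    The epoch window is half-open ``[tmin, tmax)`` at sample resolution: an
    epoch cut from ``tmin`` to ``tmax`` at rate ``r`` holds exactly
    ``round((tmax - tmin) * r)`` samples, sample ``k`` sitting at
    ``tmin + k / r`` relative to the locking event.
    """

    data: np.ndarray  # (n_trials, n_channels, n_samples)
    rate: float
    tmin: float  # time of sample 0 relative to the locking event, s
    ch_names: tuple[str, ...]
    trials: pd.DataFrame = field(default_factory=pd.DataFrame)  # one row per trial
    event: str = ""

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 3:
            raise ValueError("data must be (trials, channels, samples)")
        if self.data.shape[1] != len(self.ch_names):
            raise ValueError("channel count mismatch")
        if len(self.trials) and len(self.trials) != self.data.shape[0]:
            raise ValueError("trial table length mismatch")

    @property
    def n_trials(self) -> int:
        return self.data.shape[0]

    @property
    def n_channels(self) -> int:
        return self.data.shape[1]

    @property
    def n_samples(self) -> int:
        return self.data.shape[2]

    @property
    def times(self) -> np.ndarray:
        return self.tmin + np.arange(self.n_samples) / self.rate

    def channel_index(self, name: str) -> int:
        try:
            return self.ch_names.index(name) if isinstance(self.ch_names, list) else tuple(self.ch_names).index(name)
        except ValueError:
            raise KeyError(f"unknown channel {name!r}") from None

    def time_index(self, t: float) -> int:
        """Nearest-sample index for a latency relative to the locking event."""
        idx = int(round((t - self.tmin) * self.rate))
        if not 0 <= idx < self.n_samples:
            raise ValueError(f"time {t} s outside epoch [{self.tmin}, {self.times[-1]}]")
        return idx

    def crop(self, t0: float, t1: float) -> "EpochSet":
        """Return the sub-epoch with t0 <= t <= t1 (inclusive, nearest samples)."""
        i0 = self.time_index(t0)
        i1 = self.time_index(t1)
        if i1 < i0:
            raise ValueError("t1 < t0")
        return replace(
            self,
            data=self.data[:, :, i0 : i1 + 1].copy(),
            tmin=self.tmin + i0 / self.rate,
        )

    def copy(self) -> "EpochSet":
        return replace(self, data=self.data.copy(), trials=self.trials.copy())
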