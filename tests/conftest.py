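import numpy as np
import pandas as pd
import pytest

from deltaseg.containers import ContinuousRecording, EpochSet


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def make_recording(data, rate, events=None, ch_names=None, participant="P00"):
    n_ch = data.shape[0]
    if ch_names is None:
        ch_names = tuple(f"E{i:02d}" for i in range(n_ch))
    if events is None:
        events = pd.DataFrame(columns=["label", "time_s"])
    return ContinuousRecording(
        data=data, rate=rate, ch_names=ch_names, events=events,
        participant=participant,
    )


def make_epochs(data, rate, tmin=0.0, trials=None, ch_names=None):
    n_ch = data.shape[1]
    if ch_names is None:
        ch_names = tuple(f"E{i:02d}" for i in range(n_ch))
    if trials is None:
        trials = pd.DataFrame({"trial": np.arange(data.shape[0])})
    return EpochSet(data=data, rate=rate, tmin=tmin, ch_names=ch_names,
                    trials=trials)
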