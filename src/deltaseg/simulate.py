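"""Synthetic phase-coupled EEG generator.

Emulates the recording situation of a two-rate sentence-listening study in
which a delta-band oscillation is hypothesized to gate segmentation: every
trial carries

* an ongoing delta-band oscillation (default 0.37 Hz, one cycle = 2.7 s)
  whose phase at the sentence-internal segmentation point is drawn uniformly
  per trial and recorded as ground truth;
* a centro-parietal evoked positivity ("P600-like") peaking ~0.456 s after
  the disambiguating-verb onset, whose single-trial amplitude is
  cosine-coupled to the delta phase at the segmentation point with coupling
  strength ``kappa`` and preferred phase ``phi0``, plus a FAST-vs-SLOW rate
  effect;
* a later broad negativity carried only by FAST trials and *not* coupled to
  phase (the selectivity control);
* 1/f^alpha background noise per channel plus white sensor noise;
* a per-trial prosodic envelope proxy with an optional boundary pause.

The delta component is a burst: it ramps up just before sentence onset and is
gone ~0.5 s after the segmentation point.  An oscillation running through the
whole trial would make the voltage inside the verb-locked epoch a
deterministic function of the segmentation-point phase and thereby couple
phase to "amplitude" even at ``kappa = 0``; the burst keeps the null
condition an actual null while leaving the phase-estimation window
(−0.5..0 s) fully inside the plateau.

Phase convention everywhere: cosine phase, 0 rad at the oscillation peak,
increasing in time.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd
from scipy.signal import get_window

from .containers import ContinuousRecording, SensorLayout

__all__ = [
    "RATES",
    "BOUNDARIES",
    "SimulationConfig",
    "TrialEnvelope",
    "SimulatedDataset",
    "make_layout",
    "make_pink_noise",
    "make_envelope",
    "generate_dataset",
]

RATES = ("FAST", "SLOW")
BOUNDARIES = ("PRESENT", "ABSENT")

#: events that must exist, in temporal order, per condition
EVENT_NAMES = ("sentence_onset", "segmentation_point", "verb_onset")

_DEFAULT_EVENT_TIMES = {
    # seconds relative to sentence onset; FAST is the SLOW design compressed
    # by the study's rate-manipulation ratio (0.62/0.94 = 0.66)
    "SLOW": {"sentence_onset": 0.0, "segmentation_point": 2.7, "verb_onset": 3.7},
    "FAST": {"sentence_onset": 0.0, "segmentation_point": 1.782, "verb_onset": 2.442},
}

_DEFAULT_PAUSES = {  # boundary-pause means (s): PRESENT from the stimulus table,
    # ABSENT essentially zero
    ("FAST", "PRESENT"): 0.214,
    ("SLOW", "PRESENT"): 0.342,
    ("FAST", "ABSENT"): 0.002,
    ("SLOW", "ABSENT"): 0.008,
}

_DEFAULT_PAUSE_SD = {
    ("FAST", "PRESENT"): 0.025,
    ("SLOW", "PRESENT"): 0.043,
    ("FAST", "ABSENT"): 0.002,
    ("SLOW", "ABSENT"): 0.006,
}


@dataclass
class SimulationConfig:
    """All knobs of the generator; defaults are the simulated study conditions."""

    n_participants: int = 8
    n_trials_per_condition: int = 40  # per RATE x BOUNDARY cell
    n_channels: int = 32
    sampling_rate: float = 250.0  # Hz
    delta_freq: float = 0.37  # Hz; one cycle ~ 2.7 s
    delta_amplitude: float = 12.0  # microvolts at the topography maximum
    kappa: float = 4.0  # phase->amplitude coupling strength, microvolts
    phi0: float = np.pi / 4  # preferred phase, radians
    rate_effect: float = 3.0  # FAST minus SLOW evoked amplitude, microvolts
    baseline_amplitude: float = 5.0  # beta0, microvolts
    p600_latency: float = 0.456  # s after verb onset
    p600_width: float = 0.12  # s (Hann bump full width)
    negativity_latency: float = 0.856  # s after verb onset
    negativity_width: float = 0.3  # s
    negativity_amplitude: float = -3.0  # microvolts, FAST trials only
    event_times: Mapping[str, Mapping[str, float]] = field(
        default_factory=lambda: {k: dict(v) for k, v in _DEFAULT_EVENT_TIMES.items()}
    )
    noise_exponent: float = 1.0  # 1/f^alpha
    noise_sd: float = 5.0  # pink-noise SD per channel, microvolts
    sensor_noise_sd: float = 1.0  # white noise SD, microvolts
    amp_noise_sd: float = 1.0  # per-trial evoked-amplitude jitter, microvolts
    boundary_pause_s: Mapping[tuple[str, str], float] = field(
        default_factory=lambda: dict(_DEFAULT_PAUSES)
    )
    pause_jitter_sd: Mapping[tuple[str, str], float] = field(
        default_factory=lambda: dict(_DEFAULT_PAUSE_SD)
    )
    delta_ramp_s: float = 0.3  # raised-cosine ramp of the delta burst
    delta_stop_after_seg_s: float = 0.2  # plateau extent past the segmentation point
    spatial_sigma: float = 0.25  # Gaussian topography width on the unit disc
    phase_reset_at_onset: bool = False  # optional realism mode: phase 0 at sentence onset
    seed: int = 0

    def __post_init__(self):
        if self.n_participants < 1 or self.n_trials_per_condition < 1:
            raise ValueError("need at least one participant and one trial per cell")
        if self.n_channels < 2:
            raise ValueError("need at least 2 channels")
        for name in ("sampling_rate", "delta_freq", "p600_width", "negativity_width"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        if self.delta_freq >= 4.0:
            raise ValueError("delta_freq must stay below the 4 Hz analysis low-pass")
        if self.sampling_rate < 4 * self.delta_freq * 10:
            raise ValueError("sampling_rate must comfortably oversample delta_freq")
        if self.noise_exponent < 0:
            raise ValueError("noise_exponent must be >= 0")
        for rate in RATES:
            ev = self.event_times[rate]
            if not (
                ev["sentence_onset"] < ev["segmentation_point"] < ev["verb_onset"]
            ):
                raise ValueError(f"event times for {rate} are not ordered")

    # --- derived trial geometry (identical for every trial) -------------
    @property
    def pre_seg_s(self) -> float:
        """Seconds of trial allocated before the segmentation point."""
        gap = max(
            self.event_times[r]["segmentation_point"]
            - self.event_times[r]["sentence_onset"]
            for r in RATES
        )
        return max(3.0, gap + 2 * self.delta_ramp_s) + 0.2

    @property
    def post_seg_s(self) -> float:
        gap = max(
            self.event_times[r]["verb_onset"]
            - self.event_times[r]["segmentation_point"]
            for r in RATES
        )
        tail = gap + self.negativity_latency + self.negativity_width
        return max(3.0, tail + 0.5) + 0.2

    @property
    def trial_len_s(self) -> float:
        return self.pre_seg_s + self.post_seg_s

    @property
    def n_trials_total(self) -> int:
        return self.n_trials_per_condition * len(RATES) * len(BOUNDARIES)


@dataclass
class TrialEnvelope:
    """Per-trial prosodic envelope proxy, on the recording's absolute clock."""

    participant: str
    trial: int
    t0: float  # absolute time of the first envelope sample, s
    rate: float  # Hz
    signal: np.ndarray


@dataclass
class SimulatedDataset:
    recordings: list[ContinuousRecording]
    ground_truth: pd.DataFrame
    envelopes: list[TrialEnvelope]
    layout: SensorLayout
    config: SimulationConfig
    centers: dict[str, str] = field(default_factory=dict)  # component -> channel
    weights: dict[str, np.ndarray] = field(default_factory=dict)  # component -> map


# ----------------------------------------------------------------------
# primitives


def make_layout(n_channels: int) -> SensorLayout:
    """Deterministic sensor layout: sunflower (Fibonacci) spiral on the unit disc.

    Channel E00 sits at the disc centre, mimicking the vertex electrode; the
    spiral fills the disc with near-uniform density, so a distance- or
    triangulation-based neighbour graph is connected for any realistic n.
    """
    if n_channels < 2:
        raise ValueError("need at least 2 channels")
    k = np.arange(n_channels, dtype=float)
    golden = math.pi * (3.0 - math.sqrt(5.0))
    r = np.sqrt(k / max(n_channels - 1, 1)) * 0.95
    theta = k * golden
    pos = np.column_stack([r * np.cos(theta), r * np.sin(theta)])
    names = tuple(f"E{i:02d}" for i in range(n_channels))
    return SensorLayout(names=names, positions=pos)


def make_pink_noise(
    n_samples: int,
    exponent: float,
    rate: float,
    rng: np.random.Generator | int | None = None,
) -> np.ndarray:
    """Zero-mean noise with power spectral density proportional to 1/f^exponent.

    Generated by shaping the spectrum of white Gaussian noise; the shaping is
    flat below 0.01 Hz so the variance stays finite for exponents >= 1.  The
    output is standardized to unit variance (callers scale it).
    """
    if n_samples < 2:
        raise ValueError("n_samples must be >= 2")
    if exponent < 0:
        raise ValueError("exponent must be >= 0")
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    white = rng.standard_normal(n_samples)
    if exponent == 0:
        out = white
    else:
        spec = np.fft.rfft(white)
        freqs = np.fft.rfftfreq(n_samples, d=1.0 / rate)
        floor = 0.05  # Hz; amplifier-like drift cutoff, keeps variance finite
        shaping = np.maximum(freqs, floor) ** (-exponent / 2.0)
        shaping[0] = 0.0  # kill DC: zero mean by construction
        out = np.fft.irfft(spec * shaping, n=n_samples)
    out = out - out.mean()
    sd = out.std()
    return out / sd if sd > 0 else out


def make_envelope(
    condition: tuple[str, str],
    event_times: Mapping[str, float],
    boundary_pause_s: float,
    rate: float,
) -> np.ndarray:
    """Prosodic (pitch-envelope proxy) signal for one trial.

    Returns a nonnegative signal spanning ``[sentence_onset, speech_end)`` at
    ``rate`` Hz, a raised-cosine syllable modulation on a positive floor so
    it is strictly positive wherever speech is present.  For a nonzero
    ``boundary_pause_s`` a contiguous zero run of that duration starts at the
    segmentation point.  FAST envelopes are time-compressed versions of SLOW
    ones: the syllable rate scales inversely with the sentence duration.
    """
    rate_cond, _boundary = condition
    if rate_cond not in RATES:
        raise ValueError(f"unknown rate condition {rate_cond!r}")
    onset = event_times["sentence_onset"]
    seg = event_times["segmentation_point"]
    verb = event_times["verb_onset"]
    if not onset < seg < verb:
        raise ValueError("event times must be ordered")
    if boundary_pause_s < 0:
        raise ValueError("pause must be nonnegative")
    if boundary_pause_s > verb - seg:
        raise ValueError("pause longer than the segmentation-to-verb gap")
    # speech extends one verb-length word past verb onset; time scale relative
    # to the canonical slow design (segmentation at 2.7 s)
    scale = (seg - onset) / 2.7
    speech_end = verb + 0.6 * scale
    n = int(round((speech_end - onset) * rate))
    t = onset + np.arange(n) / rate
    syllable_hz = 4.0 / scale
    env = 0.2 + 0.8 * 0.5 * (1.0 - np.cos(2 * np.pi * syllable_hz * (t - onset)))
    if boundary_pause_s > 0:
        in_pause = (t >= seg) & (t < seg + boundary_pause_s)
        env[in_pause] = 0.0
    return env


# ----------------------------------------------------------------------
# the generator


def _gauss_weights(layout: SensorLayout, center: np.ndarray, sigma: float) -> np.ndarray:
    d2 = ((layout.positions - center) ** 2).sum(axis=1)
    return np.exp(-d2 / (2.0 * sigma**2))


def _hann_bump(width_s: float, rate: float) -> np.ndarray:
    n = max(int(round(width_s * rate)), 3)
    return get_window("hann", n, fftbins=False)


def _delta_envelope(
    t: np.ndarray, onset: float, stop: float, ramp: float
) -> np.ndarray:
    """Raised-cosine-flanked plateau: 0 before onset-ramp, 1 on [onset, stop]."""
    env = np.zeros_like(t)
    plateau = (t >= onset) & (t <= stop)
    env[plateau] = 1.0
    up = (t >= onset - ramp) & (t < onset)
    env[up] = 0.5 * (1 + np.cos(np.pi * (t[up] - onset) / ramp))
    down = (t > stop) & (t <= stop + ramp)
    env[down] = 0.5 * (1 + np.cos(np.pi * (t[down] - stop) / ramp))
    return env


def topography_centers(layout: SensorLayout) -> dict[str, str]:
    """Default component centres: delta and the positivity share the channel
    nearest the disc centre (the study's effect and phase peak coincide on one
    electrode); the negativity sits on the nearest distinct neighbour."""
    d_origin = np.linalg.norm(layout.positions, axis=1)
    center = int(np.argmin(d_origin))
    order = np.argsort(np.linalg.norm(layout.positions - layout.positions[center], axis=1))
    neg = int(order[1]) if len(order) > 1 else center
    return {
        "delta": layout.names[center],
        "p600": layout.names[center],
        "negativity": layout.names[neg],
    }


def generate_dataset(config: SimulationConfig) -> SimulatedDataset:
    """Simulate every participant's continuous recording plus ground truth.

    Each participant's recording is a concatenation of equal-length trial
    slots; the event table carries the three within-trial events with
    condition labels, so downstream epoching can lock to any of them.  A
    trial slot spans at least ``segmentation_point - 3 s`` to
    ``verb_onset + 1.5 s`` (validated here rather than silently truncated).
    """
    cfg = config
    fs = cfg.sampling_rate
    layout = make_layout(cfg.n_channels)
    centers = topography_centers(layout)
    w_delta = _gauss_weights(
        layout, layout.positions[layout.index(centers["delta"])], cfg.spatial_sigma
    )
    w_p600 = _gauss_weights(
        layout, layout.positions[layout.index(centers["p600"])], cfg.spatial_sigma
    )
    w_neg = _gauss_weights(
        layout, layout.positions[layout.index(centers["negativity"])], cfg.spatial_sigma
    )

    trial_len = cfg.trial_len_s
    n_trial_samp = int(round(trial_len * fs))
    pre = cfg.pre_seg_s
    # sanity: epoch demands fit the slot
    for r in RATES:
        ev = cfg.event_times[r]
        seg_in_trial = pre
        verb_in_trial = pre + ev["verb_onset"] - ev["segmentation_point"]
        if seg_in_trial - 3.0 < 0 or verb_in_trial + 1.5 > trial_len:
            raise ValueError(
                "trial slot too short for the required epoch windows; "
                "check event_times"
            )

    master = np.random.SeedSequence(cfg.seed)
    part_seeds = master.spawn(cfg.n_participants)

    recordings: list[ContinuousRecording] = []
    gt_rows: list[dict] = []
    envelopes: list[TrialEnvelope] = []

    n_total = cfg.n_trials_total
    conditions = [
        (r, b)
        for r in RATES
        for b in BOUNDARIES
        for _ in range(cfg.n_trials_per_condition)
    ]

    for p in range(cfg.n_participants):
        pid = f"P{p:02d}"
        rng = np.random.default_rng(part_seeds[p])
        order = rng.permutation(n_total)
        trial_conditions = [conditions[i] for i in order]

        n_samp = n_trial_samp * n_total
        data = np.zeros((cfg.n_channels, n_samp))

        # background noise, continuous across the whole recording
        for c in range(cfg.n_channels):
            data[c] += cfg.noise_sd * make_pink_noise(
                n_samp, cfg.noise_exponent, fs, rng
            )
        if cfg.sensor_noise_sd > 0:
            data += cfg.sensor_noise_sd * rng.standard_normal(data.shape)

        t_slot = np.arange(n_trial_samp) / fs  # trial-local clock
        bump_p = _hann_bump(cfg.p600_width, fs)
        bump_n = _hann_bump(cfg.negativity_width, fs)

        ev_rows = []
        for i, (rate_cond, boundary) in enumerate(trial_conditions):
            ev = cfg.event_times[rate_cond]
            slot0 = i * n_trial_samp
            t0_abs = slot0 / fs
            seg_local = pre
            onset_local = pre - (ev["segmentation_point"] - ev["sentence_onset"])
            verb_local = pre + (ev["verb_onset"] - ev["segmentation_point"])

            if cfg.phase_reset_at_onset:
                phi = (
                    -2 * np.pi * cfg.delta_freq * (seg_local - onset_local)
                ) % (2 * np.pi)
                phi = float(np.angle(np.exp(1j * phi)))
            else:
                phi = float(rng.uniform(-np.pi, np.pi))
            amp_noise = float(rng.normal(0.0, cfg.amp_noise_sd))
            amp = (
                cfg.baseline_amplitude
                + cfg.rate_effect * (rate_cond == "FAST")
                + cfg.kappa * np.cos(phi - cfg.phi0)
                + amp_noise
            )

            # delta burst with exact phase phi at the segmentation point
            if cfg.delta_amplitude != 0:
                burst = _delta_envelope(
                    t_slot,
                    onset_local,
                    seg_local + cfg.delta_stop_after_seg_s,
                    cfg.delta_ramp_s,
                )
                osc = burst * np.cos(
                    2 * np.pi * cfg.delta_freq * (t_slot - seg_local) + phi
                )
                data[:, slot0 : slot0 + n_trial_samp] += (
                    cfg.delta_amplitude * np.outer(w_delta, osc)
                )

            # evoked positivity, cosine-coupled amplitude
            pk = int(round((verb_local + cfg.p600_latency) * fs))
            b0 = slot0 + pk - len(bump_p) // 2
            data[:, b0 : b0 + len(bump_p)] += amp * np.outer(w_p600, bump_p)

            # uncoupled later negativity (FAST only)
            if rate_cond == "FAST" and cfg.negativity_amplitude != 0:
                nk = int(round((verb_local + cfg.negativity_latency) * fs))
                b0 = slot0 + nk - len(bump_n) // 2
                seg_sl = data[:, b0 : b0 + len(bump_n)]
                seg_sl += cfg.negativity_amplitude * np.outer(
                    w_neg, bump_n[: seg_sl.shape[1]]
                )

            # prosodic envelope proxy
            key = (rate_cond, boundary)
            pause = float(
                max(
                    rng.normal(cfg.boundary_pause_s[key], cfg.pause_jitter_sd[key]),
                    0.0,
                )
            )
            pause = min(pause, (ev["verb_onset"] - ev["segmentation_point"]) * 0.9)
            env = make_envelope((rate_cond, boundary), ev, pause, fs)
            envelopes.append(
                TrialEnvelope(
                    participant=pid,
                    trial=i,
                    t0=t0_abs + onset_local,
                    rate=fs,
                    signal=env,
                )
            )

            for name, local in (
                ("sentence_onset", onset_local),
                ("segmentation_point", seg_local),
                ("verb_onset", verb_local),
            ):
                ev_rows.append(
                    {
                        "label": name,
                        "time_s": t0_abs + local,
                        "trial": i,
                        "rate_cond": rate_cond,
                        "boundary": boundary,
                    }
                )
            gt_rows.append(
                {
                    "participant": pid,
                    "trial": i,
                    "rate_cond": rate_cond,
                    "boundary": boundary,
                    "true_phase_at_segpoint": phi,
                    "amp_noise": amp_noise,
                    "true_evoked_amplitude": amp,
                    "kappa": cfg.kappa,
                    "phi0": cfg.phi0,
                    "pause_s": pause,
                    "segpoint_time_s": t0_abs + seg_local,
                    "verb_time_s": t0_abs + verb_local,
                }
            )

        recordings.append(
            ContinuousRecording(
                data=data,
                rate=fs,
                ch_names=layout.names,
                events=pd.DataFrame(ev_rows),
                participant=pid,
            )
        )

    return SimulatedDataset(
        recordings=recordings,
        ground_truth=pd.DataFrame(gt_rows),
        envelopes=envelopes,
        layout=layout,
        config=cfg,
        centers=centers,
        weights={"delta": w_delta, "p600": w_p600, "negativity": w_neg},
    )
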