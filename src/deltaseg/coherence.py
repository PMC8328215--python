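"""Prosody-entrainment control: across-trial magnitude-squared coherence
between a stimulus-envelope proxy and the delta-band EEG, band-averaged over
0–4 Hz and compared between conditions with a Wilcoxon signed-rank test.

Across-trial coherence at frequency f is

    C(f) = |Σ_i X_i(f) conj(Y_i(f))|² / (Σ_i |X_i(f)|² · Σ_i |Y_i(f)|²),

the sum running over trials, each trial demeaned and Hann-tapered before
the FFT.  Cauchy–Schwarz bounds C(f) to [0, 1]; a single trial is
identically 1, hence at least two trials are required.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.signal import get_window
from scipy.stats import norm, rankdata

__all__ = [
    "CoherenceSpectrum",
    "mscoherence_across_trials",
    "band_average",
    "wilcoxon_signed_rank",
]


@dataclass
class CoherenceSpectrum:
    freqs: np.ndarray  # Hz, including the DC bin
    coherence: np.ndarray  # values in [0, 1]
    n_trials: int
    duration: float  # s of the analyzed segment (sets df = 1/duration)


def mscoherence_across_trials(
    eeg_trials: np.ndarray,
    env_trials: np.ndarray,
    rate: float,
    fmax: float = 4.0,
) -> CoherenceSpectrum:
    """Magnitude-squared coherence across trials, single Hann taper per trial.

    ``eeg_trials`` and ``env_trials`` are (n_trials, n_samples) arrays of
    matched segments.  Frequency resolution is 1/duration; bins above
    ``fmax`` are discarded.
    """
    x = np.asarray(eeg_trials, dtype=float)
    y = np.asarray(env_trials, dtype=float)
    if x.shape != y.shape or x.ndim != 2:
        raise ValueError("need matched (n_trials, n_samples) arrays")
    n_trials, n_samp = x.shape
    if n_trials < 2:
        raise ValueError("coherence of a single trial is identically 1")
    taper = get_window("hann", n_samp, fftbins=False)
    xw = (x - x.mean(axis=1, keepdims=True)) * taper
    yw = (y - y.mean(axis=1, keepdims=True)) * taper
    X = np.fft.rfft(xw, axis=1)
    Y = np.fft.rfft(yw, axis=1)
    freqs = np.fft.rfftfreq(n_samp, d=1.0 / rate)
    cross = (X * np.conj(Y)).sum(axis=0)
    px = (np.abs(X) ** 2).sum(axis=0)
    py = (np.abs(Y) ** 2).sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        coh = np.abs(cross) ** 2 / (px * py)
    coh = np.where((px > 0) & (py > 0), coh, 0.0)
    keep = freqs <= fmax
    return CoherenceSpectrum(
        freqs=freqs[keep],
        coherence=np.clip(coh[keep], 0.0, 1.0),
        n_trials=n_trials,
        duration=n_samp / rate,
    )


def band_average(spectrum: CoherenceSpectrum) -> float:
    """Unweighted mean coherence over the band, excluding the DC bin.

    The envelope is strictly positive, so its DC component would dominate
    any average that included bin 0.
    """
    keep = spectrum.freqs > 0
    if not keep.any():
        raise ValueError("no non-DC bins in the spectrum")
    return float(spectrum.coherence[keep].mean())


def _exact_signed_rank_p(ranks: np.ndarray, w_obs: float, mu: float) -> float:
    """Exact two-sided p for W⁺ by convolution over all sign assignments.

    Ranks are doubled so mid-ranks become integers; the distribution of the
    doubled W⁺ is built by dynamic programming over the 2^n equally likely
    sign patterns.
    """
    scaled = np.round(2 * ranks).astype(int)
    dist = np.zeros(scaled.sum() + 1)
    dist[0] = 1.0
    for r in scaled:
        shifted = np.zeros_like(dist)
        shifted[r:] = dist[: dist.size - r]
        dist = 0.5 * (dist + shifted)
    support = np.arange(dist.size)
    dev = np.abs(support - 2 * mu)
    return float(dist[dev >= 2 * abs(w_obs - mu) - 1e-9].sum())


def wilcoxon_signed_rank(
    a: np.ndarray, b: np.ndarray, method: str = "auto"
) -> tuple[float, float]:
    """Paired Wilcoxon signed-rank test.

    Zero differences are dropped; ties get mid-ranks with the usual
    tie-corrected variance  n(n+1)(2n+1)/24 − Σ(t³−t)/48.  Returns
    (z, two-sided p) with z = (W⁺ − μ_W)/σ_W.  The p-value is exact
    (full enumeration of sign patterns, valid with mid-ranks) for n ≤ 25
    under ``method="auto"``; larger samples use the normal approximation,
    where z and p are consistent.  All-zero differences give a degenerate
    (nan, nan) outcome with a warning.
    """
    if method not in ("auto", "exact", "approx"):
        raise ValueError("method must be 'auto', 'exact' or 'approx'")
    a = np.asarray(a, dtype=float).ravel()
    b = np.asarray(b, dtype=float).ravel()
    if a.shape != b.shape:
        raise ValueError("need matched pairs")
    d = a - b
    d = d[d != 0]
    n = d.size
    if n == 0:
        warnings.warn("all differences zero: test degenerate", RuntimeWarning,
                      stacklevel=2)
        return float("nan"), float("nan")
    ranks = rankdata(np.abs(d))
    w_plus = ranks[d > 0].sum()
    mu = n * (n + 1) / 4.0
    var = n * (n + 1) * (2 * n + 1) / 24.0
    _, counts = np.unique(ranks, return_counts=True)
    var -= ((counts**3 - counts) / 48.0).sum()
    if var <= 0:
        warnings.warn("zero variance after tie correction", RuntimeWarning,
                      stacklevel=2)
        return float("nan"), float("nan")
    z = (w_plus - mu) / np.sqrt(var)
    if method == "exact" or (method == "auto" and n <= 25):
        p = _exact_signed_rank_p(ranks, w_plus, mu)
    else:
        p = 2.0 * norm.sf(abs(z))
    return float(z), float(min(p, 1.0))
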