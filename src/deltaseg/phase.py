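"""Delta-phase / single-trial-amplitude coupling inference.

The chain is: Hilbert analytic phase of the 4-Hz low-passed signal around
the segmentation point → per participant, per (channel, sample) in the
−0.5..0 s window, circular–linear correlation between phase and the
single-trial amplitude of the downstream ERP → Fisher z → group mean z
across participants → trial-reassignment surrogate null (one shuffle per
permutation per participant, shared across all cells to preserve the
spatial/temporal dependence of the null) → Benjamini–Hochberg FDR over the
channel x sample family.

The circular–linear correlation of an angle θ with a linear variable x is

    r = sqrt((r_cx² + r_sx² − 2 r_cx r_sx r_cs) / (1 − r_cs²)),

with r_cx = corr(cos θ, x), r_sx = corr(sin θ, x), r_cs = corr(sin θ, cos θ);
equivalently, r is the maximum over φ of |corr(x, cos(θ − φ))|, which makes
it invariant to rotating all phases and to affine maps of x, and nonnegative
by construction.  The maximizing φ is the preferred phase.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.signal import hilbert
from statsmodels.stats.multitest import multipletests

from .containers import EpochSet

__all__ = [
    "PhaseMap",
    "PhaseCorrResult",
    "hilbert_phase",
    "circ_lin_corr",
    "fisher_z",
    "surrogate_null",
    "group_phase_amplitude_test",
    "fdr_bh",
    "estimate_preferred_phase",
]


@dataclass
class PhaseMap:
    """Trials x channels x samples instantaneous phase, radians in (−π, π]."""

    data: np.ndarray
    rate: float
    tmin: float  # s relative to the locking event
    ch_names: tuple[str, ...]
    trials: object = None  # trial metadata DataFrame, carried through

    @property
    def times(self) -> np.ndarray:
        return self.tmin + np.arange(self.data.shape[2]) / self.rate


def _ar_extend_batch(x: np.ndarray, order: int, n_ext: int) -> np.ndarray:
    """Linear-prediction extension of each row of ``x`` at both ends.

    Fits an order-``order`` autoregressive model per row (covariance-method
    least squares with a tiny ridge), reflects any unstable poles inside the
    unit circle, and continues the signal ``n_ext`` samples forward and
    backward.  The FFT analytic signal assumes a periodic continuation; for
    oscillations slow enough that the window holds only a couple of cycles,
    that wrap-around discontinuity leaks into the phase estimate far from
    the edges, and an AR continuation removes it.
    """
    from numpy.lib.stride_tricks import sliding_window_view

    def fit(rows: np.ndarray) -> np.ndarray:
        # predictor columns are x[t-1] .. x[t-order]
        win = sliding_window_view(rows, order, axis=-1)  # (B, n-order+1, order)
        design = np.ascontiguousarray(win[:, :-1, ::-1])
        y = rows[:, order:]
        g = np.einsum("bto,btp->bop", design, design)
        rhs = np.einsum("bto,bt->bo", design, y)
        # min-norm solution: the normal matrix is rank-deficient for clean
        # narrowband signals, and any visible ridge biases the extension
        coef = np.einsum("bop,bp->bo", np.linalg.pinv(g, rcond=1e-10), rhs)
        # reflect AR poles outside the unit circle back inside (batched):
        # the companion-matrix eigenvalues are the poles, and the polynomial
        # is rebuilt from them by iterated convolution
        comp = np.zeros((rows.shape[0], order, order))
        comp[:, 0, :] = coef
        comp[:, 1:, :-1] = np.eye(order - 1)
        poles = np.linalg.eigvals(comp)
        mags = np.abs(poles)
        bad = (mags > 1.0).any(axis=1)
        if bad.any():
            pb = poles[bad]
            mb = mags[bad]
            pb = np.where(mb > 1.0, pb / mb**2, pb)
            poly = np.zeros((pb.shape[0], order + 1), dtype=complex)
            poly[:, 0] = 1.0
            for k in range(order):
                poly[:, 1 : k + 2] -= pb[:, k, None] * poly[:, : k + 1].copy()
            coef[bad] = -poly[:, 1:].real
        return coef

    def extend(rows: np.ndarray, coef: np.ndarray) -> np.ndarray:
        buf = np.empty((rows.shape[0], order + n_ext))
        buf[:, :order] = rows[:, -order:]
        rev_coef = coef[:, ::-1]
        for i in range(order, order + n_ext):
            buf[:, i] = np.einsum("bo,bo->b", rev_coef, buf[:, i - order : i])
        return buf[:, order:]

    mean = x.mean(axis=-1, keepdims=True)
    xc = x - mean
    # one AR fit serves both directions: a real stationary AR process has
    # identical forward and backward predictors
    coef = fit(xc)
    fwd = extend(xc, coef)
    bwd = extend(xc[:, ::-1], coef)[:, ::-1]
    return np.concatenate([bwd, xc, fwd], axis=-1) + mean


def hilbert_phase(
    epochs: EpochSet,
    expected_rate: float = 100.0,
    edge: str = "ar",
    ar_order: int = 8,
) -> PhaseMap:
    """Instantaneous phase as the argument of the analytic signal.

    Cosine convention: a pure cosine has phase 0 at its local maxima.  The
    input is expected to be low-passed (≤ 4 Hz) and downsampled to
    ``expected_rate`` by the preceding pipeline stages; a mismatched rate
    only triggers a warning because the transform itself is rate-agnostic.

    ``edge="ar"`` (default) extends every trial/channel by linear prediction
    to one epoch length on each side before the FFT analytic signal, which
    suppresses the wrap-around leakage that otherwise contaminates the phase
    of sub-1-Hz components even well inside the epoch; ``edge="none"`` is
    the plain transform.
    """
    if np.isnan(epochs.data).any():
        raise ValueError("epochs contain NaN")
    if epochs.rate != expected_rate:
        warnings.warn(
            f"epochs sampled at {epochs.rate} Hz, expected {expected_rate} Hz; "
            "did the resampling stage run?",
            RuntimeWarning,
            stacklevel=2,
        )
    n_tr, n_ch, n_s = epochs.data.shape
    if edge == "ar" and n_s > 3 * ar_order:
        flat = epochs.data.reshape(n_tr * n_ch, n_s)
        ext = _ar_extend_batch(flat, ar_order, n_s)
        analytic = hilbert(ext, axis=-1)[:, n_s : 2 * n_s]
        analytic = analytic.reshape(n_tr, n_ch, n_s)
    elif edge in ("ar", "none"):
        analytic = hilbert(epochs.data, axis=-1)
    else:
        raise ValueError("edge must be 'ar' or 'none'")
    return PhaseMap(
        data=np.angle(analytic),
        rate=epochs.rate,
        tmin=epochs.tmin,
        ch_names=tuple(epochs.ch_names),
        trials=epochs.trials,
    )


# ----------------------------------------------------------------------
# circular-linear correlation


def _standardize(a: np.ndarray, axis: int = 0):
    m = a.mean(axis=axis, keepdims=True)
    s = a.std(axis=axis, keepdims=True)
    with np.errstate(invalid="ignore", divide="ignore"):
        z = (a - m) / s
    return z, np.squeeze(s, axis=axis)


def _circ_lin_map(theta: np.ndarray, xs: np.ndarray) -> np.ndarray:
    """Vectorized circular-linear r.

    theta: (n, m) angles for m cells; xs: (P, n) standardized linear
    variables (each row zero mean, unit variance).  Returns (P, m) r values;
    degenerate cells are NaN.
    """
    n = theta.shape[0]
    c, sc = _standardize(np.cos(theta))
    s, ss = _standardize(np.sin(theta))
    r_cs = np.einsum("nm,nm->m", c, s) / n
    r_cx = xs @ c / n  # (P, m)
    r_sx = xs @ s / n
    denom = 1.0 - r_cs**2
    with np.errstate(invalid="ignore", divide="ignore"):
        r2 = (r_cx**2 + r_sx**2 - 2 * r_cx * r_sx * r_cs) / denom
    r = np.sqrt(np.clip(r2, 0.0, 1.0))
    bad = (sc == 0) | (ss == 0) | (denom < 1e-12)
    r[..., bad] = np.nan
    return r


def circ_lin_corr(theta: np.ndarray, x: np.ndarray) -> float:
    """Circular–linear correlation coefficient, r in [0, 1].

    NaN (a flagged degenerate outcome, with a warning) when x has zero
    variance or the phases are degenerate (all equal, or confined so that
    sin θ and cos θ are collinear).
    """
    theta = np.asarray(theta, dtype=float).ravel()
    x = np.asarray(x, dtype=float).ravel()
    if theta.size != x.size:
        raise ValueError("theta and x must have equal length")
    if theta.size < 4:
        raise ValueError("need at least 4 observations")
    xs, xsd = _standardize(x[:, None])
    if np.ravel(xsd)[0] == 0:
        warnings.warn("x has zero variance; r undefined", RuntimeWarning, stacklevel=2)
        return float("nan")
    r = _circ_lin_map(theta[:, None], xs.T)[0, 0]
    if np.isnan(r):
        warnings.warn("degenerate phase distribution; r undefined",
                      RuntimeWarning, stacklevel=2)
    return float(r)


def fisher_z(r):
    """Variance-stabilizing Fisher transform, z = atanh(r), for r in [0, 1).

    r = 1 maps to +inf (flagged with a warning); values outside [0, 1] raise.
    """
    arr = np.asarray(r, dtype=float)
    if np.any((arr < 0) | (arr > 1)):
        raise ValueError("r must lie in [0, 1]")
    if np.any(arr == 1):
        warnings.warn("r = 1 maps to infinite z", RuntimeWarning, stacklevel=2)
    with np.errstate(divide="ignore"):
        out = np.arctanh(arr)
    return float(out) if np.isscalar(r) else out


def estimate_preferred_phase(theta: np.ndarray, x: np.ndarray) -> float:
    """Preferred phase φ̂0 = argmax over φ of corr(x, cos(θ − φ)).

    Closed form from the least-squares regression of x on (cos θ, sin θ):
    x ≈ a cos θ + b sin θ = R cos(θ − atan2(b, a)).  Wrapped to (−π, π].
    """
    theta = np.asarray(theta, dtype=float).ravel()
    x = np.asarray(x, dtype=float).ravel()
    if theta.size != x.size or theta.size < 4:
        raise ValueError("need equal-length inputs with at least 4 observations")
    design = np.column_stack([np.cos(theta), np.sin(theta)])
    design -= design.mean(axis=0)
    xc = x - x.mean()
    coef, *_ = np.linalg.lstsq(design, xc, rcond=None)
    a, b = coef
    if a == 0 and b == 0:
        warnings.warn("no cosine fit; preferred phase undefined",
                      RuntimeWarning, stacklevel=2)
        return float("nan")
    return float(np.arctan2(b, a))


def circular_mean(angles: np.ndarray) -> float:
    """Mean direction of a set of angles, radians in (−π, π]."""
    angles = np.asarray(angles, dtype=float)
    angles = angles[np.isfinite(angles)]
    if angles.size == 0:
        return float("nan")
    return float(np.angle(np.exp(1j * angles).mean()))


# ----------------------------------------------------------------------
# surrogate null


def _shuffle_matrix(n: int, n_perm: int, rng: np.random.Generator,
                    include_identity: bool) -> np.ndarray:
    idx = np.tile(np.arange(n), (n_perm, 1))
    start = 1 if include_identity else 0
    if n_perm > start:
        idx[start:] = rng.permuted(idx[start:], axis=1)
    return idx


def surrogate_null(
    theta: np.ndarray,
    x: np.ndarray,
    n_perm: int,
    seed: int | None = 0,
    include_identity: bool = False,
) -> np.ndarray:
    """Trial-reassignment surrogate distribution of Fisher z.

    Each permutation shuffles the amplitude vector's trial assignment while
    the phases stay fixed, then recomputes r and z.  ``theta`` may be
    (n_trials,) for a single cell or (n_trials, m) for m cells, in which
    case the *same* shuffle is applied to every cell of a permutation —
    preserving the spatial/temporal dependence structure in the null.  With
    ``include_identity`` the first "permutation" is the identity, so
    ``null[0]`` equals the observed z (a convention check; the inferential
    path uses all-random shuffles with the plus-one p-value rule instead).
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    theta = np.asarray(theta, dtype=float)
    if theta.ndim == 1:
        theta = theta[:, None]
    x = np.asarray(x, dtype=float).ravel()
    n = x.size
    if theta.shape[0] != n:
        raise ValueError("phase/amplitude trial counts disagree")
    if n < 4:
        raise ValueError("need at least 4 trials")
    xs, xsd = _standardize(x[:, None])
    if np.ravel(xsd)[0] == 0:
        warnings.warn("constant amplitude: surrogate null degenerate",
                      RuntimeWarning, stacklevel=2)
        return np.full((n_perm, theta.shape[1]), np.nan).squeeze()
    rng = np.random.default_rng(seed)
    idx = _shuffle_matrix(n, n_perm, rng, include_identity)
    xp = xs.ravel()[idx]  # (n_perm, n), still standardized
    r = _circ_lin_map(theta, xp)
    with np.errstate(divide="ignore"):
        z = np.arctanh(np.clip(r, 0.0, 1.0 - 1e-15))
    return z.squeeze()


def fdr_bh(pvals: np.ndarray, q: float = 0.05):
    """Benjamini–Hochberg step-up: returns (reject mask, p cutoff).

    The cutoff is the largest p_(k) <= k q / m; everything at or below it is
    rejected.  Empty input gives an empty mask and cutoff 0.
    """
    p = np.asarray(pvals, dtype=float).ravel()
    if p.size == 0:
        return np.zeros(0, dtype=bool), 0.0
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    reject = multipletests(p, alpha=q, method="fdr_bh")[0]
    cutoff = float(p[reject].max()) if reject.any() else 0.0
    return reject.reshape(np.shape(pvals)), cutoff


# ----------------------------------------------------------------------
# group inference


@dataclass
class PhaseCorrResult:
    """Group-level circular–linear coupling map with its surrogate inference."""

    mean_z: np.ndarray  # (n_channels, n_times) group mean Fisher z
    p: np.ndarray  # surrogate p per cell
    mask: np.ndarray  # BH-FDR rejection mask
    times: np.ndarray  # s relative to the segmentation point
    ch_names: tuple[str, ...]
    q: float
    fdr_cutoff: float
    n_perm: int
    seed: int | None
    n_participants: int
    peak_channel: str | None = None
    peak_time: float | None = None
    mean_z_peak: float = np.nan
    mean_z_mask: float = np.nan  # mean z over all significant cells
    participant_z_peak: np.ndarray | None = None  # per-participant z at peak
    preferred_phase_peak: float = np.nan  # φ̂0 at the peak cell
    preferred_phase_segpoint: float = np.nan  # φ̂0 at (peak channel, t = 0)

    @property
    def n_significant(self) -> int:
        return int(self.mask.sum())


def group_phase_amplitude_test(
    phase_maps: list[PhaseMap],
    amplitudes: list[np.ndarray],
    window: tuple[float, float] = (-0.5, 0.0),
    n_perm: int = 10_000,
    q: float = 0.05,
    seed: int | None = 0,
) -> PhaseCorrResult:
    """Group-level phase–amplitude coupling test with FDR control.

    Per participant and cell, Fisher z of the circular–linear correlation
    between phase and amplitude across trials; the group statistic is the
    across-participant mean z.  The null averages, per permutation, one
    independent amplitude shuffle per participant; p = (1 + #{null >=
    observed}) / (1 + n_perm), one-sided because r >= 0.  BH-FDR runs over
    all (channel, sample) cells in ``window``.  Participants with fewer than
    4 trials are dropped with a warning.
    """
    if len(phase_maps) != len(amplitudes):
        raise ValueError("need one amplitude vector per phase map")
    keep = []
    for pm, amp in zip(phase_maps, amplitudes):
        if pm.data.shape[0] != len(amp):
            raise ValueError("phase map and amplitude trial counts disagree")
        if len(amp) < 4:
            warnings.warn("participant with < 4 trials dropped", RuntimeWarning,
                          stacklevel=2)
            continue
        keep.append((pm, np.asarray(amp, dtype=float)))
    if not keep:
        raise ValueError("no participant has enough trials")
    ref = keep[0][0]
    names = tuple(ref.ch_names)
    times = ref.times
    sel = (times >= window[0]) & (times <= window[1])
    if not sel.any():
        raise ValueError("window outside the phase-map time axis")
    wtimes = times[sel]
    n_ch = len(names)
    n_t = int(sel.sum())
    m = n_ch * n_t

    master = np.random.SeedSequence(seed if seed is not None else None)
    sub = master.spawn(len(keep))

    obs_sum = np.zeros(m)
    null_sum = np.zeros((n_perm, m))
    part_theta = []  # per participant (theta window, amp) for phase estimation
    for (pm, amp), ss in zip(keep, sub):
        if tuple(pm.ch_names) != names or pm.data.shape[2] != ref.data.shape[2]:
            raise ValueError("inconsistent layouts across participants")
        theta = pm.data[:, :, sel].reshape(pm.data.shape[0], m)
        part_theta.append((theta, amp))
        xs, xsd = _standardize(amp[:, None])
        if np.ravel(xsd)[0] == 0:
            warnings.warn("participant with constant amplitude dropped",
                          RuntimeWarning, stacklevel=2)
            continue
        r_obs = _circ_lin_map(theta, xs.T)[0]
        obs_sum += np.arctanh(np.clip(np.nan_to_num(r_obs), 0, 1 - 1e-15))
        rng = np.random.default_rng(ss)
        idx = _shuffle_matrix(len(amp), n_perm, rng, include_identity=False)
        r_null = _circ_lin_map(theta, xs.ravel()[idx])
        null_sum += np.arctanh(np.clip(np.nan_to_num(r_null), 0, 1 - 1e-15))

    n_part = len(keep)
    obs = obs_sum / n_part
    null = null_sum / n_part
    p = (1 + (null >= obs[None, :]).sum(axis=0)) / (1 + n_perm)

    mask_flat, cutoff = fdr_bh(p, q)
    mean_z = obs.reshape(n_ch, n_t)
    p_map = p.reshape(n_ch, n_t)
    mask = mask_flat.reshape(n_ch, n_t)

    result = PhaseCorrResult(
        mean_z=mean_z,
        p=p_map,
        mask=mask,
        times=wtimes,
        ch_names=names,
        q=q,
        fdr_cutoff=cutoff,
        n_perm=n_perm,
        seed=seed,
        n_participants=n_part,
    )
    if mask.any():
        masked = np.where(mask, mean_z, -np.inf)
        ch, ti = np.unravel_index(np.argmax(masked), masked.shape)
        result.peak_channel = names[ch]
        result.peak_time = float(wtimes[ti])
        result.mean_z_peak = float(mean_z[ch, ti])
        result.mean_z_mask = float(mean_z[mask].mean())
        cell = ch * n_t + ti
        # preferred phase at the peak cell and at the segmentation point
        # (t = 0 sample of the peak channel), circular mean across participants
        t0 = int(np.argmin(np.abs(wtimes - 0.0)))
        cell0 = ch * n_t + t0
        phis_peak, phis_seg, zs = [], [], []
        for theta, amp in part_theta:
            phis_peak.append(estimate_preferred_phase(theta[:, cell], amp))
            phis_seg.append(estimate_preferred_phase(theta[:, cell0], amp))
            zs.append(fisher_z(circ_lin_corr(theta[:, cell], amp)))
        result.preferred_phase_peak = circular_mean(np.array(phis_peak))
        result.preferred_phase_segpoint = circular_mean(np.array(phis_seg))
        result.participant_z_peak = np.array(zs)
    return result
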