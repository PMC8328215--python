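# Methods

## The model the simulator implements

The generator emulates an EEG study of auditory sentence segmentation under
a 2 × 2 design: speech RATE (FAST/SLOW) crossed with an acoustic BOUNDARY
cue (PRESENT/ABSENT).  Its central object is a delta-band oscillation whose
phase at the sentence-internal *segmentation point* (the moment a multiword
segment can be closed or continued) is hypothesized to gate segmentation,
and thereby to predict the single-trial amplitude of a P600-like positivity
at the later disambiguating verb.

Per trial, the noiseless signal at channel c is

    s_c(t) = A_δ · w_δ(c) · g(t) · cos(2π f_δ (t − t_seg) + φ)
           + A · w_p(c) · h_p(t − t_verb − ℓ_p)
           + N · 1[FAST] · w_n(c) · h_n(t − t_verb − ℓ_n)

with

* `f_δ` = 0.37 Hz (one cycle = 2.7 s, the segmentation window the design
  manipulates), trial phase φ ~ Uniform(−π, π] at `t_seg`;
* evoked amplitude `A = β₀ + β_rate·1[FAST] + κ·cos(φ − φ₀) + ε`,
  ε ~ N(0, σ_A²) — the cosine term is the mechanism under study;
* `h_p`, `h_n` Hann bumps (latencies ℓ_p = 0.456 s, ℓ_n = 0.856 s after
  verb onset); only amplitude, latency and topography matter to the
  downstream statistics, so no biophysical kernel is used.  The positivity
  width is 0.12 s — its half-height extent (~60 ms) matches the narrow
  group-level effect the design targets — and the negativity 0.3 s;
* `N` the FAST-only negativity amplitude (−3 µV): the negativity appears in
  the FAST−SLOW contrast like the positivity but its single-trial amplitude
  is *independent of φ* — the selectivity control;
* `w` maps: Gaussians on the 2-D sensor layout (sunflower spiral on the unit
  disc; channel E00 at the centre).

Noise is 1/f^α per channel (α = 1) plus white sensor noise.  Defaults:
delta amplitude 12 µV, pink noise 5 µV, white noise 1 µV, amplitude jitter
1 µV, β₀ = 5 µV, β_rate = 3 µV, κ = 4 µV, φ₀ = π/4.  These were chosen as a
realistic-but-recoverable operating point: the delta-band amplitude SNR is
≈ 2, and single-trial amplitude noise at one sample is ≈ 5 µV, placing the
per-participant circular–linear correlation near r ≈ 0.3 at κ = 4 µV.

Event times (relative to sentence onset): SLOW — segmentation point at
2.7 s, verb at 3.7 s; FAST — the same design compressed by the rate ratio
0.66 (segmentation 1.782 s, verb 2.442 s, i.e. before the 2.7-s mark).
Envelope pauses for BOUNDARY=PRESENT average 342 ms (SLOW) and 214 ms
(FAST), jittered per trial with the stimulus-set spreads (43/25 ms).

### Deliberate departures from naive realism

* **The delta component is a burst, not a trial-long sinusoid.**  It ramps
  up (raised cosine, 0.3 s) before sentence onset, holds a plateau through
  the segmentation point + 0.2 s, and is gone by +0.5 s.  A trial-long
  oscillation would make the verb-epoch voltage a deterministic function of
  the segmentation-point phase, so phase would "predict" amplitude even at
  κ = 0 and no null condition would exist.  The phase-estimation window
  (−0.5..0 s) lies entirely inside the plateau; the energy-conservation
  property (analytic amplitude = A_δ·w_δ(c)) holds there.
* **The pink-noise spectrum flattens below 0.05 Hz**, mimicking the drift
  cutoff of any real acquisition chain; the 1/f^α law holds from ~0.1 Hz to
  a quarter of the sampling rate.  Without this floor, near-DC noise power
  dominates the delta band and no phase estimate is informative.
* **Topography width σ = 0.25** on the unit disc (≈ one inter-sensor
  distance at 12 channels).  The sampling noise of a per-channel t value
  has sd(log t) ≈ 1/√(2(n−1)) ≈ 0.3 at n = 12 participants; a peak
  electrode is identifiable only if the log-weight gap to its neighbours
  exceeds that, which fixes how focal the simulated maps must be.
* **No re-referencing by default.**  The generator emits reference-free
  potentials (the idealization that infinity-reference schemes such as REST
  approximate).  Applying the common-average operator would force every map
  to zero spatial mean, giving the focal negativity a diffuse counter-polar
  *positive* lobe whose cluster mass can exceed the true positivity's — an
  artifact of the reference, not of the physiology being modelled.  The
  operator is implemented, tested, and switchable (`PrepConfig.rereference`).
* Per-trial delta phase is drawn uniformly with no reset at sentence onset,
  which makes the trial-shuffle surrogate exactly exchangeable; an optional
  `phase_reset_at_onset` mode exists for realism experiments and is *not*
  used by any test.

### What the synthetic data does not capture

No volume conduction or forward head model (channels share signal only
through the weight maps; noise is spatially white), no artifacts (blinks,
muscle), no trial-to-trial latency jitter of the evoked components, no
oscillatory non-stationarity beyond the burst envelope, and no acoustics —
the "pitch envelope" is a syllable-rate raised-cosine proxy.  Passing tests
therefore demonstrate that the *estimators and their inference are correct
and calibrated under the model's assumptions*, not that the scientific
effect exists in real EEG.

## Estimators and inference

**Filtering** is two-pass (forward–backward) Butterworth in
second-order-sections form; `order` is the single-pass design order, so the
effective gain at the cutoff is 0.5 and the net phase shift is zero.
Filtering always precedes cropping: the wide ±3 s segmentation epochs exist
to keep low-frequency edge ringing away from the −0.5..0 s analysis window.

**Epoching** uses a half-open [tmin, tmax) convention at sample resolution
(a −0.5..1.5 s epoch at 100 Hz has exactly 200 samples); events are stored
in seconds and rounded to the nearest sample at use, so they survive
resampling exactly.

**Instantaneous phase** is the angle of the FFT analytic signal, cosine
convention (0 rad at a cosine peak).  For oscillations as slow as 0.37 Hz a
6-s window holds ~2.2 cycles and the FFT's periodic continuation leaks up
to ~0.25 rad of phase error well inside the epoch.  `hilbert_phase`
therefore extends every trial/channel by linear prediction (order-8 AR fit,
least squares with a minimum-norm solution, poles reflected into the unit
circle, one epoch length each side) before the transform; the measured
worst-case interior error at 0.37 Hz is 0.019 rad, and integer-cycle
frequencies are exact.  `edge="none"` restores the plain transform.

**Cluster inference**: paired t-maps (df = n−1), cluster-forming threshold
t_{0.975, n−1}, clusters connected via (same channel, adjacent samples) or
(same sample, neighbouring channels — Delaunay triangulation by default),
clusters with < 3 distinct channels discarded, cluster mass = sum of member
t values.  The null records, per sign-flip permutation, the per-sign
maximum mass; p = (1 + #{null ≥ observed}) / (1 + n_perm), doubled and
capped at 1 for two-sided control.  Sign flips change only the mean of the
difference maps, never their sum of squares, so the whole permutation stack
reduces to one matrix product.  An exhaustive mode enumerates all 2^n sign
patterns (n ≤ 16) and is the exactness oracle for the Monte-Carlo path.

**Phase–amplitude coupling**: per participant and (channel, sample) cell,
circular–linear r between phase and the single-trial amplitude at the ERP
peak (baseline-corrected voltage at the single peak sample; a window mean
is optional).  Group statistic: across-participant mean Fisher z.  Null:
per permutation, one amplitude shuffle per participant (the same shuffle
across all cells, preserving the spatial/temporal dependence of the null),
averaged across participants; one-sided p with the plus-one rule (r ≥ 0 by
construction).  BH-FDR runs over all cells in the −0.5..0 s window.  The
preferred phase comes in closed form from regressing x on (cos θ, sin θ).
Because r is rotation-invariant, the preferred phase at a cell at time t
equals φ₀ + 2π f_δ t; the result therefore reports it both at the peak cell
and at the t = 0 sample of the peak channel, the latter being the quantity
the hypothesis is stated about.

**Coherence**: pooled-trial magnitude-squared coherence with a single Hann
taper per demeaned 3-s segment (Δf ≈ 0.33 Hz, ~12 bins below 4 Hz), DC bin
excluded from the band average (the envelope is positive, so DC would
dominate), no small-sample bias correction (trial counts are balanced by
design).  The FAST/SLOW comparison uses the Wilcoxon signed-rank test:
z = (W⁺ − μ_W)/σ_W with tie-corrected variance; the p-value is the exact
enumeration (dynamic programming over sign patterns, valid with mid-ranks)
for n ≤ 25 and the normal approximation above.

## Degenerate inputs and tie-breaks

Zero-variance t-map cells are flagged (±inf or 0) and excluded from cluster
formation with a warning.  Constant amplitudes or collapsed phase
distributions make r undefined: NaN with a warning, and such participants
are dropped from the group test (< 4 trials likewise).  Peak extraction
breaks |t| ties on the lowest channel index, then the earliest sample; when
no cluster of the requested sign is significant it returns an explicit
no-peak outcome and the pipeline stops with status `no_positive_cluster`
unless a forced peak is configured.  Monte-Carlo p-values can never be 0
(plus-one rule).

## Problem sizes used by the test suite

All statistical tests run on scaled-down study conditions, chosen once:

* Null calibration: 200 datasets, 8 participants, 20 trials/cell,
  12 channels, 100 Hz, 500 permutations for both the cluster and the
  surrogate null.  With 500 permutations the smallest attainable surrogate
  p is 1/501, which makes BH-FDR over the 612-cell family conservative —
  the any-cell discovery criterion is a one-sided bound.
* Mechanism recovery and selectivity: 20 datasets, 12 participants,
  60 trials/cell, 12 channels, κ = 4 µV, φ₀ = π/4, 500 permutations.
* Dose–response: κ ∈ {0, 1, 2, 4} µV, 20 seeds per level, 8 participants,
  30 trials/cell, 8 channels; the group mean z at the true coupling cell is
  a point estimate, so no permutations are needed.
* Coherence control: 20 datasets, 8 participants, 15 trials/cell.

The full-scale profile (10 000 permutations, more channels/participants) is
reachable through the same configuration objects; nothing in the code is
specific to the reduced sizes.

## Known limitations

The AR edge extension assumes the signal is locally well modelled by a
low-order autoregression; for broadband unfiltered inputs it degrades
gracefully toward the plain transform but is not exact.  The group-level
aggregation (mean Fisher z with a matched permutation null) is one of
several defensible choices; per-participant FDR-then-count is not
implemented.  The exhaustive Wilcoxon p is conditional on the observed
|differences| (standard for rank tests).  Cluster p-values are Monte-Carlo
estimates; agreement with the exhaustive oracle is ±0.02 at 10 000
permutations.  The simulator's conditions are balanced by construction;
unbalanced designs would need coherence bias correction and a different
permutation scheme.
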