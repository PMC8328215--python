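# deltaseg

Does the phase of a slow (delta-band, < 4 Hz) EEG oscillation at the moment a
listener can close a multiword segment predict how strongly their brain
reacts when that segmentation later turns out to be wrong?  `deltaseg`
re-implements, as a tested Python pipeline, the inference chain behind that
question: from multi-channel epoched EEG to a single-trial link between
**upstream oscillatory phase** and **downstream P600-like ERP amplitude** —
exercised end-to-end on synthetic phase-coupled EEG with known ground truth.

The package is aimed at EEG methodologists who want a compact, fully seeded
reference implementation of this analysis style: spatio-temporal
cluster-based permutation statistics, circular–linear phase–amplitude
correlation with a trial-shuffled surrogate null and FDR control, and an
envelope-coherence prosody control.

## The analysis chain

1. **Simulation** (`deltaseg.simulate`).  Each trial of a two-rate
   (FAST/SLOW) × boundary (PRESENT/ABSENT) listening design carries a
   delta-band burst (default 0.37 Hz; one cycle ≈ 2.7 s) with uniform random
   phase φ at the segmentation point, an evoked positivity ~0.456 s after the
   disambiguating-verb onset with single-trial amplitude

       A = β₀ + β_rate·1[FAST] + κ·cos(φ − φ₀) + ε,

   an *uncoupled* later negativity, 1/f background noise, and a prosodic
   envelope proxy with an optional boundary pause.
2. **Preprocessing** (`deltaseg.prep`).  Zero-phase Butterworth filtering,
   polyphase resampling to 100 Hz, epoching (verb-locked −0.5..1.5 s; wide
   −3..3 s around the segmentation point), 0–150 ms post-onset baseline.
3. **ERP statistics** (`deltaseg.erp`).  FAST−SLOW paired t-maps in the
   0.15–1 s window; clusters over the channel×time lattice (≥ 3 channels);
   sign-flip permutation null on the per-sign maximum cluster mass; the
   positive cluster's max-|t| cell defines the amplitude mask.
4. **Phase coupling** (`deltaseg.phase`).  Hilbert phase of the 4-Hz
   low-passed signal; per cell in −0.5..0 s before the segmentation point,
   the circular–linear correlation

       r = √[(r²_cx + r²_sx − 2 r_cx r_sx r_cs) / (1 − r²_cs)]
         = max_φ |corr(x, cos(θ − φ))|,

   Fisher-z transformed, averaged across participants, tested against a
   trial-reassignment surrogate null and Benjamini–Hochberg FDR; the
   maximizing φ is the preferred phase.
5. **Coherence control** (`deltaseg.coherence`).  Across-trial
   magnitude-squared coherence between the stimulus envelope and the
   delta-band EEG at the peak electrode (0–4 Hz, ±1.5 s), band-averaged and
   compared FAST vs SLOW with a Wilcoxon signed-rank test.

## Worked example

The numbered scripts under `analysis/` run the demo study (8 participants,
40 trials per condition cell, 16 channels, κ = 4 µV, φ₀ = π/4 ≈ 0.785 rad)
and write their tables to `results/`:

```bash
python analysis/01_simulate.py
python analysis/02_preprocess.py
python analysis/03_erp_clusters.py
python analysis/04_phase_coupling.py
python analysis/05_coherence_control.py
```

Output of the last three (seed 7):

```
positivity peaks at E00, 0.450 s (t = 11.6) — the amplitude mask for the phase stage
negativity peaks at E01, 0.890 s (t = -14.3)

positivity amplitude mask at E00, 0.450 s
  253 FDR-significant cells (q = 0.05); peak E00 at -0.5 s, mean Fisher z there 0.430,
  over the mask 0.288
  preferred phase at the segmentation point: 0.788 rad (simulated: 0.785)
selectivity: negativity amplitudes at E01, 0.890 s give 0 significant cells
  (uncoupled by construction; 0 expected)

band-averaged coherence at E00, centred -0.500 s:
  FAST 0.010, SLOW 0.010
  Wilcoxon z = 0.000, p = 1.000 -> no significant difference between rate conditions
```

Reading this: the ERP stage finds the simulated positivity at the right
electrode and latency; the phase stage finds a large set of
(channel, sample) cells before the segmentation point whose delta phase
predicts the single-trial positivity amplitude (group mean Fisher z ≈ 0.29
over the mask) and recovers the preferred phase to within ~0.003 rad; the
uncoupled negativity shows no such coupling; and envelope coherence does not
differ between rates, so prosody tracking does not explain the effect.

The same chain is available as one command
(`deltaseg all --config analysis/config.yaml --out <dir> --seed 7`) or as a
library call (`deltaseg.pipeline.run_all`).

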