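# Methods

`ecgpipe` implements the complete analysis chain of a remote screening
platform for single-lead, home-device ECG: signal adequation, beat
detection, rhythm and morphology analysis. This note records the models,
the parameters that matter, and the design choices made where the design
was genuinely open.

## Signal model and units

The input is a single-channel voltage series in millivolts with a
caller-supplied sampling rate. Hand-electrode front-ends of the targeted
device class superimpose a DC level of the order of 16 mV on a ~1 mV QRS,
plus four noise classes: baseline wander below 0.5 Hz (respiration,
electrode impedance, body movement), 50 Hz mains interference (Spanish
powerline), EMG noise from roughly 20 Hz upward, and *large-amplitude
noise* — transient saturation or signal loss from electrode slips and
tremor. The sampling rate is nowhere implied by the data files; 250 Hz is
the documented default for synthetic data, and every algorithm parameter
is expressed in seconds or fractions so the chain is rate-independent.

## Signal adequation

Four stages in fixed order, each length-preserving:

1. **75 Hz low-pass** — 4th-order Butterworth applied forward-backward
   (zero phase). The filter realization is this package's choice; the
   conservative cut-off preserves QRS morphology while trimming
   high-frequency EMG. Zero-phase application avoids the phase lag that
   would distort the very morphology the chain is meant to preserve.
2. **Baseline removal** — cubic spline through knots placed at the centre
   of consecutive segments with ordinate equal to the segment mean, then
   subtracted. Knot segment length defaults to 1.0 s (configurable): long
   relative to one beat, so knots track sub-0.5 Hz drift and the DC
   offset rather than QRS energy. Records shorter than four knots fall
   back to mean subtraction (logged).
3. **50 Hz notch** — IIR notch of quality factor 30, zero-phase. Measured
   attenuation at the line frequency far exceeds 30 dB; the 5 Hz passband
   is preserved within 2%.
4. **Large-amplitude-noise (LAN) excision** — the signal is cut into
   0.5 s blocks; each block's standard deviation is compared with the
   mean + 2·std of the ten *previous* block deviations (strictly causal
   window, a deliberate reading of the otherwise ambiguous history
   definition). Flagged blocks are *masked*, never zero-filled:
   zero-filling creates step edges whose derivative mimics a QRS. The
   first ten blocks have no full history and are never flagged; the
   strict inequality means an all-tied history (constant signal, all
   deviations equal) flags nothing.

## Beat detection

A tailored Pan-Tompkins-family detector in three stages:

1. **Feature signal** — the anti-symmetric FIR
   `y[n] = (−2x[n−2] − x[n−1] + x[n+1] + 2x[n+2]) / 10`, squared. The
   kernel sums to zero (DC rejection) and squaring makes the feature
   identical for sign-inverted ECG, which matters for
   ventricular-extrasystole-like beats. The two-sample non-causal advance
   is compensated so the feature aligns with the input time base
   (offline analysis permits zero delay); the first and last two samples
   are set to zero.
2. **Zone selection** — threshold at mean + c·std of the feature over
   valid samples (c defaults to 1.0, exposed in config). Because the
   derivative crosses zero exactly at the R apex, one QRS produces two
   super-threshold runs; runs separated by less than 0.05 s (the
   `zone_merge_gap_s` default, about half a QRS width) are merged so one
   zone spans each complex and the apex itself lies inside the zone.
   Zones touching LAN-masked samples are discarded entirely.
3. **Refinement and refractory filtering** — the exact position is the
   sample of maximum |amplitude| within the zone (absolute value handles
   inverted complexes); candidates closer than the 0.2 s refractory
   default (physiological ventricular refractory, configurable) keep the
   one with the larger feature value.

The detector is scale-equivariant (threshold and feature scale together)
and position-invariant under sign inversion.

## Rhythm analysis

From the detected R positions, `RR[n]` is the interval ending at beat
n+1 and `dRR[n] = RR[n] − RR[n−1]`. Intervals spanning masked gaps are
flagged invalid and excluded from statistics.

* **Warnings** — a *rhythm alteration* is an interval differing from its
  predecessor by strictly more than 30%; a *pause* is an interval
  strictly longer than 3 s.
* **Outlier fencing** — an interval is an outlier when RR or dRR falls
  strictly outside [P25 − 3·IQR, P75 + 3·IQR] on its axis. The published
  formula joins two ">" conditions with a logical AND, which collapses
  to the upper fence alone; this package implements the standard
  two-sided fence and keeps the literal upper-fence-only variant behind
  `fence_literal_rule` for comparison. Fence boundaries are inclusive
  (a value on the fence is not an outlier), which also resolves the
  IQR = 0 degenerate case: an all-identical series flags nothing.
* **Poincaré discretization** — points (RR[n], dRR[n]) for non-outlier
  n ≥ 1 are histogrammed on a fixed grid, 30×30 bins over
  RR ∈ [0.24, 2.0] s and dRR ∈ [−0.88, 0.88] s. Fixed physiologic ranges
  (not auto-scaling) keep the index comparable across segments — an
  auto-scaled grid would let a constant rhythm spuriously fill its
  bins. Points outside a range are clipped into the edge bin so every
  point lands in exactly one bin.
* **Disorganization index** — the fraction of grid bins whose count
  reaches `af_full_bin_min_count` (default 1, i.e. occupied). AF's
  irregularly irregular RR series disperses the cloud and inflates the
  index.
* **AF segmentation** — consecutive non-overlapping 75 s segments; a
  segment is AF-suspect when its index exceeds `af_threshold`. The
  default threshold 0.0483 was derived once by
  `scripts/calibrate_af_threshold.py`: Youden's J over 200 sinus + 200
  AF-like synthetic segments (full separation; the cut sits midway
  between the highest sinus and lowest AF index). A record shorter than
  one segment is analyzed best-effort; a trailing partial segment is
  ignored.
* **HRV indices** — mean heart rate 60/mean(RR); SDNN as the population
  standard deviation; max−min RR; triangular index N / (tallest RR
  histogram bin) with the conventional 1/128 s bin width.

## Beat template

Cycle length is the global mean RR (a single length lets all windows be
averaged sample-wise). Each beat is windowed 40% of the cycle before the
R wave and 60% after, hard-cropped (windows leaving the record or
touching masked samples are dropped, never padded). A central window of
10% of the cycle isolates the QRS segment; each segment's Pearson
correlation against the pointwise-median segment (robust to a minority of
ectopic or corrupt beats; a pairwise-mean-correlation mode is available)
gates admission at > 99.5%. Accepted windows are averaged pointwise; for
N beats with uncorrelated noise of deviation σ the residual template
noise is σ/√N. If fewer than two beats pass the gate, the single
best-correlated window is returned with a warning.

## Synthetic data generator

The generator defines the study conditions for all tests. Morphology is
the standard sum-of-Gaussians beat (P, Q, R, S, T waves at fixed offsets
−0.20, −0.03, 0, +0.03, +0.30 s from R with amplitudes 0.15, −0.10, 1.00,
−0.25, 0.35 mV), rendered at beat times snapped to the sampling grid so
each R apex lies exactly on a sample. Rhythms: sinus (RR Gaussian around
60/HR with 0.05 s jitter — a realistic short-term SDNN — truncated at
0.3 s), AF-like (RR i.i.d. uniform on [0.4, 1.0] s), a deterministic
short/long bigeminy-like alternation, and sinus with one injected pause.
Noise defaults model a usable home recording: 0.3 mV drift at 0.3 Hz,
0.05 mV mains, 0.02 mV EMG (high-passed white noise above 20 Hz), no
bursts unless requested, 16 mV DC. Burst blocks are aligned to the LAN
0.5 s grid and placed beyond its warm-up so every generated burst is
scoreable. A single seed determines the output bit-exactly.

What the generator does *not* emulate: true AF dynamics (the i.i.d.
uniform model maximizes Poincaré dispersion by construction), ectopic
morphology changes, electrode pop transients, respiration-coupled
amplitude modulation, or sub-sample beat phase. Passing tests therefore
demonstrate the mechanics of the chain under controlled conditions, not
clinical performance: the published detector figures on Holter data
(95.3% sensitivity / 88.8% specificity for AF) come from a private
clinical database and cannot be reproduced here.

## Problem sizes and numerical choices

The test suite and the acceptance script use 120 s records at 250 Hz,
100–200 records per detector benchmark, 200+200 75 s segments for the AF
contrast, and 100 simulations for template statistics — sizes at which
every Monte-Carlo bound in the suite is stable across seeds. Filter
attenuation is measured in steady state (12 s sinusoids, 4 s edge margins)
because the Q=30 notch rings for more than a second. Percentiles use
linear interpolation; correlation of a zero-variance segment against a
zero-variance reference is defined as 1 when they are equal, else 0.

## Known limitations

* Beat classification (normal vs ectopic), wave delineation, and
  frequency-domain or non-linear HRV are out of scope.
* The AF threshold is calibrated on the synthetic suite only; on real
  data it must be re-calibrated against annotated rhythms.
* The LAN filter's causal history means a noise level that rises slowly
  over many blocks can escape flagging.
* Analysis treats all three electrode modes as the same single channel;
  no multi-lead fusion.
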