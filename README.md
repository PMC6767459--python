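# ecgpipe

Analysis chain for single-lead ECG recorded by hand-electrode home
devices: denoising, QRS detection, rhythm warnings, atrial-fibrillation
screening, and low-noise beat templates — plus a synthetic ECG generator
so the whole chain runs and is tested without any recorded data.

It is written for engineers and researchers building remote
cardiac-screening pipelines: recordings made by elderly users on portable
two-electrode devices carry a large DC offset, baseline wander, mains
interference, EMG noise and transient saturation artifacts, and still
have to yield reliable beat positions, arrhythmia warnings and a clean
representative beat for visual inspection.

## What it computes

* **Signal adequation** — 75 Hz zero-phase low-pass; baseline removal by
  a cubic spline through segment-mean knots; 50 Hz notch; block-wise
  *large-amplitude-noise* excision (0.5 s blocks whose standard deviation
  exceeds mean + 2·std of the ten previous block deviations are masked).
* **Beat detection** — a tailored Pan-Tompkins-family detector: the
  derivative feature `y[n] = ((−2x[n−2] − x[n−1] + x[n+1] + 2x[n+2])/10)²`,
  zone selection at mean + c·std, exact-position search by maximum
  |amplitude|, and a 0.2 s refractory filter.
* **Rhythm analysis** — RR-interval warnings (alteration when an interval
  differs >30% from its predecessor; pause when RR > 3 s); RR/dRR outlier
  fencing at [P25 − 3·IQR, P75 + 3·IQR]; a discretized Lorenz–Poincaré
  diagram whose *disorganization index* (fraction of occupied bins)
  screens consecutive 75 s segments for AF; time-domain HRV (mean HR,
  SDNN, RR range, triangular index).
* **Beat template** — beats windowed 40%/60% of the mean cycle around R;
  only beats whose central QRS segment correlates >99.5% with the
  reference contribute to the pointwise average.
* **Synthetic generator** — sum-of-Gaussians P-QRS-T morphology, sinus /
  AF-like / bigeminy-like / pause rhythms, and the device noise classes
  (drift, 50 Hz, EMG, bursts, 16 mV DC), fully seeded.

## Worked example

```python
import numpy as np
from ecgpipe import SynthSpec, analyze, generate

record, truth = generate(SynthSpec(duration_s=160, rhythm="af", seed=3))
result = analyze(record)

print("beats:", result.report.n_beats)
for seg in result.report.af_segments:
    print(f"{seg['start_s']:.0f}-{seg['end_s']:.0f} s: "
          f"disorganization {seg['disorganization']:.4f} -> "
          f"{'AF suspected' if seg['af'] else 'non-AF'}")
```

prints

```
beats: 222
0-75 s: disorganization 0.0722 -> AF suspected
75-150 s: disorganization 0.0722 -> AF suspected
```

The irregular RR series of the AF-like rhythm scatters the (RR, dRR)
Poincaré points over ~7% of the fixed 30×30 grid, well above the
calibrated decision threshold (0.0483); a sinus recording of the same
length stays near 2%. The `examples/` directory has one short script per
capability (detection accuracy, the filter bench, AF screening, rhythm
warnings, templates).

The same chain is available from the shell:

```
ecgpipe simulate --rhythm af --duration 160 --seed 3 --out rec.csv
ecgpipe analyze rec.csv --fs 250 --out results/
ecgpipe report results/report.json
```

`analyze` reads the device CSV format (one voltage per row, millivolts),
writes JSON/text reports plus the beat template, and surfaces warnings on
stdout.

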