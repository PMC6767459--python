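"""Watch the four-filter bench clean a raw device signal.

Shows the DC level, sub-0.5 Hz drift energy and 50 Hz mains energy before
and after the chain (75 Hz low-pass, spline baseline removal, 50 Hz notch,
large-amplitude-noise excision).
"""

import numpy as np

from ecgpipe import SynthSpec, generate, preprocess

record, _ = generate(
    SynthSpec(duration_s=60, drift_amp_mV=0.4, powerline_amp_mV=0.3,
              dc_offset_mV=16.0, burst_rate_per_min=1.0, seed=2)
)
filtered = preprocess(record)


def band_energy(x, fs, lo, hi):
    f = np.fft.rfftfreq(x.size, 1 / fs)
    spec = np.abs(np.fft.rfft(x - x.mean())) ** 2
    return spec[(f >= lo) & (f <= hi)].sum()


print(f"stages applied:         {filtered.stages_applied}")
print(f"DC level     raw/clean: {record.samples.mean():8.3f} / "
      f"{filtered.samples.mean():8.4f} mV")
print(f"drift energy raw/clean: {band_energy(record.samples, record.fs, 0.01, 0.5):8.1f} / "
      f"{band_energy(filtered.samples, record.fs, 0.01, 0.5):8.3f} (mV^2, <0.5 Hz)")
print(f"mains energy raw/clean: {band_energy(record.samples, record.fs, 49.5, 50.5):8.1f} / "
      f"{band_energy(filtered.samples, record.fs, 49.5, 50.5):8.3f} (mV^2, 50 Hz)")
print(f"samples masked as large-amplitude noise: {(~filtered.valid_mask).sum()}")
print()
print("The ~16 mV front-end offset collapses to near zero, drift and the")
print("mains line lose most of their energy, and noise-burst blocks are")
print("excised (masked) rather than filtered.")
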