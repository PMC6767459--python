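"""Build a low-noise averaged beat template from a noisy recording.

Beats are windowed 40%/60% of the mean cycle around each R wave; only
beats whose central QRS segment correlates above 99.5% with the reference
contribute; their pointwise mean is a clean cycle for visual morphology
inspection.
"""

import numpy as np

from ecgpipe import SynthSpec, analyze, clean_beat_waveform, generate

record, _ = generate(SynthSpec(duration_s=60, emg_amp_mV=0.06, seed=21))
result = analyze(record)
tpl = result.template

ref = clean_beat_waveform(record.fs, tpl.waveform.size / record.fs)
m = min(tpl.waveform.size, ref.size)
corr = np.corrcoef(tpl.waveform[:m], ref[:m])[0, 1]

print(f"beats detected:        {result.annotations.n_beats}")
print(f"beats contributing:    {tpl.n_contributing}")
print(f"gate minimum corr.:    {tpl.min_corr:.4f}")
print(f"template length:       {tpl.waveform.size} samples "
      f"(R wave at sample {tpl.r_offset})")
print(f"corr. with true beat:  {corr:.4f}")
print()
print("Averaging N correlated beats shrinks uncorrelated noise by sqrt(N),")
print("so the template tracks the generator's noise-free cycle almost exactly.")
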