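"""Raise rhythm warnings on a recording with an injected pause.

A >3 s RR interval triggers a pause warning, and the surrounding sudden
rate change (>30% versus the previous interval) triggers rhythm-alteration
warnings — the flags a remote platform would surface to the clinician.
"""

from ecgpipe import SynthSpec, analyze, generate

record, _ = generate(SynthSpec(duration_s=60, rhythm="pause_injected",
                               pause_rr_s=3.5, seed=12))
report = analyze(record).report

print(f"beats detected: {report.n_beats}")
for i, rr in report.pauses:
    print(f"PAUSE     interval {i}: RR = {rr:.2f} s (> 3 s)")
for i, rr, prev in report.alterations:
    print(f"ALTERATION interval {i}: RR {prev:.2f} -> {rr:.2f} s "
          f"({abs(rr - prev) / prev:.0%} change)")
print()
print("One injected 3.5 s pause produces exactly one pause warning; the")
print("abrupt return to the baseline rate also trips the 30% alteration rule.")
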