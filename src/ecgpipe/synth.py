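"""Synthetic single-lead ECG generator with ground-truth annotations.

Produces device-like recordings so the whole analysis chain is testable
without any recorded data.  Beat morphology is the standard
sum-of-Gaussians construction (one Gaussian per P, Q, R, S, T wave, fixed
offsets relative to R); rhythms cover:

* ``sinus`` — RR ~ Normal(60/HR, hrv_sd), truncated positive;
* ``af`` — RR i.i.d. uniform on [min_rr, max_rr]: serially independent,
  hence a maximally dispersed Poincaré cloud.  This is a deliberate
  simplification adequate for exercising the disorganization index, NOT a
  physiological atrial-fibrillation model;
* ``bigeminy_like`` — deterministic short/long alternation;
* ``pause_injected`` — sinus with one long interval inserted mid-record.

Noise classes emulate a hand-electrode home device: baseline drift
(sub-0.5 Hz sinusoid), 50 Hz powerline, EMG-band noise (high-passed white
noise, 20 Hz up), block-aligned large-amplitude bursts (electrode slips /
amplifier saturation), and a DC offset of ~16 mV as such front-ends
superimpose.  All randomness flows from a single seed; identical specs
give bit-identical records.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy import signal as sps

from .records import ECGRecord

__all__ = ["SynthSpec", "GroundTruth", "generate", "rr_af_sample", "rr_sinus_sample", "clean_beat_waveform"]

# (offset from R [s], width [s], amplitude [mV]) per wave
_WAVES = {
    "P": (-0.20, 0.025, 0.15),
    "Q": (-0.030, 0.010, -0.10),
    "R": (0.0, 0.012, 1.00),
    "S": (0.030, 0.010, -0.25),
    "T": (0.30, 0.050, 0.35),
}

_LAN_BLOCK_S = 0.5
_LAN_HISTORY_BLOCKS = 10


@dataclass
class SynthSpec:
    """Study conditions for one synthetic recording."""

    fs: float = 250.0
    duration_s: float = 120.0
    rhythm: str = "sinus"  # sinus | af | bigeminy_like | pause_injected
    mean_hr_bpm: float = 60.0
    hrv_sd_s: float = 0.05
    af_min_rr_s: float = 0.4
    af_max_rr_s: float = 1.0
    bigeminy_short_rr_s: float = 0.6
    bigeminy_long_rr_s: float = 1.0
    pause_rr_s: float = 3.5
    drift_amp_mV: float = 0.3
    drift_hz: float = 0.3
    powerline_amp_mV: float = 0.05
    powerline_hz: float = 50.0
    emg_amp_mV: float = 0.02
    burst_rate_per_min: float = 0.0
    burst_amp_factor: float = 10.0
    dc_offset_mV: float = 16.0
    seed: int = 0

    def validate(self) -> None:
        if self.fs <= 0 or self.duration_s <= 0:
            raise ValueError("fs and duration_s must be positive")
        if not self.drift_hz < 0.5:
            raise ValueError("baseline drift frequency must be below 0.5 Hz")
        for name in (
            "drift_amp_mV",
            "powerline_amp_mV",
            "emg_amp_mV",
            "burst_rate_per_min",
            "burst_amp_factor",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if self.rhythm not in ("sinus", "af", "bigeminy_like", "pause_injected"):
            raise ValueError(f"unknown rhythm {self.rhythm!r}")
        if self.rhythm in ("sinus", "pause_injected") and 60.0 / self.mean_hr_bpm < 0.25:
            raise ValueError("mean RR below 0.25 s is infeasible")
        if self.rhythm == "af" and not 0 < self.af_min_rr_s < self.af_max_rr_s:
            raise ValueError("require 0 < af_min_rr_s < af_max_rr_s")


@dataclass
class GroundTruth:
    """Construction-time truth for detector/classifier evaluation."""

    r_samples: np.ndarray
    rr_true_s: np.ndarray
    rhythm_labels: list[str] = field(default_factory=list)  # per 75 s segment
    burst_blocks: np.ndarray = field(default_factory=lambda: np.array([], dtype=int))


def rr_sinus_sample(
    spec: SynthSpec, n: int, rng: Optional[np.random.Generator] = None
) -> np.ndarray:
    """Sinus RR: Gaussian around 60/HR, truncated at 0.3 s."""
    rng = rng or np.random.default_rng(spec.seed)
    rr = rng.normal(60.0 / spec.mean_hr_bpm, spec.hrv_sd_s, size=n)
    return np.maximum(rr, 0.3)


def rr_af_sample(
    spec: SynthSpec, n: int, rng: Optional[np.random.Generator] = None
) -> np.ndarray:
    """AF-like RR: i.i.d. uniform on [min_rr, max_rr] (zero autocorrelation)."""
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = rng or np.random.default_rng(spec.seed)
    return rng.uniform(spec.af_min_rr_s, spec.af_max_rr_s, size=n)


def _rr_sequence(spec: SynthSpec, rng: np.random.Generator) -> np.ndarray:
    """Draw enough RR intervals to cover the record duration."""
    mean_rr = {
        "sinus": 60.0 / spec.mean_hr_bpm,
        "pause_injected": 60.0 / spec.mean_hr_bpm,
        "af": 0.5 * (spec.af_min_rr_s + spec.af_max_rr_s),
        "bigeminy_like": 0.5 * (spec.bigeminy_short_rr_s + spec.bigeminy_long_rr_s),
    }[spec.rhythm]
    n = int(np.ceil(spec.duration_s / mean_rr)) + 10
    if spec.rhythm == "af":
        rr = rr_af_sample(spec, n, rng)
    elif spec.rhythm == "bigeminy_like":
        rr = np.tile([spec.bigeminy_long_rr_s, spec.bigeminy_short_rr_s], n // 2 + 1)[:n]
    else:
        rr = rr_sinus_sample(spec, n, rng)
        if spec.rhythm == "pause_injected":
            rr[n // 2] = spec.pause_rr_s
    return rr


def clean_beat_waveform(fs: float, cycle_s: float, pre_frac: float = 0.40) -> np.ndarray:
    """One noise-free cardiac cycle, R wave at ``round(pre_frac*cycle_s*fs)``."""
    pre = int(round(pre_frac * cycle_s * fs))
    post = int(round((1.0 - pre_frac) * cycle_s * fs))
    t = (np.arange(pre + post) - pre) / fs
    w = np.zeros(t.size)
    for offset, width, amp in _WAVES.values():
        w += amp * np.exp(-0.5 * ((t - offset) / width) ** 2)
    return w


def _render_beats(r_times: np.ndarray, n: int, fs: float) -> np.ndarray:
    sig = np.zeros(n)
    span_s = 0.6  # beyond +-0.6 s every wave Gaussian is negligible
    half = int(round(span_s * fs))
    for rt in r_times:
        c = int(round(rt * fs))
        a, b = max(0, c - half), min(n, c + half)
        t = (np.arange(a, b) - rt * fs) / fs
        for offset, width, amp in _WAVES.values():
            sig[a:b] += amp * np.exp(-0.5 * ((t - offset) / width) ** 2)
    return sig


def generate(spec: SynthSpec) -> tuple[ECGRecord, GroundTruth]:
    """Render the recording described by ``spec``.

    Deterministic given ``spec.seed``.  Burst blocks are aligned to the
    0.5 s grid of the large-amplitude-noise filter and are only placed
    beyond its warm-up history, so every generated burst is scoreable.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    n = int(round(spec.duration_s * spec.fs))
    t = np.arange(n) / spec.fs

    rr = _rr_sequence(spec, rng)
    r_times = 0.5 + np.cumsum(np.concatenate(([0.0], rr)))
    keep = r_times < spec.duration_s - 0.5
    r_times = r_times[keep]
    if r_times.size < 2:
        raise ValueError("duration too short for the requested rhythm")
    # snap beats onto the sampling grid so each R apex is exactly at a sample
    r_samples = np.round(r_times * spec.fs).astype(int)
    r_times = r_samples / spec.fs
    rr_true = np.diff(r_samples) / spec.fs

    sig = _render_beats(r_times, n, spec.fs)

    if spec.drift_amp_mV > 0:
        sig += spec.drift_amp_mV * np.sin(
            2 * np.pi * spec.drift_hz * t + rng.uniform(0, 2 * np.pi)
        )
    if spec.powerline_amp_mV > 0:
        sig += spec.powerline_amp_mV * np.sin(
            2 * np.pi * spec.powerline_hz * t + rng.uniform(0, 2 * np.pi)
        )
    if spec.emg_amp_mV > 0:
        white = rng.standard_normal(n)
        if spec.fs > 44.0:  # shape into the 20 Hz+ EMG band
            sos = sps.butter(4, 20.0, btype="high", fs=spec.fs, output="sos")
            white = sps.sosfiltfilt(sos, white)
        sig += spec.emg_amp_mV / white.std() * white

    burst_blocks = np.array([], dtype=int)
    if spec.burst_rate_per_min > 0:
        block_len = int(round(_LAN_BLOCK_S * spec.fs))
        n_blocks = n // block_len
        eligible = np.arange(_LAN_HISTORY_BLOCKS, n_blocks)
        n_bursts = min(
            rng.poisson(spec.burst_rate_per_min * spec.duration_s / 60.0),
            eligible.size,
        )
        burst_blocks = np.sort(rng.choice(eligible, size=n_bursts, replace=False))
        r_amp = _WAVES["R"][2]
        for b in burst_blocks:
            sl = slice(b * block_len, (b + 1) * block_len)
            sig[sl] += spec.burst_amp_factor * r_amp * rng.standard_normal(block_len)

    sig += spec.dc_offset_mV

    record = ECGRecord(samples=sig, fs=spec.fs, subject_id="synthetic", notes=f"rhythm={spec.rhythm}")
    n_segments = max(1, int(spec.duration_s // 75.0))
    truth = GroundTruth(
        r_samples=r_samples,
        rr_true_s=rr_true,
        rhythm_labels=[spec.rhythm] * n_segments,
        burst_blocks=burst_blocks,
    )
    return record, truth
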