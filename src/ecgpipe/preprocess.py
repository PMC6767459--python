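"""Signal adequation: the four-filter denoising bench.

The chain mirrors a classical single-lead conditioning stack for noisy
hand-electrode recordings, applied in fixed order:

1. 75 Hz low-pass (morphology-preserving; EMG and residual HF rejection),
2. baseline-wander removal by cubic-spline interpolation through segment
   means (drift is sub-0.5 Hz: respiration, electrode impedance, movement),
3. 50 Hz notch for mains interference,
4. block-wise large-amplitude-noise (LAN) excision: 0.5 s blocks whose
   standard deviation exceeds mean + 2·std of the ten preceding block
   deviations are masked out (saturation / signal-loss artifacts).

All stages are length-preserving.  Removed LAN blocks are *masked*, never
zero-filled — zero-filling would create artificial edges that mimic QRS
slopes downstream; every later stage consults ``valid_mask``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import signal as sps
from scipy.interpolate import CubicSpline

from .records import AnalysisConfig, ECGRecord

logger = logging.getLogger("ecgpipe")

__all__ = [
    "FilteredECG",
    "lowpass75",
    "remove_baseline",
    "notch50",
    "remove_large_amplitude_noise",
    "preprocess",
]


@dataclass
class FilteredECG:
    """Denoised single-lead signal plus a per-sample validity mask."""

    samples: np.ndarray
    fs: float
    valid_mask: np.ndarray = None  # type: ignore[assignment]
    stages_applied: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.valid_mask is None:
            self.valid_mask = np.ones(self.samples.size, dtype=bool)
        self.valid_mask = np.asarray(self.valid_mask, dtype=bool)
        if self.valid_mask.size != self.samples.size:
            raise ValueError("valid_mask length must equal samples length")

    @classmethod
    def from_record(cls, record: ECGRecord) -> "FilteredECG":
        return cls(samples=record.samples.copy(), fs=record.fs)

    def _derive(self, samples: np.ndarray, stage: str) -> "FilteredECG":
        return FilteredECG(
            samples=samples,
            fs=self.fs,
            valid_mask=self.valid_mask.copy(),
            stages_applied=self.stages_applied + [stage],
        )

    def __len__(self) -> int:
        return self.samples.size


def _as_filtered(x: ECGRecord | FilteredECG) -> FilteredECG:
    return FilteredECG.from_record(x) if isinstance(x, ECGRecord) else x


def lowpass75(
    record: ECGRecord | FilteredECG, cutoff_hz: float = 75.0, order: int = 4
) -> FilteredECG:
    """Zero-phase Butterworth low-pass, default cut-off 75 Hz.

    Applied forward-backward (``filtfilt``) so QRS morphology is not
    distorted by phase lag; DC gain is exactly 1.
    """
    sig = _as_filtered(record)
    if not sig.fs > 2 * cutoff_hz:
        raise ValueError(
            f"low-pass cut-off {cutoff_hz} Hz requires fs > {2 * cutoff_hz} Hz "
            f"(got fs={sig.fs})"
        )
    sos = sps.butter(order, cutoff_hz, btype="low", fs=sig.fs, output="sos")
    out = sps.sosfiltfilt(sos, sig.samples)
    return sig._derive(out, "lowpass")


def remove_baseline(
    signal: ECGRecord | FilteredECG, knot_segment_s: float = 1.0
) -> FilteredECG:
    """Subtract a cubic spline through per-segment mean values.

    The signal is cut into consecutive ``knot_segment_s`` segments; knot k
    sits at the temporal centre of segment k with ordinate equal to the
    segment mean.  Segments of ~1 s are long relative to one beat, so the
    knots track sub-0.5 Hz drift (and any DC offset) rather than QRS
    energy.  Signals too short for four knots fall back to plain mean
    subtraction.
    """
    sig = _as_filtered(signal)
    n = sig.samples.size
    seg_len = max(1, int(round(knot_segment_s * sig.fs)))
    n_seg = n // seg_len
    if n_seg < 4:
        logger.warning(
            "record too short for spline baseline (%d segments); "
            "falling back to mean subtraction",
            n_seg,
        )
        return sig._derive(sig.samples - sig.samples.mean(), "baseline")
    knots_x = np.arange(n_seg) * seg_len + (seg_len - 1) / 2.0
    knots_y = np.array(
        [sig.samples[k * seg_len : (k + 1) * seg_len].mean() for k in range(n_seg)]
    )
    spline = CubicSpline(knots_x, knots_y)  # not-a-knot; extrapolates at edges
    baseline = spline(np.arange(n))
    return sig._derive(sig.samples - baseline, "baseline")


def notch50(
    signal: ECGRecord | FilteredECG, notch_hz: float = 50.0, q: float = 30.0
) -> FilteredECG:
    """Zero-phase IIR notch at the mains frequency (50 Hz in Spain)."""
    sig = _as_filtered(signal)
    if not sig.fs > 2 * notch_hz:
        raise ValueError(
            f"notch at {notch_hz} Hz requires fs > {2 * notch_hz} Hz (got fs={sig.fs})"
        )
    b, a = sps.iirnotch(notch_hz, q, fs=sig.fs)
    out = sps.filtfilt(b, a, sig.samples)
    return sig._derive(out, "notch")


def remove_large_amplitude_noise(
    signal: ECGRecord | FilteredECG,
    block_s: float = 0.5,
    history_blocks: int = 10,
    k_sigma: float = 2.0,
) -> FilteredECG:
    """Mask blocks whose dispersion jumps out of the recent history.

    Steps: (i) divide the signal into ``block_s`` blocks; (ii) compute each
    block's standard deviation; (iii) for every block, compute the mean and
    standard deviation of the ``history_blocks`` *previous* block
    deviations (strictly causal window); (iv) mask the block when its
    deviation strictly exceeds mean + ``k_sigma``·std of that history.

    The first ``history_blocks`` blocks have no full history and are never
    flagged.  The strict inequality means an all-tied history (e.g. a
    constant or all-zero signal, where every block deviation is equal)
    flags nothing.  Flagged blocks keep their samples but get
    ``valid_mask=False``; downstream stages skip them.
    """
    sig = _as_filtered(signal)
    n = sig.samples.size
    block_len = max(1, int(round(block_s * sig.fs)))
    n_blocks = n // block_len
    if n_blocks < history_blocks + 1:
        logger.warning(
            "record too short for LAN filtering (%d blocks, need %d); stage skipped",
            n_blocks,
            history_blocks + 1,
        )
        return sig._derive(sig.samples.copy(), "lan")

    block_sd = np.array(
        [sig.samples[b * block_len : (b + 1) * block_len].std() for b in range(n_blocks)]
    )
    mask = sig.valid_mask.copy()
    for b in range(history_blocks, n_blocks):
        hist = block_sd[b - history_blocks : b]
        if block_sd[b] > hist.mean() + k_sigma * hist.std():
            mask[b * block_len : (b + 1) * block_len] = False
    out = FilteredECG(
        samples=sig.samples.copy(),
        fs=sig.fs,
        valid_mask=mask,
        stages_applied=sig.stages_applied + ["lan"],
    )
    return out


def lan_flagged_blocks(signal: FilteredECG, block_s: float = 0.5) -> np.ndarray:
    """Indices of blocks masked invalid, for inspection and testing."""
    block_len = max(1, int(round(block_s * signal.fs)))
    n_blocks = signal.samples.size // block_len
    flagged = [
        b
        for b in range(n_blocks)
        if not signal.valid_mask[b * block_len : (b + 1) * block_len].all()
    ]
    return np.asarray(flagged, dtype=int)


def preprocess(record: ECGRecord, config: AnalysisConfig | None = None) -> FilteredECG:
    """Run the full bench in fixed order: low-pass → baseline → notch → LAN."""
    cfg = config or AnalysisConfig()
    sig = lowpass75(record, cfg.lowpass_cutoff_hz, cfg.lowpass_order)
    sig = remove_baseline(sig, cfg.spline_knot_s)
    sig = notch50(sig, cfg.notch_hz, cfg.notch_q)
    sig = remove_large_amplitude_noise(
        sig, cfg.lan_block_s, cfg.lan_history_blocks, cfg.lan_k_sigma
    )
    return sig
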