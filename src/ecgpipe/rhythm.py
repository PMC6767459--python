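"""Rhythm analysis: RR warnings, Poincaré disorganization, AF screening, HRV.

From the detected R-wave positions the module derives the RR-interval
series and its first difference dRR, and then:

* flags *rhythm alterations* — an interval differing from its predecessor
  by more than 30% — and *pauses* — intervals longer than 3 s;
* *denoises* the RR cloud with quartile fences: an interval is an outlier
  when it falls outside [P25 − 3·IQR, P75 + 3·IQR] on the RR axis or the
  dRR axis;
* builds a discretized Lorenz–Poincaré diagram — (RR[n], dRR[n]) points
  histogrammed on a fixed physiologic grid — and summarizes its spread as
  the *disorganization index*, the fraction of grid bins that are full.
  Atrial fibrillation produces an irregularly irregular RR series, hence a
  dispersed cloud and a high index; 75 s segments whose index exceeds a
  calibrated cut are flagged as AF-suspect;
* computes time-domain HRV indices (mean heart rate, SDNN, RR range,
  triangular index).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .qrs import BeatAnnotations
from .records import AnalysisConfig, RhythmReport

logger = logging.getLogger("ecgpipe")

__all__ = [
    "RRSeries",
    "OutlierFences",
    "PoincareGrid",
    "build_rr",
    "detect_rhythm_alterations",
    "detect_pauses",
    "fence_outliers",
    "poincare_grid",
    "disorganization_index",
    "classify_af",
    "hrv_indices",
    "analyze_rhythm",
]


@dataclass
class RRSeries:
    """Inter-beat intervals RR[n] with derivative dRR[n] and flags.

    ``rr[n]`` is the interval *ending* at beat n+1, in seconds.
    ``drr[n] = rr[n] - rr[n-1]`` (length len(rr) - 1).
    ``valid[n]`` is False for intervals spanning masked signal gaps;
    ``outlier_mask[n]`` is set by :func:`fence_outliers`.
    """

    rr: np.ndarray
    fs: float
    start_times_s: np.ndarray = None  # type: ignore[assignment]
    valid: np.ndarray = None  # type: ignore[assignment]
    outlier_mask: np.ndarray = None  # type: ignore[assignment]
    fences: "OutlierFences | None" = None

    def __post_init__(self) -> None:
        self.rr = np.asarray(self.rr, dtype=float)
        if np.any(self.rr <= 0):
            raise ValueError("all RR intervals must be positive")
        if self.start_times_s is None:
            self.start_times_s = np.concatenate(([0.0], np.cumsum(self.rr[:-1])))
        self.start_times_s = np.asarray(self.start_times_s, dtype=float)
        if self.valid is None:
            self.valid = np.ones(self.rr.size, dtype=bool)
        self.valid = np.asarray(self.valid, dtype=bool)
        if self.outlier_mask is None:
            self.outlier_mask = np.zeros(self.rr.size, dtype=bool)

    @property
    def drr(self) -> np.ndarray:
        return np.diff(self.rr)

    def __len__(self) -> int:
        return self.rr.size


@dataclass
class OutlierFences:
    """Quartiles and interquartile ranges of the RR and dRR axes (seconds)."""

    p25_rr: float
    p75_rr: float
    p25_drr: float
    p75_drr: float

    @property
    def iqr_rr(self) -> float:
        return self.p75_rr - self.p25_rr

    @property
    def iqr_drr(self) -> float:
        return self.p75_drr - self.p25_drr


@dataclass
class PoincareGrid:
    """Discretized Lorenz–Poincaré diagram: RR on x, dRR on y."""

    counts: np.ndarray
    rr_range_s: tuple[float, float]
    drr_range_s: tuple[float, float]
    n_points: int = 0

    @property
    def bins_per_axis(self) -> int:
        return self.counts.shape[0]


def build_rr(ann: BeatAnnotations, valid_mask: np.ndarray | None = None) -> RRSeries:
    """Derive the RR series from beat annotations.

    Intervals spanning any masked (excised large-amplitude-noise) sample
    are kept in the series but flagged invalid and excluded from
    statistics downstream.
    """
    if ann.n_beats < 2:
        raise ValueError(f"need at least 2 beats to build RR series, got {ann.n_beats}")
    rr = np.diff(ann.r_indices) / ann.fs
    valid = np.ones(rr.size, dtype=bool)
    if valid_mask is not None:
        vm = np.asarray(valid_mask, dtype=bool)
        for n in range(rr.size):
            a, b = ann.r_indices[n], ann.r_indices[n + 1]
            if not vm[a : b + 1].all():
                valid[n] = False
    return RRSeries(
        rr=rr,
        fs=ann.fs,
        start_times_s=ann.r_indices[:-1] / ann.fs,
        valid=valid,
    )


def detect_rhythm_alterations(
    rr: RRSeries, alteration_frac: float = 0.30
) -> list[tuple[int, float, float]]:
    """Intervals differing from their predecessor by more than 30%."""
    out = []
    for n in range(1, len(rr)):
        if not (rr.valid[n] and rr.valid[n - 1]):
            continue
        if abs(rr.rr[n] - rr.rr[n - 1]) / rr.rr[n - 1] > alteration_frac:
            out.append((n, float(rr.rr[n]), float(rr.rr[n - 1])))
    return out


def detect_pauses(rr: RRSeries, pause_s: float = 3.0) -> list[tuple[int, float]]:
    """Intervals strictly longer than the pause threshold (default 3 s)."""
    return [
        (n, float(rr.rr[n]))
        for n in range(len(rr))
        if rr.valid[n] and rr.rr[n] > pause_s
    ]


def fence_outliers(
    rr: RRSeries,
    fence_multiplier: float = 3.0,
    literal_rule: bool = False,
) -> RRSeries:
    """Flag RR outliers with quartile fences on the RR and dRR axes.

    The standard two-sided fence marks interval n when RR[n] (or dRR[n])
    lies strictly outside [P25 − m·IQR, P75 + m·IQR]; fence boundaries are
    inclusive (a value on the fence is not an outlier), which also handles
    the degenerate IQR = 0 series.  ``literal_rule=True`` switches to an
    upper-fence-only variant (outlier iff the value exceeds P75 + m·IQR)
    retained for fidelity comparisons.

    dRR[n] belongs to interval n (defined for n ≥ 1); interval 0 can only
    be fenced on the RR axis.
    """
    n = len(rr)
    if np.count_nonzero(rr.valid) < 4:
        logger.warning("fewer than 4 valid RR intervals; outlier fencing skipped")
        rr.outlier_mask = np.zeros(n, dtype=bool)
        rr.fences = None
        return rr
    vals = rr.rr[rr.valid]
    drr = rr.drr
    drr_valid = rr.valid[1:] & rr.valid[:-1]
    dvals = drr[drr_valid] if drr_valid.any() else np.array([0.0])
    f = OutlierFences(
        p25_rr=float(np.percentile(vals, 25)),
        p75_rr=float(np.percentile(vals, 75)),
        p25_drr=float(np.percentile(dvals, 25)),
        p75_drr=float(np.percentile(dvals, 75)),
    )
    m = fence_multiplier
    o1 = np.zeros(n, dtype=bool)
    o2 = np.zeros(n, dtype=bool)
    if literal_rule:
        o1 = rr.rr > f.p75_rr + m * f.iqr_rr
        o2[1:] = drr > f.p75_drr + m * f.iqr_drr
    else:
        o1 = (rr.rr < f.p25_rr - m * f.iqr_rr) | (rr.rr > f.p75_rr + m * f.iqr_rr)
        o2[1:] = (drr < f.p25_drr - m * f.iqr_drr) | (drr > f.p75_drr + m * f.iqr_drr)
    rr.outlier_mask = (o1 | o2) & rr.valid
    rr.outlier_mask[~rr.valid] = False
    rr.fences = f
    return rr


def poincare_grid(
    rr: RRSeries,
    bins_per_axis: int = 30,
    rr_range_s: tuple[float, float] = (0.24, 2.0),
    drr_range_s: tuple[float, float] = (-0.88, 0.88),
) -> PoincareGrid:
    """Histogram the (RR[n], dRR[n]) cloud on a fixed physiologic grid.

    Points use n ≥ 1 (where dRR is defined), skipping outliers and
    invalid intervals.  The axis ranges are fixed rather than auto-scaled
    so the disorganization index is comparable across segments; points
    beyond a range are clipped into the edge bin, so every plotted point
    lands in exactly one bin.
    """
    drr = rr.drr
    keep = (
        rr.valid[1:]
        & rr.valid[:-1]
        & ~rr.outlier_mask[1:]
        & ~rr.outlier_mask[:-1]
    )
    x = rr.rr[1:][keep]
    y = drr[keep]
    if x.size < 2:
        raise ValueError("need at least 2 plottable points for a Poincaré grid")
    eps = 1e-12
    x = np.clip(x, rr_range_s[0], rr_range_s[1] - eps)
    y = np.clip(y, drr_range_s[0], drr_range_s[1] - eps)
    counts, _, _ = np.histogram2d(
        x,
        y,
        bins=bins_per_axis,
        range=[list(rr_range_s), list(drr_range_s)],
    )
    return PoincareGrid(
        counts=counts.astype(int),
        rr_range_s=rr_range_s,
        drr_range_s=drr_range_s,
        n_points=int(x.size),
    )


def disorganization_index(grid: PoincareGrid, full_bin_min_count: int = 1) -> float:
    """Fraction of grid bins that are full (count ≥ ``full_bin_min_count``)."""
    total = grid.counts.size
    full = int(np.count_nonzero(grid.counts >= full_bin_min_count))
    return full / total


def classify_af(rr: RRSeries, config: AnalysisConfig | None = None) -> list[dict]:
    """Screen consecutive 75 s segments for AF-like disorganization.

    The rhythm is split into non-overlapping segments of
    ``config.af_segment_s``; per segment the RR cloud is fenced,
    discretized and scored, and the segment is flagged when the
    disorganization index exceeds ``config.af_threshold``.  A record
    shorter than one segment is analyzed as a single best-effort segment.
    A trailing partial segment is ignored.
    """
    cfg = config or AnalysisConfig()
    seg_s = cfg.af_segment_s
    end_times = rr.start_times_s + rr.rr
    total = float(end_times[-1]) if len(rr) else 0.0
    n_segments = int(total // seg_s)
    best_effort = n_segments == 0
    if best_effort:
        logger.warning(
            "record (%.1f s) shorter than one %g s segment; best-effort analysis",
            total,
            seg_s,
        )
        bounds = [(0.0, total)]
    else:
        bounds = [(k * seg_s, (k + 1) * seg_s) for k in range(n_segments)]

    segments = []
    for start, end in bounds:
        sel = (end_times > start) & (end_times <= end + 1e-9)
        seg = {
            "start_s": float(start),
            "end_s": float(end),
            "n_intervals": int(np.count_nonzero(sel)),
            "disorganization": float("nan"),
            "af": False,
            "best_effort": best_effort,
        }
        sub_rr = rr.rr[sel]
        sub_valid = rr.valid[sel]
        if sub_rr.size >= 4:
            sub = RRSeries(rr=sub_rr, fs=rr.fs, valid=sub_valid)
            sub = fence_outliers(sub, cfg.fence_multiplier, cfg.fence_literal_rule)
            try:
                grid = poincare_grid(
                    sub, cfg.af_bins_per_axis, cfg.rr_axis_range_s, cfg.drr_axis_range_s
                )
            except ValueError:
                segments.append(seg)
                continue
            idx = disorganization_index(grid, cfg.af_full_bin_min_count)
            seg["disorganization"] = idx
            seg["af"] = bool(idx > cfg.af_threshold)
        segments.append(seg)
    return segments


def hrv_indices(rr: RRSeries, triangular_bin_s: float = 1.0 / 128.0) -> dict[str, float]:
    """Time-domain HRV summary on valid intervals.

    mean_hr_bpm = 60 / mean(RR); sdnn_s is the population standard
    deviation; rr_range_s = max − min; the triangular index is
    N / (height of the tallest RR histogram bin), with the conventional
    1/128 s bin width.
    """
    vals = rr.rr[rr.valid]
    if vals.size < 2:
        raise ValueError("need at least 2 valid RR intervals for HRV indices")
    lo = np.floor(vals.min() / triangular_bin_s) * triangular_bin_s
    hi = np.ceil(vals.max() / triangular_bin_s) * triangular_bin_s
    n_bins = max(1, int(round((hi - lo) / triangular_bin_s)))
    counts, _ = np.histogram(vals, bins=n_bins, range=(lo, lo + n_bins * triangular_bin_s))
    return {
        "mean_hr_bpm": 60.0 / float(vals.mean()),
        "sdnn_s": float(vals.std()),
        "rr_range_s": float(vals.max() - vals.min()),
        "triangular_index": vals.size / int(counts.max()),
    }


def analyze_rhythm(
    ann: BeatAnnotations,
    config: AnalysisConfig | None = None,
    valid_mask: np.ndarray | None = None,
) -> RhythmReport:
    """Full rhythm stage: warnings + AF segments + HRV in one report."""
    cfg = config or AnalysisConfig()
    report = RhythmReport(n_beats=ann.n_beats)
    if ann.n_beats < 2:
        report.meta["warning"] = "fewer than 2 beats; rhythm analysis skipped"
        return report
    rr = build_rr(ann, valid_mask)
    report.alterations = detect_rhythm_alterations(rr, cfg.alteration_frac)
    report.pauses = detect_pauses(rr, cfg.pause_s)
    report.af_segments = classify_af(rr, cfg)
    try:
        report.hrv = hrv_indices(rr)
    except ValueError:
        report.meta["warning"] = "too few valid intervals for HRV indices"
    return report
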