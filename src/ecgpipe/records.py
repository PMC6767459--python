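"""Data model, CSV/JSON I/O, and analysis configuration.

The companion app of a handheld two-electrode monitor stores each ECG
registry as a plain CSV file, one voltage sample per row.  This module
defines the in-memory containers used throughout the pipeline (records,
reports, configuration) and readers/writers for those files.

Amplitudes are in millivolts throughout: hand-electrode front-ends of this
class superimpose a DC level of the order of 16 mV on a ~1 mV QRS, so mV is
the natural working unit.  The sampling rate is never implied by the file
and must always be supplied by the caller (250 Hz is the documented default
for synthetic data).
"""

from __future__ import annotations

import dataclasses
import enum
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Optional

import numpy as np

logger = logging.getLogger("ecgpipe")

__all__ = [
    "LeadMode",
    "ECGRecord",
    "ABPMeasurement",
    "AnalysisConfig",
    "RhythmReport",
    "read_ecg_csv",
    "write_ecg_csv",
    "write_report",
    "read_report",
]


class LeadMode(str, enum.Enum):
    """Electrode configuration of the acquisition device.

    The device offers three modes — two case-embedded hand electrodes, two
    wired chest electrodes, or both pairs at once.  Analysis treats all
    three as a single-channel input; the mode is carried as provenance.
    """

    EMBEDDED_2 = "embedded_2"
    WIRED_2 = "wired_2"
    TWO_BY_TWO = "two_by_two"


@dataclass
class ECGRecord:
    """A sampled single-lead ECG voltage series.

    Parameters
    ----------
    samples : array of float
        Voltage samples in millivolts.
    fs : float
        Sampling rate in Hz, strictly positive.
    start_time : str, optional
        ISO timestamp of acquisition start.
    lead_mode : LeadMode
        Electrode configuration (metadata only).
    subject_id : str
        Opaque subject identifier.
    notes : str
        Free text, e.g. the symptom description entered for an
        exceptional (symptom-triggered) measurement.
    """

    samples: np.ndarray
    fs: float
    start_time: Optional[str] = None
    lead_mode: LeadMode = LeadMode.EMBEDDED_2
    subject_id: str = ""
    notes: str = ""

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.ndim != 1 or self.samples.size < 1:
            raise ValueError("ECGRecord requires a non-empty 1-D sample array")
        if not np.all(np.isfinite(self.samples)):
            raise ValueError("ECGRecord samples must all be finite")
        if not self.fs > 0:
            raise ValueError(f"sampling rate must be positive, got {self.fs}")
        self.lead_mode = LeadMode(self.lead_mode)

    @property
    def duration_s(self) -> float:
        return self.samples.size / self.fs

    def __len__(self) -> int:
        return self.samples.size


@dataclass
class ABPMeasurement:
    """Cuff blood-pressure reading carried through as metadata only."""

    systolic: float
    diastolic: float
    timestamp: Optional[str] = None

    def __post_init__(self) -> None:
        if not (self.systolic > self.diastolic > 0):
            raise ValueError(
                "require systolic > diastolic > 0, got "
                f"{self.systolic}/{self.diastolic}"
            )


@dataclass
class AnalysisConfig:
    """Tunable parameters of the full analysis chain.

    The defaults reproduce the processing constants of the platform's
    published analysis chain: 75 Hz low-pass, 50 Hz notch (Spanish mains),
    0.5 s large-amplitude-noise blocks scored against the ten previous
    blocks at mean + 2·std, 30% rhythm-alteration threshold, 3 s pause
    threshold, 75 s AF segments, 40%/60% beat split, 10% QRS window and a
    99.5% correlation gate.  Values without a published counterpart
    (refractory period, zone threshold, grid geometry, AF cut) are this
    package's own defaults and are documented where they are used.
    """

    # -- signal adequation -------------------------------------------------
    lowpass_cutoff_hz: float = 75.0
    lowpass_order: int = 4
    notch_hz: float = 50.0
    notch_q: float = 30.0
    spline_knot_s: float = 1.0
    lan_block_s: float = 0.5
    lan_history_blocks: int = 10
    lan_k_sigma: float = 2.0
    # -- beat detection ----------------------------------------------------
    zone_threshold_c: float = 1.0
    zone_merge_gap_s: float = 0.05
    refractory_s: float = 0.2
    # -- rhythm analysis ---------------------------------------------------
    alteration_frac: float = 0.30
    pause_s: float = 3.0
    af_segment_s: float = 75.0
    af_bins_per_axis: int = 30
    af_full_bin_min_count: int = 1
    # Calibrated on the synthetic sinus/AF generator suite by
    # scripts/calibrate_af_threshold.py (Youden's J); see docs/methods.md.
    af_threshold: float = 0.0483
    rr_axis_range_s: tuple[float, float] = (0.24, 2.0)
    drr_axis_range_s: tuple[float, float] = (-0.88, 0.88)
    fence_multiplier: float = 3.0
    fence_literal_rule: bool = False
    # -- beat template -----------------------------------------------------
    template_pre_frac: float = 0.40
    template_post_frac: float = 0.60
    template_window_frac: float = 0.10
    template_corr_min: float = 0.995
    template_reference: str = "median"  # or "pairwise_mean"

    def replace(self, **overrides: Any) -> "AnalysisConfig":
        return dataclasses.replace(self, **overrides)

    def to_dict(self) -> dict[str, Any]:
        d = dataclasses.asdict(self)
        d["rr_axis_range_s"] = list(d["rr_axis_range_s"])
        d["drr_axis_range_s"] = list(d["drr_axis_range_s"])
        return d

    @classmethod
    def from_dict(cls, d: dict[str, Any]) -> "AnalysisConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        d = dict(d)
        for k in ("rr_axis_range_s", "drr_axis_range_s"):
            if k in d:
                d[k] = tuple(d[k])
        return cls(**d)


@dataclass
class RhythmReport:
    """Aggregated rhythm-analysis output for one record.

    alterations: (interval index, RR[n] s, RR[n-1] s) triples where the
        interval changed by more than the alteration fraction.
    pauses: (interval index, RR[n] s) pairs where RR exceeds the pause
        threshold.
    af_segments: per 75 s segment — (start_s, end_s, disorganization
        index, AF flag).
    hrv: time-domain indices {mean_hr_bpm, sdnn_s, rr_range_s,
        triangular_index}.
    """

    alterations: list[tuple[int, float, float]] = field(default_factory=list)
    pauses: list[tuple[int, float]] = field(default_factory=list)
    af_segments: list[dict[str, Any]] = field(default_factory=list)
    hrv: dict[str, float] = field(default_factory=dict)
    n_beats: int = 0
    meta: dict[str, Any] = field(default_factory=dict)

    def to_dict(self) -> dict[str, Any]:
        return {
            "alterations": [
                {"interval": int(i), "rr_s": float(rr), "prev_rr_s": float(prev)}
                for i, rr, prev in self.alterations
            ],
            "pauses": [
                {"interval": int(i), "rr_s": float(rr)} for i, rr in self.pauses
            ],
            "af_segments": self.af_segments,
            "hrv": {k: float(v) for k, v in self.hrv.items()},
            "n_beats": int(self.n_beats),
            "meta": self.meta,
        }

    @classmethod
    def from_dict(cls, d: dict[str, Any]) -> "RhythmReport":
        return cls(
            alterations=[
                (a["interval"], a["rr_s"], a["prev_rr_s"]) for a in d["alterations"]
            ],
            pauses=[(p["interval"], p["rr_s"]) for p in d["pauses"]],
            af_segments=list(d["af_segments"]),
            hrv=dict(d["hrv"]),
            n_beats=int(d.get("n_beats", 0)),
            meta=dict(d.get("meta", {})),
        )


def read_ecg_csv(
    path: str | Path, fs: float, metadata: Optional[dict[str, Any]] = None
) -> ECGRecord:
    """Read a one-sample-per-row CSV file into an :class:`ECGRecord`.

    A single non-numeric header row is permitted.  Any other non-numeric
    row raises a ``ValueError`` naming the 1-based row number.
    """
    path = Path(path)
    values: list[float] = []
    with open(path, "r", encoding="utf-8") as fh:
        for row_no, line in enumerate(fh, start=1):
            text = line.strip().rstrip(",")
            if not text:
                continue
            try:
                values.append(float(text))
            except ValueError:
                if row_no == 1 and not values:
                    continue  # header row
                raise ValueError(
                    f"{path}: row {row_no}: cannot parse {text!r} as a voltage"
                ) from None
    if not values:
        raise ValueError(f"{path}: no data rows")
    meta = dict(metadata or {})
    return ECGRecord(
        samples=np.asarray(values, dtype=float),
        fs=fs,
        start_time=meta.get("start_time"),
        lead_mode=meta.get("lead_mode", LeadMode.EMBEDDED_2),
        subject_id=meta.get("subject_id", ""),
        notes=meta.get("notes", ""),
    )


def write_ecg_csv(record: ECGRecord, path: str | Path) -> None:
    """Write a record as one full-precision voltage per row."""
    if len(record) == 0:  # unreachable through the constructor; guards raw arrays
        raise ValueError("refusing to write an empty record")
    path = Path(path)
    with open(path, "w", encoding="utf-8") as fh:
        for v in record.samples:
            fh.write(f"{float(v)!r}\n")


def write_report(report: RhythmReport, path: str | Path, format: str = "json") -> None:
    """Serialize a :class:`RhythmReport` as machine JSON or readable text."""
    if format not in ("json", "text"):
        raise ValueError(f"unknown report format {format!r}; use 'json' or 'text'")
    path = Path(path)
    if format == "json":
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(report.to_dict(), fh, indent=2, sort_keys=True)
            fh.write("\n")
    else:
        with open(path, "w", encoding="utf-8") as fh:
            fh.write(render_report_text(report))


def render_report_text(report: RhythmReport) -> str:
    """Human-readable summary of a rhythm report."""
    lines = ["ECG rhythm report", "=" * 17]
    lines.append(f"beats detected: {report.n_beats}")
    lines.append(f"rhythm alterations (>30% RR change): {len(report.alterations)}")
    for i, rr, prev in report.alterations:
        lines.append(f"  interval {i}: RR {rr:.3f} s (previous {prev:.3f} s)")
    lines.append(f"pauses (RR > 3 s): {len(report.pauses)}")
    for i, rr in report.pauses:
        lines.append(f"  interval {i}: RR {rr:.3f} s")
    lines.append(f"AF segments: {len(report.af_segments)}")
    for seg in report.af_segments:
        verdict = "AF suspected" if seg["af"] else "non-AF"
        lines.append(
            f"  {seg['start_s']:.0f}-{seg['end_s']:.0f} s: "
            f"disorganization {seg['disorganization']:.4f} -> {verdict}"
        )
    if report.hrv:
        lines.append("HRV (time domain):")
        for k, v in sorted(report.hrv.items()):
            lines.append(f"  {k}: {v:.4f}")
    return "\n".join(lines) + "\n"


def read_report(path: str | Path) -> RhythmReport:
    with open(path, "r", encoding="utf-8") as fh:
        return RhythmReport.from_dict(json.load(fh))
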