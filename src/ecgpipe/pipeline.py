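"""End-to-end convenience wrapper: denoise → detect → rhythm → template."""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Optional

from .preprocess import FilteredECG, preprocess
from .qrs import BeatAnnotations, detect_beats_filtered
from .records import AnalysisConfig, ECGRecord, RhythmReport
from .rhythm import analyze_rhythm
from .template import BeatTemplate, build_template

logger = logging.getLogger("ecgpipe")

__all__ = ["AnalysisResult", "analyze"]


@dataclass
class AnalysisResult:
    filtered: FilteredECG
    annotations: BeatAnnotations
    report: RhythmReport
    template: Optional[BeatTemplate]


def analyze(record: ECGRecord, config: AnalysisConfig | None = None) -> AnalysisResult:
    """Run the complete analysis chain on one record."""
    cfg = config or AnalysisConfig()
    filtered = preprocess(record, cfg)
    ann = detect_beats_filtered(filtered, cfg)
    report = analyze_rhythm(ann, cfg, filtered.valid_mask)
    report.meta.setdefault("fs", record.fs)
    report.meta.setdefault("duration_s", record.duration_s)
    template = None
    if ann.n_beats >= 2:
        try:
            template = build_template(filtered, ann, cfg)
        except ValueError as exc:
            logger.warning("no beat template: %s", exc)
    return AnalysisResult(
        filtered=filtered, annotations=ann, report=report, template=template
    )
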