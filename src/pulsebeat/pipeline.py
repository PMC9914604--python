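"""End-to-end estimation: source → ROI → preprocess → features → rate."""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Optional

from . import __version__
from .errors import PulsebeatError
from .features import DEFAULT_MAX_PIXELS, compute_feature_matrix, sample_pixels
from .preprocess import PreprocessConfig, preprocess_sequence
from .rate import (DEFAULT_INITIAL_BPM, MAX_BPM, MIN_BPM, RateEstimate,
                   condition_series, detect_peaks, estimate_rate,
                   select_feature)
from .roi import crop, detect_roi
from .video_io import FrameSequence, read_frames

SCHEMA_VERSION = 1


@dataclass
class RunConfig:
    """Resolved settings of one estimation run (embedded in every report)."""

    detector: str = "skin_chroma"
    roi_smooth: bool = False
    preprocess: PreprocessConfig = field(default_factory=PreprocessConfig)
    mode: str = "running"
    normalize_selection: bool = False
    bandpass: bool = True
    min_bpm: float = MIN_BPM
    max_bpm: float = MAX_BPM
    initial_bpm: float = DEFAULT_INITIAL_BPM
    max_pixels: int = DEFAULT_MAX_PIXELS
    seed: int = 0
    fps_override: Optional[float] = None

    def to_dict(self) -> dict:
        d = asdict(self)
        return d


def run_estimate(source, config: Optional[RunConfig] = None,
                 sequence: Optional[FrameSequence] = None) -> dict:
    """Run the full pipeline on a source and return the report dict.

    Either ``source`` (path) or a pre-loaded ``sequence`` may be given.
    """
    config = config or RunConfig()
    if sequence is None:
        sequence = read_frames(source, fps_override=config.fps_override)
    boxes = detect_roi(sequence, detector=config.detector,
                       smooth=config.roi_smooth)
    cropped = crop(sequence, boxes)
    processed = preprocess_sequence(cropped, config.preprocess)
    samples = sample_pixels(processed, max_pixels=config.max_pixels,
                            seed=config.seed)
    matrix = compute_feature_matrix(samples, processed.timestamps)
    name, series = select_feature(matrix, normalize=config.normalize_selection)
    if config.bandpass:
        series = condition_series(series, matrix.frame_times,
                                  min_bpm=config.min_bpm,
                                  max_bpm=config.max_bpm)
    peaks = detect_peaks(series, matrix.frame_times,
                         min_bpm=config.min_bpm, max_bpm=config.max_bpm,
                         feature_name=name)
    estimate = estimate_rate(peaks, mode=config.mode, h_p=config.initial_bpm)
    return build_report(estimate, config, source=str(source))


def build_report(estimate: RateEstimate, config: RunConfig,
                 source: str = "") -> dict:
    return {
        "schema_version": SCHEMA_VERSION,
        "package_version": __version__,
        "source": source,
        "bpm": estimate.bpm,
        "pre_ceil_bpm": estimate.pre_ceil,
        "mode": estimate.mode,
        "feature_name": estimate.feature_name,
        "n_peaks": estimate.n_peaks_used,
        "M": estimate.M,
        "flag": estimate.flag,
        "warnings": estimate.warnings,
        "config": config.to_dict(),
    }


def write_report(report: dict, path) -> None:
    """Atomically write a JSON report (no partial files on error)."""
    path = Path(path)
    tmp = path.with_suffix(path.suffix + ".tmp")
    tmp.write_text(json.dumps(report, indent=2))
    tmp.replace(path)
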