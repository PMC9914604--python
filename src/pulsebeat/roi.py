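"""Skin region-of-interest detection and cropping.

The pulsatile signal lives in skin pixels (face or hand), so each frame is
reduced to one rectangular skin box before preprocessing. Detection is a
pluggable contract with four detectors:

``cascade``
    Delegates to a pre-trained Haar cascade (Viola–Jones) when OpenCV and a
    cascade file are available; otherwise downgrades to ``skin_chroma``
    with a logged warning.
``skin_chroma``
    Classic YCbCr skin thresholding (77 ≤ Cb ≤ 127, 133 ≤ Cr ≤ 173, JFIF
    full-range chroma); the box is the bounding box of the largest
    connected skin component.
``center_box``
    A centered box covering 50% of each dimension — the guaranteed
    fallback.
``fixed_box``
    A user-supplied ``x,y,w,h`` applied to every frame.

When a detector finds nothing in frame *i*, the box from frame *i−1* is
carried forward; if frame 0 has no detection, ``center_box`` is used.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import List, Optional, Union

import numpy as np
from skimage.measure import label, regionprops

from .errors import ConfigurationError, InputError
from .video_io import FrameSequence

logger = logging.getLogger(__name__)

#: Minimum usable box side: smaller regions carry no pulsatile signal.
MIN_BOX_SIDE = 8

#: JFIF chroma thresholds of the classic skin-color cluster.
CB_RANGE = (77, 127)
CR_RANGE = (133, 173)


@dataclass(frozen=True)
class BoundingBox:
    """A rectangular region in one frame (0-based pixel coordinates)."""

    x: int
    y: int
    w: int
    h: int
    frame_index: int = 0
    score: Optional[float] = None

    def validate(self, frame_shape) -> None:
        height, width = frame_shape[:2]
        if self.x < 0 or self.y < 0:
            raise InputError(f"box origin negative: {self}")
        if self.x + self.w > width or self.y + self.h > height:
            raise InputError(
                f"box {self} exceeds frame bounds {width}×{height}"
            )
        if self.w < MIN_BOX_SIDE or self.h < MIN_BOX_SIDE:
            raise InputError(
                f"box {self} smaller than minimum side {MIN_BOX_SIDE}"
            )


def _rgb_to_cbcr(frame: np.ndarray):
    """Full-range (JFIF) Cb/Cr planes of an RGB uint8 frame."""
    r = frame[..., 0].astype(np.float64)
    g = frame[..., 1].astype(np.float64)
    b = frame[..., 2].astype(np.float64)
    cb = 128.0 - 0.168736 * r - 0.331264 * g + 0.5 * b
    cr = 128.0 + 0.5 * r - 0.418688 * g - 0.081312 * b
    return cb, cr


def _detect_skin_chroma(frame: np.ndarray) -> Optional[BoundingBox]:
    cb, cr = _rgb_to_cbcr(frame)
    mask = (
        (cb >= CB_RANGE[0]) & (cb <= CB_RANGE[1])
        & (cr >= CR_RANGE[0]) & (cr <= CR_RANGE[1])
    )
    if not mask.any():
        return None
    labels = label(mask, connectivity=2)
    regions = regionprops(labels)
    best = max(regions, key=lambda r: r.area)
    y0, x0, y1, x1 = best.bbox
    w, h = x1 - x0, y1 - y0
    if w < MIN_BOX_SIDE or h < MIN_BOX_SIDE:
        return None
    return BoundingBox(x=int(x0), y=int(y0), w=int(w), h=int(h))


def _center_box(frame_shape) -> BoundingBox:
    height, width = frame_shape[:2]
    w, h = width // 2, height // 2
    return BoundingBox(x=(width - w) // 2, y=(height - h) // 2, w=w, h=h)


def _cascade_detector(cascade_path: Optional[str]):
    """Return a per-frame Haar-cascade callable, or None if unavailable."""
    try:
        import cv2  # optional dependency
    except ImportError:
        logger.warning(
            "cascade detector requested but OpenCV is not installed; "
            "downgrading to skin_chroma"
        )
        return None
    path = cascade_path
    if path is None:
        candidate = getattr(cv2.data, "haarcascades", "")
        path = candidate + "haarcascade_frontalface_default.xml"
    cascade = cv2.CascadeClassifier(path)
    if cascade.empty():
        logger.warning(
            "Haar cascade file %s not loadable; downgrading to skin_chroma",
            path,
        )
        return None

    def detect(frame: np.ndarray) -> Optional[BoundingBox]:
        gray = cv2.cvtColor(frame, cv2.COLOR_RGB2GRAY)
        hits = cascade.detectMultiScale(gray, 1.1, 4)
        if len(hits) == 0:
            return None
        x, y, w, h = max(hits, key=lambda b: b[2] * b[3])  # largest area
        if w < MIN_BOX_SIDE or h < MIN_BOX_SIDE:
            return None
        return BoundingBox(x=int(x), y=int(y), w=int(w), h=int(h))

    return detect


def _parse_fixed_box(spec: str) -> BoundingBox:
    try:
        x, y, w, h = (int(v) for v in spec.split(","))
    except ValueError as exc:
        raise ConfigurationError(
            f"fixed_box spec must be 'x,y,w,h', got {spec!r}"
        ) from exc
    return BoundingBox(x=x, y=y, w=w, h=h)


def detect_roi(
    sequence: FrameSequence,
    detector: str = "skin_chroma",
    cascade_path: Optional[str] = None,
    smooth: bool = False,
) -> List[BoundingBox]:
    """Locate the skin ROI in every frame; exactly one box per frame.

    Parameters
    ----------
    sequence:
        Non-empty frame sequence.
    detector:
        ``cascade``, ``skin_chroma``, ``center_box``, or a fixed-box spec
        ``"x,y,w,h"`` (also accepted as ``fixed_box:x,y,w,h``).
    smooth:
        Apply a window-5 median filter over box coordinates (off by
        default; per-frame jitter is kept by default).
    """
    if sequence.n_frames == 0:
        raise InputError("cannot detect ROI on an empty sequence")

    fixed: Optional[BoundingBox] = None
    per_frame = None
    if detector == "center_box":
        per_frame = None  # handled via fallback below
    elif detector == "skin_chroma":
        per_frame = _detect_skin_chroma
    elif detector == "cascade":
        per_frame = _cascade_detector(cascade_path) or _detect_skin_chroma
    elif detector.startswith("fixed_box:") or ("," in detector):
        spec = detector.split(":", 1)[-1]
        fixed = _parse_fixed_box(spec)
    else:
        raise ConfigurationError(f"unknown detector: {detector!r}")

    boxes: List[BoundingBox] = []
    for i, frame in enumerate(sequence.frames):
        if fixed is not None:
            box = BoundingBox(fixed.x, fixed.y, fixed.w, fixed.h, frame_index=i)
            box.validate(frame.shape)
        else:
            hit = per_frame(frame) if per_frame is not None else None
            if hit is None:
                if boxes:
                    prev = boxes[-1]
                    box = BoundingBox(prev.x, prev.y, prev.w, prev.h,
                                      frame_index=i, score=prev.score)
                else:
                    box = _center_box(frame.shape)
                    box = BoundingBox(box.x, box.y, box.w, box.h, frame_index=i)
            else:
                box = BoundingBox(hit.x, hit.y, hit.w, hit.h,
                                  frame_index=i, score=hit.score)
            box.validate(frame.shape)
        boxes.append(box)

    if smooth:
        boxes = _median_smooth(boxes, sequence)
    return boxes


def _median_smooth(boxes: List[BoundingBox], sequence: FrameSequence,
                   window: int = 5) -> List[BoundingBox]:
    coords = np.array([[b.x, b.y, b.w, b.h] for b in boxes], dtype=float)
    half = window // 2
    out = []
    for i in range(len(boxes)):
        lo, hi = max(0, i - half), min(len(boxes), i + half + 1)
        med = np.median(coords[lo:hi], axis=0).astype(int)
        box = BoundingBox(*map(int, med), frame_index=i)
        # clamp so a smoothed box never leaves its frame
        height, width = sequence.frames[i].shape[:2]
        x = min(max(box.x, 0), width - box.w)
        y = min(max(box.y, 0), height - box.h)
        out.append(BoundingBox(x, y, box.w, box.h, frame_index=i))
    return out


def crop(sequence: FrameSequence, boxes: List[BoundingBox]) -> FrameSequence:
    """Crop each frame to its box; timestamps and fps are preserved."""
    if len(boxes) != sequence.n_frames:
        raise InputError(
            f"{len(boxes)} boxes for {sequence.n_frames} frames"
        )
    frames = []
    for frame, box in zip(sequence.frames, boxes):
        box.validate(frame.shape)
        frames.append(frame[box.y:box.y + box.h, box.x:box.x + box.w])
    return FrameSequence(
        frames=frames,
        timestamps=sequence.timestamps,
        fps=sequence.fps,
        source_id=sequence.source_id,
        meta=sequence.meta,
    )


def iou(a: BoundingBox, b: BoundingBox) -> float:
    """Intersection-over-union of two boxes."""
    x0, y0 = max(a.x, b.x), max(a.y, b.y)
    x1, y1 = min(a.x + a.w, b.x + b.w), min(a.y + a.h, b.y + b.h)
    inter = max(0, x1 - x0) * max(0, y1 - y0)
    union = a.w * a.h + b.w * b.h - inter
    return inter / union if union > 0 else 0.0
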