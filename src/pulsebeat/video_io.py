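"""Frame ingestion and color conversion.

Sources are normalized into a :class:`FrameSequence`: an ordered collection
of timestamped RGB frames (uint8, H×W×3) with a known frame rate. Three
source kinds are supported:

* a directory of sequentially numbered PNG/JPEG frames (lexicographic
  order is temporal order),
* an ``.npz`` array bundle with keys ``frames`` (N×H×W×3 uint8), ``fps``
  (scalar) and ``meta`` (JSON string), as written by :mod:`pulsebeat.synth`,
* a video container (AVI/MP4) via imageio, when a suitable plugin is
  installed.

Channel order is RGB everywhere downstream, regardless of what a decoder
natively produces.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np

from .errors import ConfigurationError, InputError

_IMAGE_SUFFIXES = {".png", ".jpg", ".jpeg", ".bmp", ".tif", ".tiff"}

#: BT.601 luma weights used for RGB → grayscale conversion.
LUMA_WEIGHTS = (0.299, 0.587, 0.114)


@dataclass
class FrameSequence:
    """An ordered, timestamped sequence of RGB video frames.

    Attributes
    ----------
    frames:
        List of uint8 RGB images (height × width × 3). Frame sizes may
        differ across the sequence (e.g. after per-frame ROI cropping).
    timestamps:
        Per-frame times in seconds, strictly increasing. When synthesized
        from ``fps``, ``timestamps[i] == i / fps``.
    fps:
        Nominal frames per second, > 0.
    gray:
        Optional grayscale twin of ``frames`` (uint8, height × width).
    source_id:
        Free-text provenance of the sequence.
    """

    frames: list
    timestamps: np.ndarray
    fps: float
    gray: Optional[list] = None
    source_id: str = ""
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.timestamps = np.asarray(self.timestamps, dtype=float)
        if len(self.frames) != len(self.timestamps):
            raise InputError(
                f"frame/timestamp length mismatch: {len(self.frames)} vs "
                f"{len(self.timestamps)}"
            )
        if len(self.timestamps) > 1 and not np.all(np.diff(self.timestamps) > 0):
            raise InputError("timestamps must be strictly increasing")
        if self.fps <= 0:
            raise ConfigurationError(f"fps must be > 0, got {self.fps}")
        if self.gray is not None and len(self.gray) != len(self.frames):
            raise InputError("gray twin must have one frame per RGB frame")

    @property
    def n_frames(self) -> int:
        return len(self.frames)

    def with_gray(self) -> "FrameSequence":
        """Return the sequence with the grayscale twin populated."""
        if self.gray is not None:
            return self
        return FrameSequence(
            frames=self.frames,
            timestamps=self.timestamps,
            fps=self.fps,
            gray=[to_grayscale(f) for f in self.frames],
            source_id=self.source_id,
            meta=self.meta,
        )


def to_grayscale(frame: np.ndarray) -> np.ndarray:
    """Convert one RGB frame to grayscale.

    Uses BT.601 luma weights (0.299, 0.587, 0.114) with half-up rounding
    to integers in [0, 255]. An image whose three channels are equal maps
    back to that channel exactly.
    """
    frame = np.asarray(frame)
    if frame.ndim != 3 or frame.shape[2] != 3:
        raise InputError(
            f"expected an H×W×3 RGB frame, got shape {frame.shape}"
        )
    luma = frame[..., 0] * LUMA_WEIGHTS[0] + frame[..., 1] * LUMA_WEIGHTS[1] \
        + frame[..., 2] * LUMA_WEIGHTS[2]
    # round half-up (np.round is banker's rounding)
    return np.clip(np.floor(luma + 0.5), 0, 255).astype(np.uint8)


def _timestamps_from_fps(n: int, fps: float) -> np.ndarray:
    return np.arange(n, dtype=float) / fps


def _read_frame_directory(path: Path, fps: float) -> FrameSequence:
    import imageio.v3 as iio

    files = sorted(
        p for p in path.iterdir() if p.suffix.lower() in _IMAGE_SUFFIXES
    )
    if not files:
        raise InputError(f"no image frames found in directory: {path}")
    frames = []
    for p in files:
        img = np.asarray(iio.imread(p))
        if img.ndim == 2:  # grayscale file: promote to RGB
            img = np.stack([img] * 3, axis=-1)
        if img.shape[2] == 4:  # drop alpha
            img = img[..., :3]
        frames.append(np.ascontiguousarray(img, dtype=np.uint8))
    meta = {}
    meta_file = path / "meta.json"
    if meta_file.exists():
        meta = json.loads(meta_file.read_text())
    return FrameSequence(
        frames=frames,
        timestamps=_timestamps_from_fps(len(frames), fps),
        fps=fps,
        source_id=str(path),
        meta=meta,
    )


def _read_bundle(path: Path, fps_override: Optional[float]) -> FrameSequence:
    with np.load(path, allow_pickle=False) as npz:
        if "frames" not in npz:
            raise InputError(f"bundle {path} lacks a 'frames' array")
        frames_arr = np.asarray(npz["frames"], dtype=np.uint8)
        fps = float(fps_override or npz["fps"])
        meta = json.loads(str(npz["meta"])) if "meta" in npz else {}
    if frames_arr.ndim != 4 or frames_arr.shape[-1] != 3:
        raise InputError(
            f"bundle frames must be N×H×W×3, got {frames_arr.shape}"
        )
    if frames_arr.shape[0] == 0:
        raise InputError(f"bundle {path} contains no frames")
    return FrameSequence(
        frames=list(frames_arr),
        timestamps=_timestamps_from_fps(frames_arr.shape[0], fps),
        fps=fps,
        source_id=str(path),
        meta=meta,
    )


def _read_container(path: Path, fps_override: Optional[float]) -> FrameSequence:
    import imageio.v2 as iio

    try:
        reader = iio.get_reader(str(path))
    except Exception as exc:  # missing plugin or corrupt file
        raise InputError(f"cannot open video container {path}: {exc}") from exc
    try:
        meta = reader.get_meta_data()
        fps = float(fps_override or meta.get("fps") or 0.0)
        if fps <= 0:
            raise ConfigurationError(
                f"fps not recoverable from {path}; pass fps_override"
            )
        frames = []
        for img in reader:
            img = np.asarray(img)
            if img.ndim == 2:
                img = np.stack([img] * 3, axis=-1)
            frames.append(np.ascontiguousarray(img[..., :3], dtype=np.uint8))
    finally:
        reader.close()
    if not frames:
        raise InputError(f"no frames decoded from {path}")
    return FrameSequence(
        frames=frames,
        timestamps=_timestamps_from_fps(len(frames), fps),
        fps=fps,
        source_id=str(path),
    )


def read_frames(
    source, fps_override: Optional[float] = None
) -> FrameSequence:
    """Read a video source into a :class:`FrameSequence`.

    Parameters
    ----------
    source:
        Path to a frame directory, an ``.npz`` array bundle, or a video
        container (AVI/MP4, requires an imageio video plugin).
    fps_override:
        Frame rate to use when the source carries none (mandatory for
        frame directories without a ``meta.json`` recording fps).
    """
    path = Path(source)
    if not path.exists():
        raise InputError(f"source does not exist: {path}")
    if path.is_dir():
        fps = fps_override
        meta_file = path / "meta.json"
        if fps is None and meta_file.exists():
            fps = json.loads(meta_file.read_text()).get("fps")
        if fps is None:
            raise ConfigurationError(
                f"fps_override required for frame directory {path}"
            )
        return _read_frame_directory(path, float(fps))
    if path.suffix.lower() == ".npz":
        return _read_bundle(path, fps_override)
    return _read_container(path, fps_override)
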