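"""Synthetic pulsatile videos and signals with known ground-truth bpm.

No public dataset accompanies the method, so every stage is exercised
against generated inputs: a skin-colored elliptical region whose intensity
oscillates sinusoidally at a set bpm on a dark background, with optional
additive Gaussian noise, linear illumination drift, and integer ROI jitter.
The signal model is deliberately a plain sinusoid — the pipeline only needs
periodicity, not a hemodynamically realistic pulse waveform.

Defaults (fps 30, 10 s, 128 px frames, amplitude 4, noise σ 2) mimic a
short webcam clip of a skin patch: the pulse is a few intensity units on
top of comparable per-pixel sensor noise.

Truth metadata (bpm, per-frame ellipse geometry, seed) is recorded so
detectors and estimators can be scored exactly.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from pathlib import Path
from typing import Optional, Tuple

import numpy as np

from .errors import ConfigurationError
from .video_io import FrameSequence

BACKGROUND_LEVEL = 64.0


@dataclass(frozen=True)
class SynthSpec:
    """Parameters of the synthetic pulsatile scene."""

    bpm: float = 72.0
    fps: float = 30.0
    duration: float = 10.0
    frame_size: int = 128
    roi_center: Optional[Tuple[float, float]] = None  # (row, col); default center
    roi_axes: Optional[Tuple[float, float]] = None    # (semi_r, semi_c)
    base_rgb: Tuple[float, float, float] = (200.0, 160.0, 140.0)
    pulse_amplitude: float = 4.0
    noise_sigma: float = 2.0
    drift_per_s: float = 0.0
    jitter_px: int = 0
    seed: int = 0

    def __post_init__(self) -> None:
        if not 40.0 <= self.bpm <= 220.0:
            raise ConfigurationError(f"bpm {self.bpm} outside [40, 220]")
        if self.pulse_amplitude <= 0:
            raise ConfigurationError("pulse_amplitude must be > 0")
        if self.noise_sigma < 0:
            raise ConfigurationError("noise_sigma must be ≥ 0")
        if self.fps <= 0 or self.duration <= 0 or self.frame_size < 32:
            raise ConfigurationError("fps/duration/frame_size invalid")
        center = self.center
        axes = self.axes
        margin = self.jitter_px
        for c, a, lim in ((center[0], axes[0], self.frame_size),
                          (center[1], axes[1], self.frame_size)):
            if c - a - margin < 0 or c + a + margin > lim:
                raise ConfigurationError(
                    "ROI ellipse (plus jitter) must fit inside the frame"
                )

    @property
    def center(self) -> Tuple[float, float]:
        if self.roi_center is not None:
            return self.roi_center
        return (self.frame_size / 2.0, self.frame_size / 2.0)

    @property
    def axes(self) -> Tuple[float, float]:
        if self.roi_axes is not None:
            return self.roi_axes
        return (self.frame_size * 0.3, self.frame_size * 0.3)

    @property
    def n_frames(self) -> int:
        return int(round(self.duration * self.fps))


def _pulse_offset(spec: SynthSpec, t: np.ndarray) -> np.ndarray:
    freq_hz = spec.bpm / 60.0
    return (spec.pulse_amplitude * np.sin(2.0 * np.pi * freq_hz * t)
            + spec.drift_per_s * t)


def generate_signal(spec: SynthSpec):
    """The 1-D pulsatile series alone (no imaging).

    Returns ``(series, times, truth)``: mean-ROI-like intensity values,
    their times in seconds, and the truth metadata dict.
    """
    rng = np.random.default_rng(spec.seed)
    times = np.arange(spec.n_frames, dtype=float) / spec.fps
    base = float(np.mean(spec.base_rgb))
    series = base + _pulse_offset(spec, times)
    if spec.noise_sigma > 0:
        series = series + rng.normal(0.0, spec.noise_sigma, size=times.size)
    truth = {"bpm": spec.bpm, "fps": spec.fps, "seed": spec.seed,
             "duration": spec.duration}
    return series, times, truth


def generate_video(spec: SynthSpec) -> FrameSequence:
    """Render the pulsatile scene to a FrameSequence with truth metadata.

    Pixels inside the (jittered) ellipse take
    ``base_rgb + amplitude·sin(2π·(bpm/60)·t) + drift·t + N(0, σ)`` per
    channel (one shared noise draw per pixel), clipped to [0, 255]; the
    background is constant 64 + noise. ``sequence.meta["truth"]`` records
    bpm, per-frame ellipse geometry, and the seed.
    """
    rng = np.random.default_rng(spec.seed)
    n = spec.n_frames
    size = spec.frame_size
    times = np.arange(n, dtype=float) / spec.fps
    offsets = _pulse_offset(spec, times)
    rr, cc = np.mgrid[0:size, 0:size]
    center = spec.center
    axes = spec.axes

    frames = []
    geometry = []
    base = np.asarray(spec.base_rgb, dtype=np.float64)
    for i in range(n):
        if spec.jitter_px > 0:
            dr = int(rng.integers(-spec.jitter_px, spec.jitter_px + 1))
            dc = int(rng.integers(-spec.jitter_px, spec.jitter_px + 1))
        else:
            dr = dc = 0
        cy, cx = center[0] + dr, center[1] + dc
        mask = (((rr - cy) / axes[0]) ** 2 + ((cc - cx) / axes[1]) ** 2) <= 1.0
        frame = np.full((size, size, 3), BACKGROUND_LEVEL, dtype=np.float64)
        frame[mask] = base + offsets[i]
        if spec.noise_sigma > 0:
            noise = rng.normal(0.0, spec.noise_sigma, size=(size, size))
            frame += noise[..., None]
        frames.append(
            np.clip(np.floor(frame + 0.5), 0, 255).astype(np.uint8)
        )
        geometry.append({"center": [cy, cx], "axes": list(axes)})

    truth = {
        "bpm": spec.bpm,
        "seed": spec.seed,
        "roi_geometry": geometry,
        "spec": asdict(spec),
    }
    return FrameSequence(
        frames=frames,
        timestamps=times,
        fps=spec.fps,
        source_id=f"synth(bpm={spec.bpm},seed={spec.seed})",
        meta={"truth": truth, "fps": spec.fps},
    )


def save_bundle(sequence: FrameSequence, path) -> Path:
    """Write a FrameSequence as an npz array bundle readable by video_io."""
    path = Path(path)
    if path.suffix != ".npz":
        path = path.parent / (path.name + ".npz")
    np.savez_compressed(
        path,
        frames=np.stack(sequence.frames),
        fps=np.float64(sequence.fps),
        meta=json.dumps(sequence.meta),
    )
    return path


def save_frames(sequence: FrameSequence, out_dir) -> Path:
    """Write a FrameSequence as a PNG frame directory plus meta.json."""
    import imageio.v3 as iio

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    width = len(str(sequence.n_frames - 1))
    for i, frame in enumerate(sequence.frames):
        iio.imwrite(out_dir / f"frame_{i:0{width}d}.png", frame)
    meta = dict(sequence.meta)
    meta["fps"] = sequence.fps
    (out_dir / "meta.json").write_text(json.dumps(meta))
    return out_dir
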