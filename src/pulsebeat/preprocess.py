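"""Frame preprocessing: grayscale, rescale, denoise, optional enhancement.

Fixed processing order per frame:

1. grayscale conversion (BT.601), if the input is RGB;
2. anisotropic bilinear rescale to a square ``target_size``;
3. median filter (salt-noise robustness);
4. Gaussian blur (sensor noise);
5. optional global histogram equalization.

Equalization is a per-frame rank transform: it is invariant to the global
intensity modulation that carries the pulse, so it flattens the very signal
the rate estimator needs. It is therefore OFF by default and provided as an
explicit opt-in for viewing/contrast purposes.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from skimage.transform import resize

from .errors import ConfigurationError
from .video_io import FrameSequence, to_grayscale


@dataclass(frozen=True)
class PreprocessConfig:
    """Preprocessing parameters.

    target_size:
        Output side length in pixels (square); 227 matches the classic
        227×227 CNN input convention.
    median_kernel:
        Odd median-filter window (1 disables).
    gaussian_sigma:
        Gaussian blur σ in pixels (0 disables).
    enhance:
        Global histogram equalization toggle (default off; see module
        docstring).
    """

    target_size: int = 227
    median_kernel: int = 3
    gaussian_sigma: float = 1.0
    enhance: bool = False

    def __post_init__(self) -> None:
        if self.target_size < 32:
            raise ConfigurationError("target_size must be ≥ 32")
        if self.median_kernel < 1 or self.median_kernel % 2 == 0:
            raise ConfigurationError("median_kernel must be odd and ≥ 1")
        if self.gaussian_sigma < 0:
            raise ConfigurationError("gaussian_sigma must be ≥ 0")


def preprocess_frame(frame: np.ndarray, config: PreprocessConfig) -> np.ndarray:
    """Apply the full preprocessing chain to one frame; returns uint8 gray."""
    if frame.ndim == 3:
        gray = to_grayscale(frame)
    else:
        gray = frame
    size = (config.target_size, config.target_size)
    if gray.shape != size:
        out = resize(gray.astype(np.float64), size, order=1,
                     mode="edge", anti_aliasing=False, preserve_range=True)
    else:
        out = gray.astype(np.float64)
    if config.median_kernel > 1:
        out = ndimage.median_filter(out, size=config.median_kernel,
                                    mode="nearest")
    if config.gaussian_sigma > 0:
        out = ndimage.gaussian_filter(out, sigma=config.gaussian_sigma,
                                      mode="nearest")
    out = np.clip(np.floor(out + 0.5), 0, 255).astype(np.uint8)
    if config.enhance:
        out = equalize_histogram(out)
    return out


def equalize_histogram(gray: np.ndarray) -> np.ndarray:
    """Classic global histogram equalization of a uint8 image.

    Each value v maps to round(255 · cdf(v)) with cdf the empirical
    cumulative distribution; a single occupied bin therefore maps to 255.
    """
    counts = np.bincount(gray.ravel(), minlength=256)
    cdf = np.cumsum(counts) / gray.size
    lut = np.floor(255.0 * cdf + 0.5).astype(np.uint8)
    return lut[gray]


def preprocess_sequence(
    sequence: FrameSequence, config: PreprocessConfig = PreprocessConfig()
) -> FrameSequence:
    """Preprocess every frame; the result's ``gray`` field is populated.

    Output frames are ``target_size × target_size`` grayscale (the RGB
    ``frames`` field holds the channel-replicated twin so both views stay
    consistent).
    """
    gray = [preprocess_frame(f, config) for f in sequence.frames]
    rgb = [np.repeat(g[..., None], 3, axis=2) for g in gray]
    return FrameSequence(
        frames=rgb,
        timestamps=sequence.timestamps,
        fps=sequence.fps,
        gray=gray,
        source_id=sequence.source_id,
        meta=sequence.meta,
    )
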