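"""Feature selection, peak detection, and heartbeat-rate estimation.

The dominant feature series is mined for periodicity: its local maxima mark
beats, successive peak times give inter-beat intervals Δt, and each interval
yields an instantaneous rate 60/Δt bpm. Three estimation modes:

``running`` (default)
    Running mean of instantaneous rates over all peak intervals — the
    physiological reading of the iterative update.
``top2``
    One interval: the time gap between the two largest peaks.
``literal``
    The verbatim printed recurrence
    h_n = [h_n·(counter+1) / ((t−t_p)·60)] / (counter+1), iterated over
    peak events. It algebraically reduces to h_n ← h_n / ((t−t_p)·60) per
    step and is dimensionally inconsistent; it is retained for fidelity and
    flagged non-physiological in reports.

With zero or one detected peak every mode returns the initial rate h_p
(default 60 bpm, the conventional lower bound of the normal resting range).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import List, Optional, Tuple

import numpy as np

from .errors import InputError
from .features import FEATURE_NAMES, FeatureMatrix

DEFAULT_INITIAL_BPM = 60.0
LOW_BPM, HIGH_BPM = 60, 100
MIN_BPM, MAX_BPM = 40.0, 220.0

MODES = ("running", "top2", "literal")


@dataclass
class PeakSet:
    """Detected local maxima of the selected feature series."""

    feature_name: str
    peak_times: np.ndarray
    peak_values: np.ndarray
    series: np.ndarray
    times: np.ndarray

    @property
    def n_peaks(self) -> int:
        return int(self.peak_times.size)

    @property
    def M(self) -> Optional[float]:
        """Mean of the two largest peak values (absent with < 2 peaks)."""
        if self.n_peaks < 2:
            return None
        top2 = np.sort(self.peak_values)[-2:]
        return float(top2.mean())


@dataclass
class RateState:
    """Accumulator of the iterative rate update."""

    h_p: float = DEFAULT_INITIAL_BPM
    h_n: float = DEFAULT_INITIAL_BPM
    counter: int = 0
    t_p: float = 0.0
    t: float = 0.0


@dataclass
class RateEstimate:
    """Final bpm estimate with provenance."""

    bpm: int
    mode: str
    n_peaks_used: int
    pre_ceil: float
    flag: str = "normal"
    warnings: List[str] = field(default_factory=list)
    M: Optional[float] = None
    feature_name: str = ""


def select_feature(matrix: FeatureMatrix,
                   normalize: bool = False) -> Tuple[str, np.ndarray]:
    """Pick the dominant feature column of the matrix.

    literal selection (``normalize=False``): the column whose mean over
    rows is largest. With ``normalize=True`` each column is z-scored over
    rows first and the means of absolute z-scores are compared. Ties go to
    the first column in the fixed order.
    """
    if matrix.values.shape[0] == 0:
        raise InputError("empty feature matrix")
    values = matrix.values
    if normalize:
        mu = values.mean(axis=0)
        sd = values.std(axis=0)
        sd = np.where(sd == 0, 1.0, sd)
        scores = np.abs((values - mu) / sd).mean(axis=0)
    else:
        scores = values.mean(axis=0)
    idx = int(np.argmax(scores))  # argmax returns the first maximum: tie rule
    return FEATURE_NAMES[idx], values[:, idx]


def condition_series(
    series: np.ndarray,
    frame_times: np.ndarray,
    min_bpm: float = MIN_BPM,
    max_bpm: float = MAX_BPM,
) -> np.ndarray:
    """Band-pass the selected feature series to the physiological band.

    A zero-phase Butterworth band-pass over [min_bpm, max_bpm]/60 Hz — the
    standard rPPG conditioning step — removes the DC offset and slow drift
    of the raw statistic as well as super-physiological noise, so each
    cardiac cycle contributes exactly one local maximum. Series too short
    to filter stably (or with an unusable band) are returned unchanged
    apart from mean removal.
    """
    from scipy.signal import butter, filtfilt

    series = np.asarray(series, dtype=float)
    frame_times = np.asarray(frame_times, dtype=float)
    centered = series - series.mean()
    if series.size < 24:
        return centered
    fs = 1.0 / float(np.median(np.diff(frame_times)))
    nyquist = fs / 2.0
    low = (min_bpm / 60.0) / nyquist
    high = min((max_bpm / 60.0) / nyquist, 0.99)
    if not 0 < low < high:
        return centered
    b, a = butter(3, [low, high], btype="band")
    return filtfilt(b, a, centered)


def detect_peaks(
    series: np.ndarray,
    frame_times: np.ndarray,
    min_bpm: float = MIN_BPM,
    max_bpm: float = MAX_BPM,
    feature_name: str = "",
) -> PeakSet:
    """Find beat peaks: strict local maxima with physiological spacing.

    A sample counts as a peak when strictly greater than both neighbors; a
    run of equal values strictly above both its flanks (a sampling plateau,
    e.g. a sinusoid crest landing exactly between two samples) counts as a
    single peak at the plateau midpoint. Peaks closer than 60/max_bpm
    seconds are thinned by repeatedly dropping the smaller of the closest
    offending pair and re-scanning.
    """
    from scipy.signal import find_peaks

    series = np.asarray(series, dtype=float)
    frame_times = np.asarray(frame_times, dtype=float)
    if series.size < 3:
        raise InputError("series must have length ≥ 3")
    if series.size != frame_times.size:
        raise InputError("series and frame_times must align")

    idx, _ = find_peaks(series)  # strict maxima, plateau midpoints
    idx = list(idx)
    min_gap = 60.0 / max_bpm
    idx = _thin_peaks(idx, series, frame_times, min_gap)
    idx = np.asarray(idx, dtype=int)
    return PeakSet(
        feature_name=feature_name,
        peak_times=frame_times[idx] if idx.size else np.empty(0),
        peak_values=series[idx] if idx.size else np.empty(0),
        series=series,
        times=frame_times,
    )


def _thin_peaks(idx, series, times, min_gap):
    idx = list(idx)
    changed = True
    while changed and len(idx) > 1:
        changed = False
        for k in range(len(idx) - 1):
            if times[idx[k + 1]] - times[idx[k]] < min_gap:
                # keep the larger value, drop the smaller, re-scan
                drop = k if series[idx[k]] <= series[idx[k + 1]] else k + 1
                del idx[drop]
                changed = True
                break
    return idx


def estimate_rate(
    peaks: PeakSet,
    mode: str = "running",
    h_p: float = DEFAULT_INITIAL_BPM,
) -> RateEstimate:
    """Estimate bpm from detected peaks; see module docstring for modes."""
    if mode not in MODES:
        raise InputError(f"unknown mode {mode!r}; expected one of {MODES}")
    times = np.asarray(peaks.peak_times, dtype=float)
    if times.size > 1 and not np.all(np.diff(times) > 0):
        raise InputError("peak times must be strictly increasing")

    warnings: List[str] = []
    if times.size < 2:
        pre = float(h_p)
        n_used = 0
    elif mode == "running":
        intervals = np.diff(times)
        rates = 60.0 / intervals
        pre = float(rates.mean())
        n_used = times.size
    elif mode == "top2":
        order = np.argsort(peaks.peak_values)
        t1, t2 = times[order[-1]], times[order[-2]]
        dt = abs(t1 - t2)
        if dt == 0:
            raise InputError("the two largest peaks coincide in time")
        pre = 60.0 / dt
        n_used = 2
    else:  # literal: the printed recurrence, verbatim over peak events
        state = RateState(h_p=h_p, h_n=h_p, t_p=times[0])
        for t in times[1:]:
            state.t = float(t)
            state.h_n = (state.h_n * (state.counter + 1)
                         / ((state.t - state.t_p) * 60.0)) / (state.counter + 1)
            state.counter += 1
            state.t_p = state.t
        pre = state.h_n
        n_used = times.size
        warnings.append("non_physiological")

    bpm = math.ceil(pre)
    if not MIN_BPM <= bpm <= MAX_BPM and n_used > 0:
        warnings.append("outside_physiological_bounds")
    return RateEstimate(
        bpm=bpm,
        mode=mode,
        n_peaks_used=n_used,
        pre_ceil=pre,
        flag=classify_rate(bpm),
        warnings=warnings,
        M=peaks.M,
        feature_name=peaks.feature_name,
    )


def classify_rate(bpm: float, low: float = LOW_BPM,
                  high: float = HIGH_BPM) -> str:
    """Flag a rate as low (< low), high (> high), or normal."""
    if bpm < 0:
        raise InputError("bpm must be ≥ 0")
    if bpm < low:
        return "low"
    if bpm > high:
        return "high"
    return "normal"
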