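"""Per-frame statistical feature battery.

Each preprocessed frame is reduced to a fixed subsample of pixel
intensities, and every frame index i ≥ 2 yields one row of 14 statistics
computed over the 3-frame window (x_{i−2}, x_{i−1}, x_i):

* one-sample summaries of x_i: mean, median, variance (n−1 divisor),
  standard deviation;
* two-sample comparisons of x_i against x_{i−1}: Pearson correlation,
  two-sample chi-square on 16-bin histograms, RMSE of the difference,
  least-squares regression slope, Wilcoxon signed-rank W⁺, Mann–Whitney U
  (midranks), two-sample Kolmogorov–Smirnov D;
* k-sample comparisons over the ordered window: Kruskal–Wallis H,
  Jonckheere–Terpstra J, Friedman chi-square (pixels as blocks).

All values are raw statistics, not p-values: downstream feature selection
mines their magnitude over time, no hypothesis is being tested. The pixel
positions are drawn once and shared across frames so paired statistics are
aligned.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Sequence

import numpy as np
from scipy.stats import rankdata

from .errors import InputError
from .video_io import FrameSequence

#: Fixed column order of the feature matrix.
FEATURE_NAMES = (
    "mean", "median", "variance", "std", "correlation", "chi_square",
    "rmse", "regression_slope", "wilcoxon", "mann_whitney", "ks",
    "kruskal_wallis", "jonckheere", "friedman",
)

CHI_SQUARE_BINS = 16
DEFAULT_MAX_PIXELS = 2048


@dataclass
class PixelSample:
    """Intensity values of one frame at the shared subsample positions."""

    values: np.ndarray
    frame_index: int
    positions: np.ndarray  # (k, 2) row/col indices, identical across frames


@dataclass
class FeatureMatrix:
    """Rows of the 14 named statistics, one per frame index ≥ 2."""

    values: np.ndarray          # (n_rows, 14)
    frame_times: np.ndarray     # seconds, aligned with rows
    frame_indices: np.ndarray

    @property
    def names(self):
        return FEATURE_NAMES

    def column(self, name: str) -> np.ndarray:
        return self.values[:, FEATURE_NAMES.index(name)]

    def to_dataframe(self):
        import pandas as pd

        df = pd.DataFrame(self.values, columns=list(FEATURE_NAMES))
        df.insert(0, "time_s", self.frame_times)
        df.insert(0, "frame_index", self.frame_indices)
        return df


def sample_pixels(
    sequence: FrameSequence,
    max_pixels: int = DEFAULT_MAX_PIXELS,
    seed: int = 0,
) -> List[PixelSample]:
    """Subsample pixel positions once and read them from every gray frame.

    If the frame area is ≤ ``max_pixels`` every pixel is used in row-major
    order; otherwise ``max_pixels`` positions are drawn uniformly without
    replacement from the first frame's grid and reused for all frames.
    """
    seq = sequence.with_gray()
    if seq.n_frames == 0:
        raise InputError("empty sequence")
    h, w = seq.gray[0].shape
    area = h * w
    if area <= max_pixels:
        rows, cols = np.unravel_index(np.arange(area), (h, w))
    else:
        rng = np.random.default_rng(seed)
        flat = rng.choice(area, size=max_pixels, replace=False)
        rows, cols = np.unravel_index(flat, (h, w))
    positions = np.column_stack([rows, cols])
    samples = []
    for i, g in enumerate(seq.gray):
        if g.shape != (h, w):
            raise InputError("all frames must share one shape for sampling")
        samples.append(PixelSample(
            values=g[rows, cols].astype(np.float64),
            frame_index=i,
            positions=positions,
        ))
    return samples


# ---------------------------------------------------------------------------
# individual statistics (raw statistics, authored here; scipy.stats serves
# as the independent cross-check in the test suite)
# ---------------------------------------------------------------------------

def pearson_correlation(x: np.ndarray, y: np.ndarray) -> float:
    """Pearson r; 0 when either sample is constant (undefined case)."""
    xd = x - x.mean()
    yd = y - y.mean()
    denom = np.sqrt((xd ** 2).sum() * (yd ** 2).sum())
    if denom == 0:
        return 0.0
    return float((xd * yd).sum() / denom)


def chi_square_hist(x: np.ndarray, y: np.ndarray,
                    bins: int = CHI_SQUARE_BINS) -> float:
    """Two-sample chi-square on paired equal-width histograms over [0, 255].

    Expected count per bin is the mean of the two observed counts; bins
    empty in both samples are excluded.
    """
    edges = np.linspace(0.0, 255.0, bins + 1)
    ox, _ = np.histogram(x, bins=edges)
    oy, _ = np.histogram(y, bins=edges)
    keep = (ox + oy) > 0
    ox, oy = ox[keep].astype(float), oy[keep].astype(float)
    expected = (ox + oy) / 2.0
    return float((((ox - expected) ** 2 + (oy - expected) ** 2)
                  / expected).sum())


def rmse(x: np.ndarray, y: np.ndarray) -> float:
    return float(np.sqrt(np.mean((x - y) ** 2)))


def regression_slope(x: np.ndarray, y: np.ndarray) -> float:
    """Least-squares slope of y regressed on x; 0 for constant x."""
    xd = x - x.mean()
    sxx = (xd ** 2).sum()
    if sxx == 0:
        return 0.0
    return float((xd * (y - y.mean())).sum() / sxx)


def wilcoxon_signed_rank(x: np.ndarray, y: np.ndarray) -> float:
    """W⁺: sum of ranks of positive paired differences (zeros dropped)."""
    d = x - y
    d = d[d != 0]
    if d.size == 0:
        return 0.0
    ranks = rankdata(np.abs(d))
    return float(ranks[d > 0].sum())


def mann_whitney_u(x: np.ndarray, y: np.ndarray) -> float:
    """U statistic of sample x vs sample y, with midranks for ties."""
    n1 = x.size
    ranks = rankdata(np.concatenate([x, y]))
    r1 = ranks[:n1].sum()
    return float(r1 - n1 * (n1 + 1) / 2.0)


def ks_statistic(x: np.ndarray, y: np.ndarray) -> float:
    """Two-sample Kolmogorov–Smirnov D (max empirical-CDF gap)."""
    xs, ys = np.sort(x), np.sort(y)
    grid = np.concatenate([xs, ys])
    cdf_x = np.searchsorted(xs, grid, side="right") / xs.size
    cdf_y = np.searchsorted(ys, grid, side="right") / ys.size
    return float(np.abs(cdf_x - cdf_y).max())


def _tie_counts(values: np.ndarray) -> np.ndarray:
    _, counts = np.unique(values, return_counts=True)
    return counts[counts > 1]


def kruskal_wallis(groups: Sequence[np.ndarray]) -> float:
    """Kruskal–Wallis H with tie correction; 0 when all values are tied."""
    pooled = np.concatenate(groups)
    n_total = pooled.size
    ranks = rankdata(pooled)
    h = 0.0
    start = 0
    for g in groups:
        r = ranks[start:start + g.size].sum()
        h += r * r / g.size
        start += g.size
    h = 12.0 / (n_total * (n_total + 1)) * h - 3.0 * (n_total + 1)
    ties = _tie_counts(pooled)
    correction = 1.0 - (ties ** 3 - ties).sum() / (n_total ** 3 - n_total)
    if correction == 0:
        return 0.0
    return float(h / correction)


def jonckheere_stat(groups: Sequence[np.ndarray]) -> float:
    """Jonckheere–Terpstra J for an a-priori group ordering.

    J = Σ over ordered group pairs (g < h) of the number of cross pairs
    (x ∈ g, y ∈ h) with x < y, counting ties as ½.
    """
    if len(groups) < 2:
        raise InputError("jonckheere_stat needs ≥ 2 groups")
    arrays = [np.asarray(g, dtype=np.float64) for g in groups]
    for g in arrays:
        if g.size == 0:
            raise InputError("jonckheere_stat: empty group")
    j = 0.0
    for gi in range(len(arrays) - 1):
        g_sorted = np.sort(arrays[gi])
        for hi in range(gi + 1, len(arrays)):
            y = arrays[hi]
            less = np.searchsorted(g_sorted, y, side="left")
            less_or_eq = np.searchsorted(g_sorted, y, side="right")
            j += less.sum() + 0.5 * (less_or_eq - less).sum()
    return float(j)


def friedman_chi_square(groups: Sequence[np.ndarray]) -> float:
    """Friedman chi-square with blocks = paired observations (pixels).

    Midranks within blocks, standard tie correction; fully tied data
    (zero tie-corrected denominator) returns 0.
    """
    data = np.column_stack(groups)  # (n_blocks, k)
    n, k = data.shape
    ranks = rankdata(data, axis=1)
    col_sums = ranks.sum(axis=0)
    stat = (12.0 / (n * k * (k + 1))) * (col_sums ** 2).sum() \
        - 3.0 * n * (k + 1)
    # tie correction Σ(t³−t) over within-block tie runs, vectorized:
    # each element's tie-group size c gives Σ_runs t³ == Σ_elements c².
    c = (data[:, :, None] == data[:, None, :]).sum(axis=2)
    tie_term = float((c.astype(np.float64) ** 2).sum() - n * k)
    denom = 1.0 - tie_term / (n * k * (k * k - 1))
    if denom == 0:
        return 0.0
    return float(stat / denom)


# ---------------------------------------------------------------------------
# the matrix
# ---------------------------------------------------------------------------

def compute_feature_row(x_prev2: np.ndarray, x_prev: np.ndarray,
                        x_cur: np.ndarray) -> np.ndarray:
    """One feature-matrix row from the 3-frame window ending at x_cur."""
    var = float(np.var(x_cur, ddof=1))
    window = (x_prev2, x_prev, x_cur)
    return np.array([
        float(np.mean(x_cur)),
        float(np.median(x_cur)),
        var,
        float(np.sqrt(var)),
        pearson_correlation(x_cur, x_prev),
        chi_square_hist(x_cur, x_prev),
        rmse(x_cur, x_prev),
        regression_slope(x_prev, x_cur),
        wilcoxon_signed_rank(x_cur, x_prev),
        mann_whitney_u(x_cur, x_prev),
        ks_statistic(x_cur, x_prev),
        kruskal_wallis(window),
        jonckheere_stat(window),
        friedman_chi_square(window),
    ])


def compute_feature_matrix(
    samples: List[PixelSample], frame_times: np.ndarray
) -> FeatureMatrix:
    """Compute the full matrix; rows start at frame index 2 (window warm-up)."""
    if len(samples) < 3:
        raise InputError("need at least 3 frames for the 3-frame window")
    frame_times = np.asarray(frame_times, dtype=float)
    if frame_times.size != len(samples):
        raise InputError("frame_times must align with samples")
    rows, times, indices = [], [], []
    for i in range(2, len(samples)):
        rows.append(compute_feature_row(
            samples[i - 2].values, samples[i - 1].values, samples[i].values
        ))
        times.append(frame_times[i])
        indices.append(samples[i].frame_index)
    values = np.vstack(rows)
    if not np.all(np.isfinite(values)):
        raise InputError("non-finite feature value computed")
    return FeatureMatrix(
        values=values,
        frame_times=np.asarray(times),
        frame_indices=np.asarray(indices),
    )
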