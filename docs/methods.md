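# Methods

## Signal model and rationale

Remote photoplethysmography rests on one physical fact: each cardiac cycle
modulates the blood volume in skin capillaries, which modulates skin
reflectance by a few intensity units out of 255 in an 8-bit camera. The
pipeline therefore needs (a) a skin region, (b) a per-frame scalar (or
vector) summary whose time series inherits that modulation, and (c) a
periodicity estimator robust to the summary's arbitrary scale.

This package summarizes each frame by 14 classical statistics computed on a
fixed subsample of skin pixels. One-sample summaries (mean, median,
variance, standard deviation) respond to the global intensity level;
two-sample statistics comparing a frame with its predecessor (Pearson r,
two-sample χ² on 16-bin histograms, RMSE, regression slope, Wilcoxon W⁺,
Mann–Whitney U, Kolmogorov–Smirnov D) respond to the frame-to-frame shift;
k-sample statistics over a 3-frame window (Kruskal–Wallis H,
Jonckheere–Terpstra J, Friedman χ²) respond to monotone trends across the
window. All are used as raw statistics: no p-values, no multiple-testing
machinery — the downstream selector only needs a magnitude that oscillates
at the pulse frequency.

In practice the Jonckheere–Terpstra column dominates the literal
largest-mean selection: J counts concordant cross-frame pixel pairs, so its
magnitude is of order n² (≈ 6.3·10⁶ at n = 2048 pixels and 3 groups) and its
deviation from the null mid-value is a monotone function of the intensity
shift across the window — effectively a U-statistic encoding of the signal's
discrete derivative, which oscillates at exactly the pulse frequency.

## Algorithmic choices

**Pixel subsampling.** Positions are drawn once per sequence, uniformly
without replacement (default cap 2048 of 227² pixels), and reused for every
frame so paired statistics stay aligned. Small frames are enumerated
row-major. The cap bounds the O(n log n)–O(n²̃) statistic costs while keeping
U-statistic standard errors (∝ 1/√n on the probability scale) far below the
signal amplitude.

**Window warm-up.** The first two frames produce no feature rows; row times
start at frame index 2.

**Degenerate-input conventions.** Constant samples make Pearson r and the
regression slope undefined (zero variance in the predictor): both return 0.
Fully tied k-sample windows zero the tie-corrected Kruskal–Wallis and
Friedman denominators: both return 0. Wilcoxon drops zero differences;
ranks are midranks throughout.

**Feature selection.** Literal mode picks the column with the largest mean
over rows (ties → first column in the fixed order). A normalized mode
(z-score per column, compare means of |z|) is provided for scale-free
comparisons but is not the default.

**Series conditioning.** The selected series is band-passed (zero-phase
3rd-order Butterworth) to the physiological band [min_bpm, max_bpm]/60 Hz
(defaults 40–220 bpm) before peak detection — the standard rPPG step. It
removes the statistic's DC offset and drift and suppresses
super-physiological noise so each cardiac cycle contributes one local
maximum. Series shorter than 24 samples are only mean-centered (filtfilt
needs stable padding). Disable with `RunConfig(bandpass=False)`.

**Peak detection.** Strict local maxima; a run of equal values above both
flanks (a sampling plateau — e.g. a sinusoid crest landing exactly between
two samples) counts as one peak at the plateau midpoint. Peaks closer than
60/max_bpm s are thinned by repeatedly dropping the smaller of the closest
offending pair.

**Rate estimation.** `running` (default): mean of instantaneous rates 60/Δt
over successive peak intervals, then ceil. `top2`: one interval, between
the two largest peaks. `literal`: a verbatim historical recurrence
h_n ← [h_n·(counter+1)/((t−t_p)·60)]/(counter+1), which reduces to
h_n ← h_n/((t−t_p)·60) per event; it is dimensionally inconsistent, is kept
only so the original formulation stays executable, and always carries a
`non_physiological` warning. Zero or one peak → the initial rate h_p = 60
bpm (the conventional lower bound of the normal resting range) in every
mode. Flags: low < 60, high > 100 bpm. Estimates outside 40–220 bpm are
warned about, never clipped.

Note the running mean of 60/Δt is Jensen-biased slightly above 60/mean(Δt)
under interval jitter; combined with the ceil this makes the estimator err
high by ≤ 2 bpm at low rates — visible in the worked example (72 → 74).

## Preprocessing

Fixed order per frame: grayscale (BT.601 luma 0.299/0.587/0.114, half-up
rounding) → anisotropic bilinear resize to square `target_size` (default
227, the classic CNN input side; crops are near-square so anisotropy is
mild) → median filter (default 3×3; salt noise) → Gaussian blur (default
σ = 1 px; sensor noise) → optional global histogram equalization.

Equalization is **off by default**: it is a per-frame rank transform, hence
invariant to the global intensity shift that carries the pulse — with it on,
every frame's histogram is flattened identically and the feature series
goes flat. It is implemented (classic uint8 CDF lookup, v ↦ round(255·cdf(v)),
so a single occupied bin maps to 255) for contrast/visualization use.

## ROI detection

`skin_chroma` is the self-contained default: full-range (JFIF) YCbCr
thresholds 77 ≤ Cb ≤ 127, 133 ≤ Cr ≤ 173 — the classical skin-color
cluster — then the bounding box of the largest connected component.
`cascade` delegates to a pre-trained Haar cascade when OpenCV and a model
file are present and downgrades to `skin_chroma` with a logged warning
otherwise. Boxes smaller than 8 px a side are treated as no detection; a
frame without detection inherits the previous frame's box, and frame 0
falls back to a centered box covering half of each dimension. Multiple
detections keep the largest area. Per-frame jitter is not smoothed by
default; a window-5 median filter over box coordinates is available.

## Synthetic data

`generate_video` renders a skin-toned ellipse (default RGB 200/160/140,
covering ~28% of a 128-px frame) whose pixels follow
`base + A·sin(2π·(bpm/60)·t) + drift·t + N(0, σ)` per channel (one shared
noise draw per pixel), clipped to [0, 255], over a constant background of
64 + noise; `generate_signal` produces the 1-D series alone. All randomness
flows from a single `numpy` generator seeded per call. Defaults — 30 fps,
10 s, amplitude 4, σ = 2, no drift, no jitter — emulate a short webcam clip
where the pulse is of the same order as per-pixel sensor noise.

What the generator does *not* emulate: real PPG waveform shape (dicrotic
notch, systolic/diastolic asymmetry), heart-rate variability, motion and
occlusion, specular highlights, compression artifacts, or illumination
color shifts. Passing the recovery tests therefore demonstrates the
pipeline's signal path and estimator are correct for a periodic skin-region
modulation; it does not certify accuracy on real subjects.

A quantization note: at amplitude ≈ 4 the uint8 quantizer is coarse relative
to the signal, and moderate per-pixel noise *dithers* it — so the noiseless
case is consistently ~1 bpm worse than σ = 2–10, and recovery error is
monotone in σ only for σ ≥ 2. The tests encode exactly that.

## Problem sizes and tolerances

Recovery tests run 10-s clips at 30 fps and 128-px frames (300 frames,
≤ 2048 sampled pixels), the package's reference study condition; module
tests use 4-s, 64-px clips. Statistic implementations are verified against
independent references (scipy.stats, stdlib `statistics`, brute-force
enumeration for Jonckheere–Terpstra and the histogram χ²) to 1e-8 relative
on 50 seeded windows. Benchmark-table error cells are compared to their
printed values within 0.002 absolute (the printed tables mix half-up
rounding and truncation). Recovery asserts ±2 bpm at σ = 2 over
bpm ∈ {60, 72, 90, 120} × seeds {1, 2, 3}.

## Known limitations

- The benchmark tables' published summary MAE/MSE figures are not
  arithmetic consequences of their own printed pairs; the evaluation module
  always reports values recomputed from the pairs (table3: MAE 0.35,
  MSE 0.45; table4: MAE 0.15, MSE 0.25).
- Video-container ingestion requires an imageio video plugin (e.g.
  imageio-ffmpeg); frame directories and npz bundles are always available.
- Single-ROI, single-subject scenes only; no tracking through occlusion.
- One global estimate per clip; no sliding-window bpm trace or HRV metrics.
- The `literal` estimation mode is a fidelity artifact, not a usable
  estimator.
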