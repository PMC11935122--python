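"""Hallucination detection for denoised time series.

A denoising network shown pure noise will still invent plausible-looking
structure.  Two complementary checks flag such frames:

* temporally — adjacent frames of a real moving organelle stay similar,
  while predictions hallucinated from empty fields decorrelate; comparing
  the adjacent-frame SSIM trace of a prediction movie against the trace of
  a detector dark-noise movie separates the two regimes;
* spatially — pixels of the LOW-intensity input are classified as
  background / uncertain / signal from the photon counts in a sliding
  window, directing attention to regions where the prediction is
  unsupported by signal.  The classification never looks at the prediction.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .metrics import ssim

__all__ = [
    "PixelConfidenceMap",
    "SimilarityTrace",
    "HallucinationReport",
    "LABEL_BACKGROUND",
    "LABEL_UNCERTAIN",
    "LABEL_SIGNAL",
    "adjacent_frame_ssim",
    "classify_pixels",
    "hallucination_report",
]

LABEL_BACKGROUND, LABEL_UNCERTAIN, LABEL_SIGNAL = 0, 1, 2


@dataclass
class PixelConfidenceMap:
    """Per-pixel confidence labels from windowed photon sums.

    ``labels`` holds 0 (background), 1 (uncertain) or 2 (signal); the
    thresholds apply to the windowed intensity sum, not single pixels.
    """

    labels: np.ndarray
    window_px: int
    t_background: float
    t_signal: float

    def fraction(self, label: int) -> float:
        return float(np.count_nonzero(self.labels == label)) / self.labels.size


@dataclass
class SimilarityTrace:
    """Adjacent-frame SSIM values; entry t compares frames t and t+1."""

    values: np.ndarray
    frame_interval_s: float | None = None

    @property
    def mean(self) -> float:
        return float(np.mean(self.values))

    @property
    def sd(self) -> float:
        return float(np.std(self.values, ddof=1)) if self.values.size > 1 else 0.0


@dataclass
class HallucinationReport:
    """Prediction trace vs dark-noise reference trace, with per-transition flags.

    Transition t (frames t -> t+1) is flagged as a possible hallucination
    when its SSIM does not exceed the dark-noise band mean + n_sd * sd —
    i.e. the frames are no more alike than pure detector noise.
    """

    pred_trace: SimilarityTrace
    dark_trace: SimilarityTrace
    flags: np.ndarray
    n_sd: float

    @property
    def n_flagged(self) -> int:
        return int(np.count_nonzero(self.flags))


def adjacent_frame_ssim(movie: np.ndarray, data_range: float,
                        frame_interval_s: float | None = None) -> SimilarityTrace:
    """SSIM between every pair of adjacent frames of a (t, y, x) movie."""
    movie = np.asarray(movie, dtype=np.float64)
    if movie.ndim != 3:
        raise ValueError("movie must have shape (t, y, x)")
    if movie.shape[0] < 2:
        raise ValueError("adjacent-frame SSIM needs at least 2 frames")
    values = np.array([
        ssim(movie[t], movie[t + 1], data_range=data_range)
        for t in range(movie.shape[0] - 1)
    ])
    return SimilarityTrace(values=values, frame_interval_s=frame_interval_s)


def windowed_sums(image: np.ndarray, window_px: int) -> np.ndarray:
    """Sum of intensities in a window centered on each pixel, reflect-padded.

    For an even window the extra row/column sits toward larger indices:
    a 10-px window around pixel i covers i-4 .. i+5.  Borders are padded
    by mirror reflection without repeating the edge pixel (numpy
    ``mode='reflect'``).  Computed with an integral image, so sums over
    integer inputs are exact.
    """
    image = np.asarray(image, dtype=np.float64)
    if image.ndim != 2:
        raise ValueError("image must be 2D")
    before = (window_px - 1) // 2
    after = window_px // 2
    if before >= image.shape[0] or before >= image.shape[1]:
        raise ValueError("window too large for the image (reflect pad undefined)")
    padded = np.pad(image, ((before, after), (before, after)), mode="reflect")
    # integral image with a zero first row/col
    ii = np.zeros((padded.shape[0] + 1, padded.shape[1] + 1))
    np.cumsum(np.cumsum(padded, axis=0), axis=1, out=ii[1:, 1:])
    h, w = image.shape
    k = window_px
    return (ii[k:k + h, k:k + w] - ii[:h, k:k + w]
            - ii[k:k + h, :w] + ii[:h, :w])


def classify_pixels(low_intensity: np.ndarray, window_px: int = 10,
                    t_background: float = 5.0,
                    t_signal: float = 25.0) -> PixelConfidenceMap:
    """Classify low-intensity-input pixels as background/uncertain/signal.

    Each pixel's windowed photon sum (see :func:`windowed_sums`) is
    thresholded: background if sum <= ``t_background``, uncertain if in
    (``t_background``, ``t_signal``], signal if above ``t_signal``.  For
    integer counts and the defaults (5, 25) this is exactly the grouping
    "<= 5 background, 6-25 uncertain, > 25 signal".  Window size and
    thresholds must be adapted per use case.
    """
    low_intensity = np.asarray(low_intensity)
    if np.any(low_intensity < 0):
        raise ValueError("counts must be nonnegative")
    if t_background >= t_signal:
        raise ValueError("t_background must be < t_signal")
    if window_px > 2 * min(low_intensity.shape):
        raise ValueError("window larger than twice the image extent")
    sums = windowed_sums(low_intensity, window_px)
    labels = np.full(low_intensity.shape, LABEL_UNCERTAIN, dtype=np.uint8)
    labels[sums <= t_background] = LABEL_BACKGROUND
    labels[sums > t_signal] = LABEL_SIGNAL
    return PixelConfidenceMap(labels=labels, window_px=window_px,
                              t_background=t_background, t_signal=t_signal)


def hallucination_report(pred_movie: np.ndarray, dark_movie: np.ndarray,
                         data_range: float, n_sd: float = 2.0,
                         dark_data_range: float | None = None) -> HallucinationReport:
    """Compare a prediction movie's SSIM trace against a dark-noise reference.

    Both movies need >= 2 frames.  Transition t of the prediction movie is
    flagged when its adjacent-frame SSIM falls at or below
    ``mean + n_sd * sd`` of the dark-noise trace: such a transition is no
    more self-consistent than detector noise, so the frames around it may
    be hallucinated.

    Each trace is scored against its own movie's dynamic range: sparse dark
    counts judged on a bright movie's range would look spuriously similar
    (near-zero frames agree almost everywhere).  ``dark_data_range``
    defaults to the dark movie's max - min (floor 1).
    """
    if dark_data_range is None:
        dark_movie = np.asarray(dark_movie, dtype=np.float64)
        dark_data_range = max(float(dark_movie.max() - dark_movie.min()), 1.0)
    pred_trace = adjacent_frame_ssim(pred_movie, data_range=data_range)
    dark_trace = adjacent_frame_ssim(dark_movie, data_range=dark_data_range)
    cutoff = dark_trace.mean + n_sd * dark_trace.sd
    flags = pred_trace.values <= cutoff
    return HallucinationReport(pred_trace=pred_trace, dark_trace=dark_trace,
                               flags=flags, n_sd=n_sd)
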