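"""Full-reference image quality metrics and FRC-based resolution.

The metric suite (MAE, SSIM, PSNR, Pearson) compares a denoised prediction
against its high-dose ground truth.  Resolution is estimated by Fourier
ring correlation (FRC): the correlation of two images' Fourier spectra per
frequency ring; the first frequency where the curve drops below 1/7
defines the resolution as 1/f.  A rolling (blockwise) FRC produces a
spatial map of local resolution; blocks with near-background intensity in
both images are excluded.

``total_score`` ranks model runs by combining SSIM, MAE and resolution,
each linearly transformed to [0, 1] across the cohort (1 = best).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage, stats
from skimage.metrics import structural_similarity

__all__ = [
    "FRCCurve",
    "RFRCMap",
    "QCReport",
    "ModelRunRecord",
    "mae",
    "ssim",
    "psnr",
    "pearson",
    "frc_curve",
    "frc_resolution",
    "rfrc_map",
    "total_score",
    "qc_report",
]


def _check_shapes(a: np.ndarray, b: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    a = np.asarray(a, dtype=np.float64)
    b = np.asarray(b, dtype=np.float64)
    if a.shape != b.shape:
        raise ValueError(f"shape mismatch: {a.shape} vs {b.shape}")
    return a, b


def mae(a: np.ndarray, b: np.ndarray) -> float:
    """Mean absolute difference of pixel values."""
    a, b = _check_shapes(a, b)
    return float(np.mean(np.abs(a - b)))


def ssim(a: np.ndarray, b: np.ndarray, data_range: float) -> float:
    """Structural similarity index, Gaussian-weighted 11x11 window.

    Standard constants K1=0.01, K2=0.03, sigma=1.5, averaged over the image.
    """
    a, b = _check_shapes(a, b)
    if data_range <= 0:
        raise ValueError("data_range must be positive")
    return float(structural_similarity(
        a, b, data_range=data_range, gaussian_weights=True, sigma=1.5,
        win_size=11, use_sample_covariance=False, K1=0.01, K2=0.03))


def psnr(a: np.ndarray, b: np.ndarray, data_range: float) -> float:
    """Peak signal-to-noise ratio in dB; ``inf`` for identical images.

    The infinite sentinel (rather than an exception) keeps batch reports
    from aborting on a perfect pair.
    """
    a, b = _check_shapes(a, b)
    if data_range <= 0:
        raise ValueError("data_range must be positive")
    mse = float(np.mean((a - b) ** 2))
    if mse == 0.0:
        return math.inf
    return float(10.0 * np.log10(data_range**2 / mse))


def pearson(a: np.ndarray, b: np.ndarray) -> float:
    """Pearson correlation of the flattened pixel vectors."""
    a, b = _check_shapes(a, b)
    if np.std(a) == 0 or np.std(b) == 0:
        raise ValueError("Pearson correlation undefined for zero-variance image")
    return float(stats.pearsonr(a.ravel(), b.ravel()).statistic)


@dataclass
class FRCCurve:
    """Per-ring Fourier correlation between two images of one scene.

    ``ring_frequencies`` are ring-center spatial frequencies in cycles/nm,
    strictly increasing and bounded by Nyquist = 1/(2 * pixel size); the
    zero-frequency (DC) term is excluded.
    """

    ring_frequencies: np.ndarray
    correlations: np.ndarray
    pixel_size_nm: float


@dataclass
class RFRCMap:
    """Blockwise local resolution map in nm.

    ``block_resolutions_nm`` is NaN where a block was background
    (mean intensity <= ``background_intensity`` in both inputs).
    """

    block_resolutions_nm: np.ndarray
    block_size_px: int
    stride_px: int
    background_intensity: float
    threshold: float
    pixel_size_nm: float

    @property
    def valid(self) -> np.ndarray:
        return ~np.isnan(self.block_resolutions_nm)

    @property
    def mean_resolution_nm(self) -> float:
        return float(np.nanmean(self.block_resolutions_nm))

    @property
    def min_resolution_nm(self) -> float:
        return float(np.nanmin(self.block_resolutions_nm))


@dataclass
class QCReport:
    """One row of full-reference QC for a prediction/ground-truth pair."""

    mae: float
    ssim: float
    psnr: float
    pearson: float
    mean_resolution_nm: float | None = None
    min_resolution_nm: float | None = None


@dataclass
class ModelRunRecord:
    """Metrics of one trained-model run, plus its cohort total score."""

    run_id: str
    ssim: float
    mae: float
    resolution_nm: float
    total_score: float | None = field(default=None)


def _hann2d(shape: tuple[int, int]) -> np.ndarray:
    wy = np.hanning(shape[0])
    wx = np.hanning(shape[1])
    return np.outer(wy, wx)


def _center_crop_square(img: np.ndarray) -> np.ndarray:
    h, w = img.shape
    n = min(h, w)
    r0 = (h - n) // 2
    c0 = (w - n) // 2
    return img[r0:r0 + n, c0:c0 + n]


def frc_curve(a: np.ndarray, b: np.ndarray, pixel_size_nm: float) -> FRCCurve:
    """Fourier ring correlation between two images of the same scene.

    Both images are Hann-apodized, Fourier transformed, and correlated
    ring by ring (rings one frequency bin wide): the real part of the
    ring-summed cross-spectrum over the geometric mean of the ring-summed
    power spectra.  Non-square inputs are center-cropped to square.
    """
    a, b = _check_shapes(a, b)
    a = _center_crop_square(a)
    b = _center_crop_square(b)
    n = a.shape[0]
    win = _hann2d(a.shape)
    fa = np.fft.fftshift(np.fft.fft2(a * win))
    fb = np.fft.fftshift(np.fft.fft2(b * win))

    cy = cx = n // 2
    yy, xx = np.indices((n, n))
    radius = np.hypot(yy - cy, xx - cx)
    rbin = np.round(radius).astype(int)
    n_rings = n // 2  # rings 1..n//2-1 are fully inside the square

    cross = fa * np.conj(fb)
    num = ndimage.sum_labels(cross.real, rbin, index=np.arange(n_rings))
    pa = ndimage.sum_labels(np.abs(fa) ** 2, rbin, index=np.arange(n_rings))
    pb = ndimage.sum_labels(np.abs(fb) ** 2, rbin, index=np.arange(n_rings))

    with np.errstate(invalid="ignore", divide="ignore"):
        corr = num / np.sqrt(pa * pb)
    corr = np.nan_to_num(corr, nan=0.0)

    freqs = np.arange(n_rings) / (n * pixel_size_nm)  # cycles/nm
    # drop the DC ring
    return FRCCurve(ring_frequencies=freqs[1:], correlations=corr[1:],
                    pixel_size_nm=pixel_size_nm)


def frc_resolution(curve: FRCCurve, threshold: float = 1.0 / 7.0,
                   smooth_rings: int = 3) -> tuple[float, bool]:
    """Resolution in nm from an FRC curve: 1 / (first crossing below threshold).

    The curve is lightly smoothed (``smooth_rings``-ring moving average) so
    a single noisy ring cannot set the crossing; the crossing frequency is
    linearly interpolated between rings.  If the curve never drops below the
    threshold the Nyquist bound 2 * pixel size is returned with
    ``at_nyquist=True``.

    Returns ``(resolution_nm, at_nyquist)``.
    """
    corr = np.asarray(curve.correlations, dtype=np.float64)
    freqs = np.asarray(curve.ring_frequencies, dtype=np.float64)
    if corr.size == 0:
        raise ValueError("empty FRC curve")
    if smooth_rings > 1:
        kernel = np.ones(smooth_rings) / smooth_rings
        # reflect-pad so the ends keep full support
        pad = smooth_rings // 2
        padded = np.pad(corr, pad, mode="edge")
        corr = np.convolve(padded, kernel, mode="valid")[:freqs.size]

    below = corr < threshold
    nyquist_res = 2.0 * curve.pixel_size_nm
    if not below.any():
        return nyquist_res, True
    i = int(np.argmax(below))
    if i == 0:
        return float(1.0 / freqs[0]), False
    # linear interpolation between ring i-1 (above) and ring i (below)
    f0, f1 = freqs[i - 1], freqs[i]
    c0, c1 = corr[i - 1], corr[i]
    fstar = f0 + (c0 - threshold) * (f1 - f0) / (c0 - c1)
    res = float(1.0 / fstar)
    return max(res, nyquist_res), res <= nyquist_res


def rfrc_map(a: np.ndarray, b: np.ndarray, pixel_size_nm: float,
             block_size_px: int = 64, stride_px: int = 16,
             threshold: float = 1.0 / 7.0,
             background_intensity: float = 20.0) -> RFRCMap:
    """Rolling FRC: blockwise local resolution map.

    FRC resolution is computed on each block pair along a stride grid.
    Blocks whose mean intensity is <= ``background_intensity`` in BOTH
    images carry no structure to correlate and are marked invalid (NaN).
    Raises if every block is background.
    """
    a, b = _check_shapes(a, b)
    h, w = a.shape
    if block_size_px > min(h, w):
        raise ValueError("block_size_px exceeds image size")
    rows = range(0, h - block_size_px + 1, stride_px)
    cols = range(0, w - block_size_px + 1, stride_px)
    out = np.full((len(rows), len(cols)), np.nan)
    for i, r in enumerate(rows):
        for j, c in enumerate(cols):
            pa = a[r:r + block_size_px, c:c + block_size_px]
            pb = b[r:r + block_size_px, c:c + block_size_px]
            if pa.mean() <= background_intensity and pb.mean() <= background_intensity:
                continue
            curve = frc_curve(pa, pb, pixel_size_nm)
            res, _ = frc_resolution(curve, threshold=threshold)
            out[i, j] = res
    if np.all(np.isnan(out)):
        raise ValueError("all blocks are background; no resolution to report")
    return RFRCMap(out, block_size_px, stride_px, background_intensity,
                   threshold, pixel_size_nm)


def total_score(runs: list[ModelRunRecord]) -> list[ModelRunRecord]:
    """Cohort total score: mean of three [0, 1]-transformed metrics.

    SSIM is transformed so the cohort maximum maps to 1; MAE and
    resolution (lower is better) so the cohort minimum maps to 1.  A metric
    constant across the cohort contributes 0.5 to every run.  Returns the
    records sorted by descending total score.
    """
    if len(runs) < 2:
        raise ValueError("total score needs a cohort of >= 2 runs")
    for r in runs:
        for v in (r.ssim, r.mae, r.resolution_nm):
            if not math.isfinite(v):
                raise ValueError(f"non-finite metric in run {r.run_id!r}")

    def transform(values: np.ndarray, higher_better: bool) -> np.ndarray:
        lo, hi = values.min(), values.max()
        if hi == lo:
            return np.full_like(values, 0.5)
        scaled = (values - lo) / (hi - lo)
        return scaled if higher_better else 1.0 - scaled

    ssims = transform(np.array([r.ssim for r in runs]), higher_better=True)
    maes = transform(np.array([r.mae for r in runs]), higher_better=False)
    ress = transform(np.array([r.resolution_nm for r in runs]), higher_better=False)
    totals = (ssims + maes + ress) / 3.0
    scored = [ModelRunRecord(r.run_id, r.ssim, r.mae, r.resolution_nm, float(t))
              for r, t in zip(runs, totals)]
    return sorted(scored, key=lambda r: -r.total_score)


def qc_report(pred: np.ndarray, truth: np.ndarray, pixel_size_nm: float,
              data_range: float | None = None,
              with_resolution: bool = True, **rfrc_kwargs) -> QCReport:
    """All full-reference metrics for one prediction/ground-truth pair."""
    pred, truth = _check_shapes(pred, truth)
    if data_range is None:
        data_range = float(truth.max() - truth.min()) or 1.0
    report = QCReport(
        mae=mae(pred, truth),
        ssim=ssim(pred, truth, data_range=data_range),
        psnr=psnr(pred, truth, data_range=data_range),
        pearson=pearson(pred, truth),
    )
    if with_resolution:
        rmap = rfrc_map(pred, truth, pixel_size_nm, **rfrc_kwargs)
        report.mean_resolution_nm = rmap.mean_resolution_nm
        report.min_resolution_nm = rmap.min_resolution_nm
    return report
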