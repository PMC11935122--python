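"""Rescaling of normalized network predictions onto ground-truth intensities.

Denoising networks emit images on a normalized scale; before quality
metrics are meaningful the predictions must be mapped back onto the pixel
distribution of the high-dose ground truth.  A single global affine map
(scale, offset) is fitted by ordinary least squares over all pooled
training-pair pixels, and outputs are clipped to the 1st/99th percentile
band of the pooled ground-truth pixels.  The fit uses training pairs only;
test frames are deliberately never seen by it.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import yaml

__all__ = ["RescaleParams", "fit_rescale", "apply_rescale",
           "save_rescale_params", "load_rescale_params"]


@dataclass(frozen=True)
class RescaleParams:
    """Affine map plus clip band learned from training pairs.

    ``clip_low``/``clip_high`` are the 1st/99th percentiles of the pooled
    ground-truth training pixels (linear interpolation between order
    statistics).  Clipping is applied after the affine map.
    """

    scale: float
    offset: float
    clip_low: float
    clip_high: float
    n_training_pixels: int

    def __post_init__(self) -> None:
        if not np.isfinite(self.scale) or self.scale == 0:
            raise ValueError("scale must be finite and nonzero")
        if self.clip_low > self.clip_high:
            raise ValueError("clip_low must be <= clip_high")


def fit_rescale(predictions: Sequence[np.ndarray],
                ground_truths: Sequence[np.ndarray]) -> RescaleParams:
    """Fit (scale, offset) by OLS over pooled training-pair pixels.

    Minimizes sum((scale * p + offset - g)^2) over all pixels of all pairs;
    pairs must be pixel-aligned and same-shape.  Requires >= 1000 pooled
    pixels and non-constant predictions.
    """
    if len(predictions) != len(ground_truths) or len(predictions) == 0:
        raise ValueError("need equal-length, nonempty prediction/truth sequences")
    ps, gs = [], []
    for p, g in zip(predictions, ground_truths):
        p = np.asarray(p, dtype=np.float64)
        g = np.asarray(g, dtype=np.float64)
        if p.shape != g.shape:
            raise ValueError(f"pair shape mismatch: {p.shape} vs {g.shape}")
        ps.append(p.ravel())
        gs.append(g.ravel())
    x = np.concatenate(ps)
    y = np.concatenate(gs)
    if x.size < 1000:
        raise ValueError(f"need >= 1000 training pixels, got {x.size}")
    if np.ptp(x) == 0:
        raise ValueError("degenerate fit: prediction pixels are constant")
    # closed-form simple linear regression
    xm, ym = x.mean(), y.mean()
    scale = float(np.dot(x - xm, y - ym) / np.dot(x - xm, x - xm))
    offset = float(ym - scale * xm)
    clip_low, clip_high = np.percentile(y, [1.0, 99.0])
    return RescaleParams(scale=scale, offset=offset,
                         clip_low=float(clip_low), clip_high=float(clip_high),
                         n_training_pixels=int(x.size))


def apply_rescale(image: np.ndarray, params: RescaleParams) -> np.ndarray:
    """Affine-map an image and clip to the learned percentile band."""
    image = np.asarray(image, dtype=np.float64)
    out = params.scale * image + params.offset
    return np.clip(out, params.clip_low, params.clip_high)


def save_rescale_params(params: RescaleParams, path: str | Path) -> None:
    """Serialize parameters to a small YAML sidecar."""
    doc = asdict(params)
    doc["clip_order"] = "affine_then_clip"
    Path(path).write_text(yaml.safe_dump(doc, sort_keys=True))


def load_rescale_params(path: str | Path) -> RescaleParams:
    doc = yaml.safe_load(Path(path).read_text())
    doc.pop("clip_order", None)
    return RescaleParams(**doc)
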