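"""TIFF stack I/O with mandatory physical metadata.

Images travel as multi-page TIFF (uint16 for photon counts, float32 for
normalized predictions, uint8 for label maps) with a YAML sidecar carrying
pixel size, frame interval, seed and generation parameters.  Pixel size is
never inferred: it must come from the sidecar or an explicit argument.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import tifffile
import yaml

__all__ = ["StackMeta", "read_stack", "write_stack", "sidecar_path"]


@dataclass
class StackMeta:
    """Physical metadata for a stack; pixel size is mandatory."""

    pixel_size_nm: float
    frame_interval_s: float | None = None
    rng_seed: int | None = None
    extra: dict | None = None

    def __post_init__(self) -> None:
        if self.pixel_size_nm is None or self.pixel_size_nm <= 0:
            raise ValueError("pixel_size_nm is mandatory and must be positive")


def sidecar_path(path: str | Path) -> Path:
    return Path(path).with_suffix(Path(path).suffix + ".yaml")


def write_stack(path: str | Path, data: np.ndarray, meta: StackMeta) -> None:
    """Write a frame (y, x) or stack (t, y, x) as TIFF plus YAML sidecar.

    Singleton leading axes are dropped, so a 1-frame stack reads back as a
    single Frame.
    """
    data = np.asarray(data)
    if data.ndim == 3 and data.shape[0] == 1:
        data = data[0]
    if data.ndim not in (2, 3):
        raise ValueError("data must be 2D (y, x) or 3D (t, y, x)")
    tifffile.imwrite(Path(path), data, photometric="minisblack")
    doc = {
        "pixel_size_nm": float(meta.pixel_size_nm),
        "frame_interval_s": meta.frame_interval_s,
        "rng_seed": meta.rng_seed,
        "extra": meta.extra or {},
    }
    sidecar_path(path).write_text(yaml.safe_dump(doc, sort_keys=True))


def read_stack(path: str | Path,
               pixel_size_nm: float | None = None) -> tuple[np.ndarray, StackMeta]:
    """Read a TIFF; returns ``(array, meta)``.

    Single-page files come back 2D (a Frame), multi-page as (t, y, x).
    Pixel size is taken from the sidecar if present, else from the
    ``pixel_size_nm`` argument; missing in both is a hard error.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    data = tifffile.imread(path)
    if data.ndim not in (2, 3):
        raise ValueError(f"unsupported TIFF dimensionality: {data.ndim}")
    sc = sidecar_path(path)
    meta_doc: dict = {}
    if sc.exists():
        meta_doc = yaml.safe_load(sc.read_text()) or {}
    px = meta_doc.get("pixel_size_nm", pixel_size_nm)
    if px is None:
        raise ValueError(
            f"pixel size for {path.name} not found in sidecar and not given; "
            "physical units are never silently assumed")
    meta = StackMeta(pixel_size_nm=float(px),
                     frame_interval_s=meta_doc.get("frame_interval_s"),
                     rng_seed=meta_doc.get("rng_seed"),
                     extra=meta_doc.get("extra") or {})
    return data, meta
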