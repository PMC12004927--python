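"""Calibrated image containers and TIFF/CSV I/O.

All imagery is grayscale with intensities in [0, 1].  Physical calibration
(micrometres per pixel, Z-step, frame rate) travels with the container and is
persisted in a JSON sidecar next to each multi-page TIFF, because plain TIFF
tags are too lossy to serve as the single source of truth.

Coordinate convention (used package-wide): 0-based pixel indices, ``x``
rightward (columns), ``y`` downward (rows), ``z`` upward from the dish bottom.
Physical outputs are in micrometres and seconds.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import tifffile

__all__ = [
    "ImageFrame",
    "ImageStack",
    "VideoSequence",
    "write_tiff_series",
    "read_tiff_series",
]


def _validate_pixels(pixels: np.ndarray) -> np.ndarray:
    pixels = np.asarray(pixels, dtype=float)
    if pixels.ndim != 2 or pixels.size == 0:
        raise ValueError("pixels must be a non-empty 2D array")
    if pixels.min() < 0.0 or pixels.max() > 1.0:
        raise ValueError("intensities must lie in [0, 1]")
    return pixels


@dataclass
class ImageFrame:
    """One calibrated grayscale frame.

    Parameters
    ----------
    pixels : 2D float array, intensities in [0, 1].
    pixel_size_um : micrometres per pixel (> 0).
    timestamp_s : acquisition time in seconds.
    """

    pixels: np.ndarray
    pixel_size_um: float
    timestamp_s: float = 0.0

    def __post_init__(self) -> None:
        self.pixels = _validate_pixels(self.pixels)
        if self.pixel_size_um <= 0:
            raise ValueError("pixel_size_um must be > 0")

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape


@dataclass
class ImageStack:
    """Z-stack of equally spaced slices above the dish bottom."""

    slices: list[ImageFrame]
    z_step_um: float
    z0_um: float = 0.0

    def __post_init__(self) -> None:
        if self.z_step_um <= 0:
            raise ValueError("z_step_um must be > 0")
        shapes = {s.shape for s in self.slices}
        if len(shapes) > 1:
            raise ValueError(f"slices differ in shape: {sorted(shapes)}")

    @property
    def z_span_um(self) -> float:
        """Height of the top slice above the bottom slice."""
        return (len(self.slices) - 1) * self.z_step_um

    def z_positions_um(self) -> np.ndarray:
        return self.z0_um + self.z_step_um * np.arange(len(self.slices))

    def as_array(self) -> np.ndarray:
        """(Z, Y, X) intensity array."""
        return np.stack([s.pixels for s in self.slices], axis=0)


@dataclass
class VideoSequence:
    """Time-lapse video at constant frame rate."""

    frames: list[ImageFrame]
    fps: float
    pixel_size_um: float = field(default=0.0)

    def __post_init__(self) -> None:
        if self.fps <= 0:
            raise ValueError("fps must be > 0")
        if self.frames and self.pixel_size_um == 0.0:
            self.pixel_size_um = self.frames[0].pixel_size_um
        shapes = {f.shape for f in self.frames}
        if len(shapes) > 1:
            raise ValueError("video frames differ in shape")

    def __len__(self) -> int:
        return len(self.frames)

    def as_array(self) -> np.ndarray:
        """(T, Y, X) intensity array."""
        return np.stack([f.pixels for f in self.frames], axis=0)


def write_tiff_series(
    path: str | Path,
    frames: Sequence[np.ndarray] | np.ndarray,
    *,
    pixel_size_um: float,
    fps: float | None = None,
    z_step_um: float | None = None,
    extra_meta: dict | None = None,
) -> Path:
    """Write frames as a multi-page TIFF plus a ``.meta.json`` sidecar.

    Float imagery in [0, 1] is stored as 16-bit; integer label/phase maps are
    stored unchanged (16-bit for labels, 8-bit for phase maps).
    """
    path = Path(path)
    arr = np.asarray(frames)
    if np.issubdtype(arr.dtype, np.floating):
        data = np.round(arr * 65535).astype(np.uint16)
        scale = 65535.0
    else:
        data = arr.astype(np.uint16 if arr.max() > 255 else np.uint8)
        scale = 1.0
    tifffile.imwrite(path, data, photometric="minisblack")
    meta = {"pixel_size_um": pixel_size_um, "intensity_scale": scale}
    if fps is not None:
        meta["fps"] = fps
    if z_step_um is not None:
        meta["z_step_um"] = z_step_um
    if extra_meta:
        meta.update(extra_meta)
    sidecar = path.with_suffix(path.suffix + ".meta.json")
    sidecar.write_text(json.dumps(meta, indent=1, sort_keys=True))
    return path


def read_tiff_series(path: str | Path) -> tuple[np.ndarray, dict]:
    """Read a multi-page TIFF written by :func:`write_tiff_series`.

    Returns the (T/Z, Y, X) array (floats rescaled back to [0, 1] when the
    sidecar records an intensity scale) and the sidecar metadata dict.
    Raises ``FileNotFoundError`` if the sidecar is missing — calibration is
    mandatory, never silently defaulted.
    """
    path = Path(path)
    sidecar = path.with_suffix(path.suffix + ".meta.json")
    if not sidecar.exists():
        raise FileNotFoundError(
            f"metadata sidecar {sidecar} missing; pixel size / fps unknown"
        )
    meta = json.loads(sidecar.read_text())
    data = tifffile.imread(path)
    if data.ndim == 2:
        data = data[None]
    scale = meta.get("intensity_scale", 1.0)
    if scale != 1.0:
        data = data.astype(float) / scale
    return data, meta
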