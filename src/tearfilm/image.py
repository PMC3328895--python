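"""Core raster types: RGB photographs and single-channel analysis images.

Stored files use 8-bit channels; everything in memory is float in [0, 1]
(RGB) or the native range of the analysis space (L in [0, 100], signed
chromatic/opponent channels).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import imageio.v3 as iio
import numpy as np

#: Valid tags for single-channel images.
SPACE_TAGS = ("gray", "L", "a", "b", "RG", "GR", "BY")


@dataclass(frozen=True)
class RGBImage:
    """An H×W×3 colour raster with channel values in [0, 1]."""

    pixels: np.ndarray

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels, dtype=np.float64)
        if px.ndim != 3 or px.shape[2] != 3:
            raise ValueError(f"expected H×W×3 array, got shape {px.shape}")
        if px.shape[0] < 2 or px.shape[1] < 2:
            raise ValueError("image must be at least 2×2")
        if not np.isfinite(px).all():
            raise ValueError("image contains non-finite values")
        if px.min() < 0.0 or px.max() > 1.0:
            raise ValueError("RGB values must lie in [0, 1]")
        object.__setattr__(self, "pixels", px)

    @property
    def height(self) -> int:
        return self.pixels.shape[0]

    @property
    def width(self) -> int:
        return self.pixels.shape[1]

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape[:2]


@dataclass(frozen=True)
class ChannelImage:
    """A single-channel H×W image tagged with the analysis space it lives in."""

    pixels: np.ndarray
    space_tag: str = "gray"

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels, dtype=np.float64)
        if px.ndim != 2:
            raise ValueError(f"expected 2-D array, got shape {px.shape}")
        if not np.isfinite(px).all():
            raise ValueError("channel contains non-finite values")
        if self.space_tag not in SPACE_TAGS:
            raise ValueError(f"unknown space tag {self.space_tag!r}")
        object.__setattr__(self, "pixels", px)

    @property
    def height(self) -> int:
        return self.pixels.shape[0]

    @property
    def width(self) -> int:
        return self.pixels.shape[1]

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape


def read_image(path: str | Path) -> RGBImage:
    """Read an 8-bit PNG/TIFF/BMP file as an RGBImage normalised to [0, 1].

    Greyscale files are broadcast to three identical channels; an alpha
    channel, if present, is dropped.
    """
    raw = iio.imread(Path(path))
    arr = np.asarray(raw)
    if arr.ndim == 2:
        arr = np.stack([arr] * 3, axis=-1)
    if arr.shape[-1] == 4:
        arr = arr[..., :3]
    if arr.dtype == np.uint8:
        arr = arr.astype(np.float64) / 255.0
    elif arr.dtype == np.uint16:
        arr = arr.astype(np.float64) / 65535.0
    else:
        arr = arr.astype(np.float64)
        if arr.max() > 1.0:
            arr = arr / 255.0
    return RGBImage(np.clip(arr, 0.0, 1.0))


def write_image(img: RGBImage, path: str | Path) -> None:
    """Write an RGBImage as an 8-bit file (format chosen by extension)."""
    data = np.clip(np.round(img.pixels * 255.0), 0, 255).astype(np.uint8)
    iio.imwrite(Path(path), data)
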