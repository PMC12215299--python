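"""Raster I/O for plantar-pressure maps.

Pedobarographic platforms (e.g. Win-Track) export pressure maps as
color-coded raster images in which deeper red marks higher pressure.
This module reads such rasters into a :class:`PressureImage` — an
H×W×3 grid of 8-bit band intensities with row 0 at the top — and
separates the red, green and blue bands into 2-D matrices for the
downstream segmentation stages.

PNG and TIFF round-trip losslessly; JPEG is accepted on input but its
quantization makes it unsuitable for bit-exact work.
"""

from __future__ import annotations

import json
import logging
import os
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
from PIL import Image, UnidentifiedImageError

logger = logging.getLogger("pedopress")

BANDS = ("red", "green", "blue")
_BAND_INDEX = {"red": 0, "green": 1, "blue": 2}


class InputError(ValueError):
    """Raised for unreadable, truncated or empty image inputs."""


@dataclass(frozen=True)
class PressureImage:
    """An RGB plantar-pressure raster.

    Attributes
    ----------
    pixels:
        ``(H, W, 3)`` uint8 array of band intensities; row 0 is the top
        of the image.
    """

    pixels: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels)
        if px.ndim != 3 or px.shape[2] != 3:
            raise InputError(f"expected an H x W x 3 pixel grid, got shape {px.shape}")
        if px.shape[0] < 1 or px.shape[1] < 1:
            raise InputError("zero-sized image")
        if px.dtype != np.uint8:
            if px.min() < 0 or px.max() > 255:
                raise InputError("band intensities must lie in [0, 255]")
            px = px.astype(np.uint8)
        object.__setattr__(self, "pixels", px)

    @property
    def height(self) -> int:
        return int(self.pixels.shape[0])

    @property
    def width(self) -> int:
        return int(self.pixels.shape[1])


def read_image(path: str | os.PathLike) -> PressureImage:
    """Read a PNG/TIFF/JPEG raster into a :class:`PressureImage`.

    Grayscale inputs are replicated across all three bands; an alpha
    channel, if present, is dropped (platform exports are opaque).
    """
    try:
        with Image.open(path) as im:
            im.load()
            if im.mode in ("RGBA", "LA", "PA"):
                logger.warning("dropping alpha channel of %s", path)
            rgb = im.convert("RGB")
            px = np.asarray(rgb, dtype=np.uint8)
    except FileNotFoundError:
        raise InputError(f"image file not found: {path}") from None
    except (UnidentifiedImageError, OSError) as exc:
        raise InputError(f"cannot decode image {path}: {exc}") from exc
    if px.size == 0:
        raise InputError(f"zero-sized image: {path}")
    return PressureImage(px)


def write_image(image: PressureImage | np.ndarray, path: str | os.PathLike) -> None:
    """Write an RGB pixel grid (or boolean mask) to a raster file.

    Boolean arrays are written as 1-bit black/white PNGs; everything
    else as 8-bit RGB. PNG/TIFF outputs round-trip bit-exactly.
    """
    if isinstance(image, PressureImage):
        arr = image.pixels
    else:
        arr = np.asarray(image)
    if arr.dtype == bool:
        Image.fromarray(arr).convert("1").save(path)
        return
    Image.fromarray(arr.astype(np.uint8)).save(path)


def extract_band(image: PressureImage, band: str) -> np.ndarray:
    """Return one color band as an H×W matrix of intensities in [0, 255]."""
    if band not in _BAND_INDEX:
        raise ValueError(f"unknown band {band!r}; expected one of {BANDS}")
    return image.pixels[:, :, _BAND_INDEX[band]].copy()


def write_report_json(report: Mapping, path: str | os.PathLike) -> None:
    """Serialize a report mapping to JSON deterministically (sorted keys)."""

    def _default(obj):
        if isinstance(obj, (np.integer,)):
            return int(obj)
        if isinstance(obj, (np.floating,)):
            return float(obj)
        if isinstance(obj, np.ndarray):
            return obj.tolist()
        raise TypeError(f"not JSON-serializable: {type(obj)}")

    with open(path, "w") as fh:
        json.dump(report, fh, sort_keys=True, indent=2, default=_default)
        fh.write("\n")
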