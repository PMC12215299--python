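"""Pressure segmentation: thresholding, morphological enhancement, blobs.

Turns a color pressure map into a clean binary mask of pressure pixels
and a list of connected "blobs". High pressure is rendered as deep red,
so a pixel is called pressure when its red intensity clears a histogram
threshold *and* dominates the other two bands by a margin — the margin
keeps orange/yellow colormap zones out of the mask. Enhancement then
follows the classic order: area opening (drop speckle), morphological
closing (smooth boundaries), and hole filling (solidify regions).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Literal

import numpy as np
from scipy import ndimage
from skimage import morphology

from .image_io import PressureImage, extract_band

__all__ = [
    "SegmentationParams",
    "PressureMask",
    "Blob",
    "DegenerateHistogramError",
    "otsu_threshold",
    "redness_mask",
    "area_opening",
    "close_and_fill",
    "enhance_mask",
    "find_blobs",
    "segment",
]


class DegenerateHistogramError(ValueError):
    """Histogram has a single occupied bin; Otsu cannot split it."""


@dataclass(frozen=True)
class SegmentationParams:
    """Tunable knobs of the segmentation stage.

    The source method names no numeric values for the threshold, the
    minimum object size or the structuring element, so all of them are
    explicit parameters, echoed into every report.
    """

    threshold_mode: Literal["otsu", "fixed"] = "otsu"
    fixed_threshold: int | None = None
    red_dominance_margin: int = 30
    min_blob_area: int = 20
    closing_radius: int = 2
    connectivity: Literal[4, 8] = 8

    def __post_init__(self) -> None:
        if self.threshold_mode not in ("otsu", "fixed"):
            raise ValueError(f"unknown threshold_mode {self.threshold_mode!r}")
        if self.threshold_mode == "fixed":
            if self.fixed_threshold is None or not 0 <= self.fixed_threshold <= 255:
                raise ValueError("fixed threshold_mode needs fixed_threshold in [0, 255]")
        if self.red_dominance_margin < 0:
            raise ValueError("red_dominance_margin must be >= 0")
        if self.min_blob_area < 1:
            raise ValueError("min_blob_area must be >= 1")
        if self.closing_radius < 0:
            raise ValueError("closing_radius must be >= 0")
        if self.connectivity not in (4, 8):
            raise ValueError("connectivity must be 4 or 8")

    def as_dict(self) -> dict:
        return {
            "threshold_mode": self.threshold_mode,
            "fixed_threshold": self.fixed_threshold,
            "red_dominance_margin": self.red_dominance_margin,
            "min_blob_area": self.min_blob_area,
            "closing_radius": self.closing_radius,
            "connectivity": self.connectivity,
        }


@dataclass(frozen=True)
class PressureMask:
    """Binary pressure raster plus the parameters that produced it."""

    grid: np.ndarray = field(repr=False)
    params: SegmentationParams = field(default_factory=SegmentationParams)

    def __post_init__(self) -> None:
        g = np.asarray(self.grid, dtype=bool)
        object.__setattr__(self, "grid", g)

    @property
    def marked_count(self) -> int:
        return int(self.grid.sum())


@dataclass(frozen=True)
class Blob:
    """One connected pressure component with its summary statistics."""

    pixel_list: np.ndarray = field(repr=False)  # (n, 2) array of (row, col)
    area: int
    centroid: tuple[float, float]
    mean_rgb: tuple[float, float, float]
    total_red_intensity: int
    bounding_box: tuple[int, int, int, int]  # (row_min, col_min, row_max, col_max) inclusive


# connectivity name -> ndimage structuring element
_STRUCTURE = {
    4: ndimage.generate_binary_structure(2, 1),
    8: ndimage.generate_binary_structure(2, 2),
}


def otsu_threshold(histogram: np.ndarray) -> int:
    """Between-class-variance-maximizing cut of a 256-bin histogram.

    Returns the threshold ``T`` such that intensities ``>= T`` form the
    upper class; ties are broken toward the lower intensity. Requires at
    least two occupied bins.
    """
    hist = np.asarray(histogram, dtype=np.float64)
    if hist.shape != (256,):
        raise ValueError("histogram must have exactly 256 bins")
    if np.count_nonzero(hist) < 2:
        raise DegenerateHistogramError(
            "histogram has a single occupied bin; use a fixed threshold instead"
        )
    total = hist.sum()
    levels = np.arange(256, dtype=np.float64)
    # cumulative mass/mean of the lower class {i < T} for T = 0..255
    w0 = np.concatenate(([0.0], np.cumsum(hist)[:-1]))
    m0 = np.concatenate(([0.0], np.cumsum(hist * levels)[:-1]))
    w1 = total - w0
    grand_mean = (hist * levels).sum()
    with np.errstate(divide="ignore", invalid="ignore"):
        mu0 = np.where(w0 > 0, m0 / w0, 0.0)
        mu1 = np.where(w1 > 0, (grand_mean - m0) / w1, 0.0)
    between = np.where((w0 > 0) & (w1 > 0), w0 * w1 * (mu0 - mu1) ** 2, 0.0)
    return int(np.argmax(between))  # argmax takes the first (lowest) maximizer


def redness_mask(image: PressureImage, params: SegmentationParams | None = None) -> PressureMask:
    """Raw (pre-enhancement) pressure mask.

    A pixel is marked iff ``red >= T`` and ``red - max(green, blue) >=
    red_dominance_margin``, with ``T`` either fixed or the Otsu cut of
    the red-band histogram.
    """
    params = params or SegmentationParams()
    red = extract_band(image, "red").astype(np.int64)
    green = extract_band(image, "green").astype(np.int64)
    blue = extract_band(image, "blue").astype(np.int64)
    if params.threshold_mode == "fixed":
        threshold = int(params.fixed_threshold)
    else:
        hist = np.bincount(red.ravel(), minlength=256)[:256]
        threshold = otsu_threshold(hist)
    dominance = red - np.maximum(green, blue)
    grid = (red >= threshold) & (dominance >= params.red_dominance_margin)
    return PressureMask(grid, params)


def area_opening(mask: PressureMask, min_blob_area: int | None = None) -> PressureMask:
    """Remove connected components smaller than ``min_blob_area`` pixels."""
    min_area = mask.params.min_blob_area if min_blob_area is None else int(min_blob_area)
    if min_area < 1:
        raise ValueError("min_blob_area must be >= 1")
    if min_area == 1:
        return mask
    conn = 1 if mask.params.connectivity == 4 else 2
    # max_size removes components of area <= max_size, i.e. area < min_area
    grid = morphology.remove_small_objects(mask.grid, max_size=min_area - 1, connectivity=conn)
    return PressureMask(grid, replace(mask.params, min_blob_area=min_area))


def close_and_fill(mask: PressureMask, closing_radius: int | None = None) -> PressureMask:
    """Morphological closing with a disk element, then hole filling.

    Holes are background regions not connected to the image border
    (4-connected background flood). The result is always a superset of
    the input pixel set.
    """
    radius = mask.params.closing_radius if closing_radius is None else int(closing_radius)
    if radius < 0:
        raise ValueError("closing_radius must be >= 0")
    grid = mask.grid
    if radius > 0:
        # pad so border pixels see a proper neighborhood; closing stays extensive
        pad = radius + 1
        padded = np.pad(grid, pad, mode="constant", constant_values=False)
        closed = morphology.closing(padded, morphology.disk(radius))
        grid = closed[pad:-pad, pad:-pad] | grid
    filled = ndimage.binary_fill_holes(grid)
    return PressureMask(filled, replace(mask.params, closing_radius=radius))


def enhance_mask(mask: PressureMask) -> PressureMask:
    """Full enhancement chain: area opening, closing, hole filling."""
    return close_and_fill(area_opening(mask))


def find_blobs(
    mask: PressureMask, image: PressureImage, connectivity: int | None = None
) -> list[Blob]:
    """Connected-component blob analysis over the mask.

    One :class:`Blob` per component, sorted by the (row_min, col_min)
    corner of its bounding box; statistics are computed over member
    pixels of the source image. An empty mask yields an empty list.
    """
    conn = mask.params.connectivity if connectivity is None else int(connectivity)
    if conn not in (4, 8):
        raise ValueError("connectivity must be 4 or 8")
    if mask.grid.shape != image.pixels.shape[:2]:
        raise ValueError("mask and image dimensions differ")
    labels, n = ndimage.label(mask.grid, structure=_STRUCTURE[conn])
    blobs: list[Blob] = []
    px = image.pixels.astype(np.float64)
    red = image.pixels[:, :, 0].astype(np.int64)
    for lab in range(1, n + 1):
        rows, cols = np.nonzero(labels == lab)
        coords = np.column_stack([rows, cols])
        mean_rgb = tuple(float(px[rows, cols, c].mean()) for c in range(3))
        blobs.append(
            Blob(
                pixel_list=coords,
                area=int(len(rows)),
                centroid=(float(rows.mean()), float(cols.mean())),
                mean_rgb=mean_rgb,
                total_red_intensity=int(red[rows, cols].sum()),
                bounding_box=(int(rows.min()), int(cols.min()), int(rows.max()), int(cols.max())),
            )
        )
    blobs.sort(key=lambda b: (b.bounding_box[0], b.bounding_box[1]))
    return blobs


def segment(
    image: PressureImage, params: SegmentationParams | None = None
) -> tuple[PressureMask, list[Blob]]:
    """Threshold, enhance and blob-analyze an image in one call."""
    params = params or SegmentationParams()
    raw = redness_mask(image, params)
    clean = enhance_mask(raw)
    return clean, find_blobs(clean, image)


def blobs_to_records(blobs: list[Blob]) -> list[dict]:
    """Blob list as flat records for CSV export."""
    return [
        {
            "blob_id": i,
            "area_px": b.area,
            "centroid_row": b.centroid[0],
            "centroid_col": b.centroid[1],
            "mean_r": b.mean_rgb[0],
            "mean_g": b.mean_rgb[1],
            "mean_b": b.mean_rgb[2],
            "total_red_intensity": b.total_red_intensity,
            "bbox": "{}:{}:{}:{}".format(*b.bounding_box),
        }
        for i, b in enumerate(blobs)
    ]
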