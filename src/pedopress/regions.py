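"""Forefoot/hindfoot regionalization and foot-type classification.

The detected pressure field is split at the midpoint row of its
bounding box: with toes at the top of the image, marked pixels above
the split row form the forefoot (metatarsal heads and toes), the rest
the hindfoot (heel and mid-arch). Region pressure is the summed
red-band intensity over the region's pixels — raw red intensity is the
pressure proxy, since deeper red encodes higher pressure; no colormap
decoding is attempted. The forefoot:hindfoot ratio then classifies the
foot:

* Type 0 — hindfoot dominant, ratio < 0.8
* Type 1 — balanced, 0.8 <= ratio <= 1.2 (closed interval)
* Type 2 — forefoot dominant, ratio > 1.2

The per-pixel split guarantees exact conservation: forefoot plus
hindfoot pressure equals the whole-mask pressure as integers.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Literal

import numpy as np

from .image_io import PressureImage
from .segmentation import PressureMask, SegmentationParams, find_blobs, segment

__all__ = [
    "EmptyFootError",
    "RegionReport",
    "split_regions",
    "region_pressure",
    "classify_foot_type",
    "annotate",
    "analyze_image",
]

FOREFOOT_BOX_COLOR = (255, 215, 0)  # gold
HINDFOOT_BOX_COLOR = (0, 200, 255)  # cyan

TYPE_0_MAX_RATIO = 0.8  # below: hindfoot dominant
TYPE_2_MIN_RATIO = 1.2  # above: forefoot dominant


class EmptyFootError(ValueError):
    """No pressure pixels detected — nothing to regionalize."""


@dataclass(frozen=True)
class RegionReport:
    """Quantitative forefoot/hindfoot summary of one pressure image."""

    forefoot_pressure: int
    hindfoot_pressure: int
    ratio: float
    foot_type: int
    split_row: int
    forefoot_bbox: tuple[int, int, int, int] | None  # (row_min, col_min, row_max, col_max)
    hindfoot_bbox: tuple[int, int, int, int] | None

    def as_dict(self) -> dict:
        return {
            "forefoot_pressure": self.forefoot_pressure,
            "hindfoot_pressure": self.hindfoot_pressure,
            "ratio": self.ratio if math.isfinite(self.ratio) else "inf",
            "foot_type": self.foot_type,
            "split_row": self.split_row,
            "forefoot_bbox": list(self.forefoot_bbox) if self.forefoot_bbox else None,
            "hindfoot_bbox": list(self.hindfoot_bbox) if self.hindfoot_bbox else None,
            "pressure_proxy": "red_band_intensity_sum",
        }


def split_regions(
    mask: PressureMask,
    orientation: Literal["toes_up", "toes_down"] = "toes_up",
    mode: Literal["pixel", "component"] = "pixel",
    image: PressureImage | None = None,
) -> tuple[np.ndarray, np.ndarray, int]:
    """Partition the mask into forefoot and hindfoot pixel sets.

    The split row is the midpoint of the marked pixels' bounding box,
    ``floor((row_min + row_max + 1) / 2)``. In ``pixel`` mode each
    marked pixel is assigned by its own row (rows < split_row are
    forefoot under ``toes_up``); in ``component`` mode whole connected
    components are assigned by centroid row, which sacrifices exact
    conservation of the 50% rule for anatomically intact blobs.

    Returns two boolean grids (forefoot, hindfoot) partitioning the
    mask, and the split row.
    """
    if orientation not in ("toes_up", "toes_down"):
        raise ValueError(f"unknown orientation {orientation!r}")
    rows = np.nonzero(mask.grid.any(axis=1))[0]
    if rows.size == 0:
        raise EmptyFootError("mask contains no pressure pixels")
    row_min, row_max = int(rows[0]), int(rows[-1])
    split_row = (row_min + row_max + 1) // 2

    if mode == "pixel":
        above = np.zeros_like(mask.grid)
        above[:split_row, :] = True
        top = mask.grid & above
        bottom = mask.grid & ~above
    elif mode == "component":
        if image is None:
            raise ValueError("component mode needs the source image for blob analysis")
        top = np.zeros_like(mask.grid)
        for blob in find_blobs(mask, image):
            if blob.centroid[0] < split_row:
                top[blob.pixel_list[:, 0], blob.pixel_list[:, 1]] = True
        bottom = mask.grid & ~top
    else:
        raise ValueError(f"unknown split mode {mode!r}")

    if orientation == "toes_up":
        return top, bottom, split_row
    return bottom, top, split_row


def region_pressure(region: np.ndarray, image: PressureImage) -> int:
    """Summed red-band intensity over a pixel set (boolean grid or (n,2) coords)."""
    red = image.pixels[:, :, 0].astype(np.int64)
    region = np.asarray(region)
    if region.dtype == bool:
        if region.shape != red.shape:
            raise ValueError("region grid does not match image dimensions")
        return int(red[region].sum())
    if region.size == 0:
        return 0
    coords = region.reshape(-1, 2)
    if (
        coords.min() < 0
        or coords[:, 0].max() >= image.height
        or coords[:, 1].max() >= image.width
    ):
        raise ValueError("region coordinate outside image bounds")
    return int(red[coords[:, 0], coords[:, 1]].sum())


def classify_foot_type(forefoot_pressure: float, hindfoot_pressure: float) -> tuple[float, int]:
    """Forefoot:hindfoot ratio and the Type 0/1/2 label it implies."""
    if forefoot_pressure < 0 or hindfoot_pressure < 0:
        raise ValueError("pressures must be non-negative")
    if forefoot_pressure == 0 and hindfoot_pressure == 0:
        raise EmptyFootError("both regions empty; no pressure detected")
    if hindfoot_pressure == 0:
        return math.inf, 2
    ratio = forefoot_pressure / hindfoot_pressure
    if ratio < TYPE_0_MAX_RATIO:
        return ratio, 0
    if ratio <= TYPE_2_MIN_RATIO:
        return ratio, 1
    return ratio, 2


def _bbox_of(grid: np.ndarray) -> tuple[int, int, int, int] | None:
    rows, cols = np.nonzero(grid)
    if rows.size == 0:
        return None
    return int(rows.min()), int(cols.min()), int(rows.max()), int(cols.max())


def _draw_box(px: np.ndarray, bbox: tuple[int, int, int, int], color: tuple[int, int, int]) -> None:
    r0, c0, r1, c1 = bbox
    px[r0, c0 : c1 + 1] = color
    px[r1, c0 : c1 + 1] = color
    px[r0 : r1 + 1, c0] = color
    px[r0 : r1 + 1, c1] = color


def annotate(image: PressureImage, report: RegionReport) -> PressureImage:
    """Copy of the image with forefoot/hindfoot bounding boxes drawn.

    Only the one-pixel rectangle borders are touched; the numeric
    report travels separately as a JSON sidecar (see the CLI).
    """
    px = image.pixels.copy()
    if report.forefoot_bbox is not None:
        _draw_box(px, report.forefoot_bbox, FOREFOOT_BOX_COLOR)
    if report.hindfoot_bbox is not None:
        _draw_box(px, report.hindfoot_bbox, HINDFOOT_BOX_COLOR)
    return PressureImage(px)


def analyze_image(
    image: PressureImage,
    params: SegmentationParams | None = None,
    orientation: Literal["toes_up", "toes_down"] = "toes_up",
    split_mode: Literal["pixel", "component"] = "pixel",
):
    """Full pipeline: segment, regionalize, classify.

    Returns ``(mask, blobs, report)``.
    """
    mask, blobs = segment(image, params)
    fore, hind, split_row = split_regions(mask, orientation, split_mode, image=image)
    fore_p = region_pressure(fore, image)
    hind_p = region_pressure(hind, image)
    ratio, foot_type = classify_foot_type(fore_p, hind_p)
    report = RegionReport(
        forefoot_pressure=fore_p,
        hindfoot_pressure=hind_p,
        ratio=ratio,
        foot_type=foot_type,
        split_row=split_row,
        forefoot_bbox=_bbox_of(fore),
        hindfoot_bbox=_bbox_of(hind),
    )
    return mask, blobs, report
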