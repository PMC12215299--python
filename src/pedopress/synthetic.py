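"""Synthetic plantar-pressure image generator with ground-truth manifests.

Clinical pedobarographic images are rarely shareable, so every stage of
the analysis pipeline is exercised on generated stand-ins: RGB rasters
in which pressure regions are filled disks of deep red (intensity
decaying from the center) on a non-red background, mimicking platform
colormaps where deeper red encodes higher pressure. Each image ships
with a :class:`GroundTruth` manifest — the exact pressure pixel set,
per-region red-intensity sums, the true forefoot:hindfoot ratio and the
foot-type label it implies — computed from the noise-free rendering
before any noise is added.

Rendering choices that keep the manifest exact under the default
segmentation parameters:

* blob red intensities stay in a high band (edge value 60% of the
  peak), so the red histogram is strongly bimodal against the zero-red
  background and Otsu lands between the two modes;
* the background red component is 0, so any pixels the morphological
  closing adds around blob boundaries contribute nothing to the
  pressure sums;
* green/blue inside blobs are held far below red, so the red-dominance
  margin never rejects a pressure pixel.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .image_io import PressureImage
from .regions import classify_foot_type

__all__ = [
    "SyntheticSpecError",
    "BlobSpec",
    "SyntheticSpec",
    "GroundTruth",
    "generate_pressure_image",
    "ratio_targeted_spec",
    "foot_preset",
    "generate_labeled_points",
]

BLOB_GREEN_BLUE = 10  # green/blue value inside pressure blobs
EDGE_FRACTION = 0.6  # red at the disk edge, as a fraction of the peak


class SyntheticSpecError(ValueError):
    """The requested synthetic image is geometrically or photometrically invalid."""


@dataclass(frozen=True)
class BlobSpec:
    """One circular pressure blob: center, radius, peak red, region label."""

    center_row: int
    center_col: int
    radius: int
    peak_red: int
    region: str  # "forefoot" | "hindfoot"

    def __post_init__(self) -> None:
        if self.region not in ("forefoot", "hindfoot"):
            raise SyntheticSpecError(f"unknown region label {self.region!r}")
        if self.radius < 1:
            raise SyntheticSpecError("blob radius must be >= 1")
        if not 0 < self.peak_red <= 255:
            raise SyntheticSpecError("peak_red must be in (0, 255]")


@dataclass(frozen=True)
class SyntheticSpec:
    """Recipe for one synthetic pressure image."""

    height: int = 96
    width: int = 64
    blob_specs: Sequence[BlobSpec] = field(default_factory=tuple)
    background_color: tuple[int, int, int] = (0, 0, 120)
    noise_sd: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.height < 1 or self.width < 1:
            raise SyntheticSpecError("image dimensions must be positive")
        r, g, b = self.background_color
        if r - max(g, b) >= 0:
            raise SyntheticSpecError("background must not be red-dominant")
        if self.noise_sd < 0:
            raise SyntheticSpecError("noise_sd must be >= 0")
        for blob in self.blob_specs:
            if (
                blob.center_row - blob.radius < 0
                or blob.center_row + blob.radius >= self.height
                or blob.center_col - blob.radius < 0
                or blob.center_col + blob.radius >= self.width
            ):
                raise SyntheticSpecError("blob does not fit inside the image")


@dataclass(frozen=True)
class GroundTruth:
    """Noise-free manifest accompanying a generated image."""

    pressure_pixels: np.ndarray = field(repr=False)  # H x W bool
    forefoot_pressure: int = 0
    hindfoot_pressure: int = 0
    ratio: float = 0.0
    foot_type: int = 0
    blob_areas: tuple[int, ...] = ()
    seed: int = 0


def _render_blob(red: np.ndarray, blob: BlobSpec) -> np.ndarray:
    """Paint one radial-decay disk into the red band; return its member mask."""
    h, w = red.shape
    rr, cc = np.ogrid[:h, :w]
    dist = np.sqrt((rr - blob.center_row) ** 2 + (cc - blob.center_col) ** 2)
    inside = dist <= blob.radius
    edge = EDGE_FRACTION * blob.peak_red
    values = np.rint(blob.peak_red - (blob.peak_red - edge) * dist / blob.radius)
    red[inside] = np.maximum(red[inside], values[inside].astype(np.int64))
    return inside


def generate_pressure_image(spec: SyntheticSpec) -> tuple[PressureImage, GroundTruth]:
    """Render a spec into an image plus its ground-truth manifest.

    The manifest is computed from the noise-free rendering; seeded
    Gaussian noise (if any) is added afterwards and clipped to
    [0, 255]. Identical spec + seed yields identical pixel bytes.
    """
    if not spec.blob_specs:
        raise SyntheticSpecError("spec contains no blobs")
    h, w = spec.height, spec.width
    red = np.zeros((h, w), dtype=np.int64)
    pressure = np.zeros((h, w), dtype=bool)
    fore = np.zeros((h, w), dtype=bool)
    hind = np.zeros((h, w), dtype=bool)
    areas = []
    for blob in spec.blob_specs:
        member = _render_blob(red, blob)
        pressure |= member
        areas.append(int(member.sum()))
        if blob.region == "forefoot":
            fore |= member
        else:
            hind |= member
    if (fore & hind).any():
        raise SyntheticSpecError("forefoot and hindfoot blobs overlap")

    rows = np.nonzero(pressure.any(axis=1))[0]
    split_row = (int(rows[0]) + int(rows[-1]) + 1) // 2
    fore_rows = np.nonzero(fore.any(axis=1))[0]
    hind_rows = np.nonzero(hind.any(axis=1))[0]
    if fore_rows.size and hind_rows.size:
        if fore_rows[-1] >= hind_rows[0]:
            raise SyntheticSpecError("forefoot blobs must lie strictly above hindfoot blobs")
        if not (fore_rows[-1] < split_row <= hind_rows[0]):
            raise SyntheticSpecError(
                "blobs cross the forefoot/hindfoot midline; ground truth would be ambiguous"
            )

    fore_sum = int(red[fore].sum())
    hind_sum = int(red[hind].sum())
    ratio, foot_type = classify_foot_type(fore_sum, hind_sum)
    truth = GroundTruth(
        pressure_pixels=pressure,
        forefoot_pressure=fore_sum,
        hindfoot_pressure=hind_sum,
        ratio=ratio,
        foot_type=foot_type,
        blob_areas=tuple(areas),
        seed=spec.seed,
    )

    px = np.empty((h, w, 3), dtype=np.int64)
    px[:, :] = spec.background_color
    px[pressure, 0] = red[pressure]
    px[pressure, 1] = BLOB_GREEN_BLUE
    px[pressure, 2] = BLOB_GREEN_BLUE
    if spec.noise_sd > 0:
        rng = np.random.default_rng(spec.seed)
        px = px + np.rint(rng.normal(0.0, spec.noise_sd, size=px.shape)).astype(np.int64)
    px = np.clip(px, 0, 255).astype(np.uint8)
    return PressureImage(px), truth


def _disk_profile_sum(radius: int, peak: int) -> int:
    """Exact red-intensity sum of one rendered disk of the given radius/peak."""
    red = np.zeros((2 * radius + 3, 2 * radius + 3), dtype=np.int64)
    _render_blob(red, BlobSpec(radius + 1, radius + 1, radius, peak, "forefoot"))
    return int(red.sum())


def ratio_targeted_spec(
    target_ratio: float,
    seed: int = 0,
    height: int = 96,
    width: int = 64,
    noise_sd: float = 0.0,
) -> SyntheticSpec:
    """Two-blob spec whose ground-truth ratio approximates ``target_ratio``.

    One forefoot and one hindfoot disk share an intensity profile; the
    forefoot radius gives coarse control over the pressure ratio and
    its peak intensity fine control, keeping every blob pixel bright
    enough that histogram thresholding cannot split the two blobs
    apart. The realized ground-truth ratio (exact, from the manifest)
    lands within about 1% of the target.
    """
    if target_ratio <= 0:
        raise SyntheticSpecError("target_ratio must be positive")
    base_peak = 210
    hind_radius = 11
    hind_sum = _disk_profile_sum(hind_radius, base_peak)
    best: tuple[float, int, int] | None = None
    for r in range(5, 16):
        base = _disk_profile_sum(r, base_peak) / hind_sum
        peak = int(round(base_peak * target_ratio / base))
        if not 140 <= peak <= 253:
            continue
        realized = _disk_profile_sum(r, peak) / hind_sum
        err = abs(realized / target_ratio - 1.0)
        if best is None or err < best[0]:
            best = (err, r, peak)
    if best is None:
        raise SyntheticSpecError(f"target ratio {target_ratio} not reachable with default geometry")
    _, fore_radius, fore_peak = best
    col = width // 2
    blobs = (
        BlobSpec(height // 4, col, fore_radius, fore_peak, "forefoot"),
        BlobSpec(3 * height // 4, col, hind_radius, base_peak, "hindfoot"),
    )
    return SyntheticSpec(height, width, blobs, noise_sd=noise_sd, seed=seed)


def foot_preset(seed: int = 0, noise_sd: float = 0.0) -> SyntheticSpec:
    """A foot-shaped demo layout: toes, metatarsal pad, and heel."""
    blobs = (
        BlobSpec(14, 24, 4, 190, "forefoot"),
        BlobSpec(12, 36, 4, 180, "forefoot"),
        BlobSpec(13, 48, 4, 170, "forefoot"),
        BlobSpec(30, 36, 11, 230, "forefoot"),
        BlobSpec(78, 38, 13, 245, "hindfoot"),
    )
    return SyntheticSpec(height=104, width=72, blob_specs=blobs, noise_sd=noise_sd, seed=seed)


def generate_labeled_points(
    n_clusters: int,
    points_per_cluster: int,
    centers: Sequence[Sequence[float]],
    spread: float,
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray]:
    """Seeded isotropic Gaussian clusters for exercising validity indices.

    Returns ``(points, labels)`` with ``n_clusters * points_per_cluster``
    rows; deterministic per seed.
    """
    if n_clusters < 2:
        raise SyntheticSpecError("validity indices need at least 2 clusters")
    centers_arr = np.asarray(centers, dtype=np.float64)
    if centers_arr.shape[0] != n_clusters:
        raise SyntheticSpecError("need one center per cluster")
    if len({tuple(c) for c in centers_arr}) != n_clusters:
        raise SyntheticSpecError("cluster centers must be pairwise distinct")
    if spread <= 0:
        raise SyntheticSpecError("spread must be positive")
    rng = np.random.default_rng(seed)
    points = np.concatenate(
        [rng.normal(c, spread, size=(points_per_cluster, centers_arr.shape[1])) for c in centers_arr]
    )
    labels = np.repeat(np.arange(n_clusters), points_per_cluster)
    return points, labels
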