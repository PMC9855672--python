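"""Lesion morphology and B-mode texture features.

Covers the convex-hull boundary-roughness ratio dA/A, lesion-interior
B-scan intensity statistics, and the inner/outer margin bands obtained by
morphological erosion and dilation with a disk whose radius is tied to the
lesion length (maximum Feret diameter).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import binary_dilation, binary_erosion
from shapely.geometry import Polygon
from skimage.draw import polygon as raster_polygon
from skimage.morphology import disk

from .frames import BModeImage


@dataclass
class LesionContour:
    """Closed simple polygon in 0-based pixel coordinates (x = column, y = row)."""

    vertices: np.ndarray  # [n, 2] as (x_px, y_px)

    def __post_init__(self):
        v = np.asarray(self.vertices, dtype=float)
        if v.ndim != 2 or v.shape[1] != 2 or v.shape[0] < 3:
            raise ValueError("contour needs >= 3 (x, y) vertices")
        # drop an explicit closing vertex if present
        if np.allclose(v[0], v[-1]):
            v = v[:-1]
        self.vertices = v
        poly = Polygon(v)
        if not poly.is_valid or poly.area <= 0:
            raise ValueError("contour must be a simple polygon with positive area")

    def polygon(self) -> Polygon:
        return Polygon(self.vertices)

    @property
    def area_px(self) -> float:
        return self.polygon().area

    def feret_diameter(self) -> float:
        """Maximum pairwise vertex distance (max Feret diameter), px."""
        v = self.vertices
        d2 = np.sum((v[:, None, :] - v[None, :, :]) ** 2, axis=-1)
        return float(np.sqrt(d2.max()))


@dataclass
class LesionMask:
    """Boolean raster aligned to the B-mode grid."""

    mask: np.ndarray
    axial_pitch: float = 1.0  # mm per row
    lateral_pitch: float = 1.0  # mm per column

    def __post_init__(self):
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.mask.ndim != 2:
            raise ValueError("mask must be 2-D")

    @property
    def area_px(self) -> int:
        return int(self.mask.sum())

    @property
    def area_cm2(self) -> float:
        return self.area_px * self.axial_pitch * self.lateral_pitch / 100.0


def rasterize_contour(
    contour: LesionContour, shape: tuple[int, int], axial_pitch: float = 1.0,
    lateral_pitch: float = 1.0,
) -> LesionMask:
    """Pixel centers inside the polygon belong to the mask (even-odd rule)."""
    rr, cc = raster_polygon(contour.vertices[:, 1], contour.vertices[:, 0], shape=shape)
    m = np.zeros(shape, dtype=bool)
    m[rr, cc] = True
    return LesionMask(mask=m, axial_pitch=axial_pitch, lateral_pitch=lateral_pitch)


@dataclass
class ShapeFeature:
    dA: float  # hull area - contour area, px^2
    A: float  # contour area, px^2

    @property
    def ratio(self) -> float:
        return self.dA / self.A


def boundary_shape(contour: LesionContour) -> ShapeFeature:
    """Boundary roughness dA/A = (convex hull area - contoured area) / contoured area.

    Smooth (near-convex) boundaries give dA/A near zero; spiculated or
    lobulated boundaries give larger values.
    """
    poly = contour.polygon()
    if poly.area <= 0:
        raise ValueError("degenerate contour")
    hull = poly.convex_hull
    dA = hull.area - poly.area
    return ShapeFeature(dA=float(max(dA, 0.0)), A=float(poly.area))


@dataclass
class MarginBands:
    """Inner and outer boundary margins from erosion/dilation with a disk."""

    inner: np.ndarray  # bool, subset of the lesion mask
    outer: np.ndarray  # bool, disjoint from the lesion mask
    disk_radius_px: int
    band_fraction: float = 0.10


def margin_disk_radius(lesion_length_px: float, band_fraction: float = 0.10) -> int:
    """Disk radius so total band width (inner + outer) = band_fraction of length."""
    return int(round(0.5 * band_fraction * lesion_length_px))


def lesion_margins(
    mask: LesionMask,
    contour: LesionContour | None = None,
    band_fraction: float = 0.10,
) -> MarginBands:
    """Build inner/outer margin bands around the lesion boundary.

    The structuring element is a discrete disk of radius ``r = round(0.5 *
    band_fraction * lesion_length)`` where lesion length is the maximum Feret
    diameter (of the contour when given, else of the mask's foreground pixels).
    """
    m = mask.mask
    if not m.any():
        raise ValueError("empty lesion mask")
    if contour is not None:
        length = contour.feret_diameter()
    else:
        pts = np.argwhere(m).astype(float)
        d2 = np.sum((pts[:, None, :] - pts[None, :, :]) ** 2, axis=-1)
        length = float(np.sqrt(d2.max()))
    r = margin_disk_radius(length, band_fraction)
    if r < 1:
        raise ValueError("lesion too small for the requested band fraction")
    selem = disk(r)
    eroded = binary_erosion(m, structure=selem)
    if not eroded.any():
        raise ValueError(
            "erosion emptied the mask; use a smaller band_fraction for this lesion"
        )
    dilated = binary_dilation(m, structure=selem)
    return MarginBands(
        inner=m & ~eroded,
        outer=dilated & ~m,
        disk_radius_px=r,
        band_fraction=band_fraction,
    )


def _masked_stats(img: np.ndarray, mask: np.ndarray) -> tuple[float, float]:
    vals = img[mask]
    if vals.size == 0:
        raise ValueError("empty mask")
    return float(vals.mean()), float(vals.std())


def bscan_stats(bmode: BModeImage, mask: LesionMask) -> dict:
    """Mean and population STD of B-mode intensity within the lesion."""
    mean, std = _masked_stats(bmode.intensity, mask.mask)
    return {"bscan_intensity": mean, "bscan_std": std}


def boundary_stats(bmode: BModeImage, bands: MarginBands) -> dict:
    """Mean and population STD of B-mode intensity over inner + outer margins."""
    union = bands.inner | bands.outer
    mean, std = _masked_stats(bmode.intensity, union)
    return {"boundary_intensity": mean, "boundary_std": std}


def chaikin_smooth(contour: LesionContour, iterations: int = 2) -> LesionContour:
    """Chaikin corner-cutting smoothing of a closed contour.

    Used (optionally) for the mask feeding texture and speckle features;
    the roughness ratio dA/A always uses the raw contour.
    """
    v = contour.vertices
    for _ in range(iterations):
        nxt = np.roll(v, -1, axis=0)
        q = 0.75 * v + 0.25 * nxt
        r = 0.25 * v + 0.75 * nxt
        v = np.empty((2 * len(q), 2))
        v[0::2] = q
        v[1::2] = r
    return LesionContour(vertices=v)
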