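"""Contour-based pancreas morphometry and ROI summaries over parametric maps.

Volume is the slice-area sum times the inter-slice distance; surface area is
the slice-perimeter sum times the inter-slice distance (an open-tube
construction with no end caps, matching the radiologic slice-stack
convention); the surface-area-to-volume ratio divides the two and is
reported in 1/mm.  The pancreas volume index (PVI) normalizes volume by body
weight.  ROI means rasterize the contours directly at each parametric map's
own grid (center-of-voxel sampling) and average over valid in-mask voxels.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import shapely

from .imaging import ContourStack, ImageVolume, rasterize_contours
from .mapping import ParametricMap

__all__ = [
    "SubjectMeasures",
    "polygon_geometry",
    "pancreas_volume",
    "pancreas_volume_index",
    "surface_area_to_volume",
    "roi_mean_on_map",
    "circular_roi_mean",
    "RoiSummary",
]

# canonical measure names used throughout tables and reports
MEASURE_NAMES = (
    "volume",             # ml
    "pvi",                # ml/kg
    "surface_to_volume",  # 1/mm
    "adc",                # mm^2/s
    "t1",                 # ms
    "mtr",                # dimensionless
    "panc_fat_fraction",
    "hep_fat_fraction",
)


@dataclass
class SubjectMeasures:
    """All per-scan scalar measures for one subject at one site."""

    subject_id: str
    site_id: str
    weight_kg: float | None = None
    values: dict = field(default_factory=dict)  # measure -> scalar (absent = missing)

    def __post_init__(self) -> None:
        if "pvi" in self.values and (self.weight_kg is None or self.weight_kg <= 0):
            raise ValueError("PVI requires a positive body weight")
        if self.values.get("volume", 1.0) <= 0:
            raise ValueError("pancreas volume must be positive when present")


@dataclass(frozen=True)
class RoiSummary:
    mean: float
    n_voxels: int
    n_censored: int


def polygon_geometry(vertices_mm: np.ndarray) -> tuple[float, float]:
    """(area mm², perimeter mm) of a closed polygon given as (n, 2) vertices.

    Area is the absolute shoelace value (orientation-independent); perimeter
    is the closed polyline length.  A degenerate (collinear) polygon yields
    zero area but still a perimeter.
    """
    v = np.asarray(vertices_mm, dtype=np.float64)
    if v.ndim != 2 or v.shape[1] != 2 or v.shape[0] < 3:
        raise ValueError("polygon needs >= 3 (x, y) vertices")
    ring = shapely.LinearRing(v) if not _degenerate(v) else None
    if ring is None:
        closed = np.vstack([v, v[:1]])
        perimeter = float(np.sum(np.linalg.norm(np.diff(closed, axis=0), axis=1)))
        return 0.0, perimeter
    return float(shapely.Polygon(v).area), float(ring.length)


def _degenerate(v: np.ndarray) -> bool:
    x, y = v[:, 0], v[:, 1]
    area2 = abs(np.dot(x, np.roll(y, -1)) - np.dot(np.roll(x, -1), y))
    return area2 == 0.0


def pancreas_volume(stack: ContourStack) -> float:
    """Volume in ml: (sum of per-slice polygon areas) x inter-slice distance."""
    if len(stack) == 0:
        raise ValueError("cannot compute volume of an empty contour stack")
    total_area = sum(polygon_geometry(c.vertices_mm)[0] for c in stack.contours)
    return total_area * stack.frame_spacing / 1000.0  # mm^3 -> ml


def pancreas_volume_index(volume_ml: float, weight_kg: float) -> float:
    """PVI in ml/kg."""
    if weight_kg <= 0:
        raise ValueError("weight must be positive")
    return volume_ml / weight_kg


def surface_area_to_volume(stack: ContourStack) -> float:
    """((sum of perimeters) x inter-slice distance) / volume, in 1/mm.

    Multiply by 10 for 1/cm.  No end caps are added to the surface.
    """
    if len(stack) == 0:
        raise ValueError("cannot compute surface/volume of an empty contour stack")
    areas, perimeters = zip(*(polygon_geometry(c.vertices_mm) for c in stack.contours))
    volume_mm3 = sum(areas) * stack.frame_spacing
    if volume_mm3 <= 0:
        raise ValueError("degenerate structure: zero volume")
    surface_mm2 = sum(perimeters) * stack.frame_spacing
    return surface_mm2 / volume_mm3


def roi_mean_on_map(pmap: ParametricMap, stack: ContourStack) -> RoiSummary:
    """Mean of the map over valid voxels whose centers fall inside the
    contours, rasterized at the map's own grid."""
    mask = rasterize_contours(stack, pmap.volume.grid).data > 0
    n_total = int(mask.sum())
    if n_total == 0:
        raise ValueError("ROI does not intersect the map grid")
    in_roi = pmap.data[mask]
    valid = np.isfinite(in_roi)
    if not valid.any():
        raise ValueError("ROI contains no valid voxels")
    return RoiSummary(float(in_roi[valid].mean()), n_total, int(n_total - valid.sum()))


def circular_roi_mean(
    pmap: ParametricMap,
    center_xy_mm: tuple[float, float],
    slice_index: int,
    area_cm2: float = 4.0,
) -> RoiSummary:
    """Mean over a circular single-slice ROI of the given area (default 4 cm²,
    the hepatic sampling convention); the circle must fit inside the slice."""
    grid = pmap.volume.grid
    if not 0 <= slice_index < grid.shape[2]:
        raise ValueError(f"slice {slice_index} outside volume")
    radius = float(np.sqrt(area_cm2 * 100.0 / np.pi))  # mm
    xs = grid.axis_coords(0)
    ys = grid.axis_coords(1)
    x0, y0 = center_xy_mm
    if (
        x0 - radius < xs[0] or x0 + radius > xs[-1]
        or y0 - radius < ys[0] or y0 + radius > ys[-1]
    ):
        raise ValueError("circular ROI extends outside the image extent")
    gx, gy = np.meshgrid(xs, ys, indexing="ij")
    disk = (gx - x0) ** 2 + (gy - y0) ** 2 <= radius**2
    vals = pmap.data[:, :, slice_index][disk]
    valid = np.isfinite(vals)
    if not valid.any():
        raise ValueError("circular ROI contains no valid voxels")
    return RoiSummary(float(vals[valid].mean()), int(disk.sum()), int(disk.sum() - valid.sum()))
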