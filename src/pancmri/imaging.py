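"""Image/contour data model, NIfTI and contour I/O, regridding, rasterization.

Coordinate convention
---------------------
All geometry lives in a single axial millimetre frame.  A voxel with index
``(i, j, k)`` (row, column, slice; 0-based) has its *center* at

    x = origin[0] + i * in_plane_spacing[0]
    y = origin[1] + j * in_plane_spacing[1]
    z = origin[2] + k * slice_spacing

Contour vertices are ``(x, y)`` pairs in the same frame, attached to a slice
index.  Alignment between acquisitions of one session is translation-only
(coplanar axial series); rotational registration is out of scope.

Invalid voxels are flagged with a single reserved sentinel, IEEE NaN, which
propagates through interpolation (any contributing invalid neighbor
invalidates the output voxel).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import nibabel as nib
import numpy as np
import shapely

__all__ = [
    "ImageVolume",
    "GridSpec",
    "ContourStack",
    "Contour",
    "read_volume",
    "write_volume",
    "read_contours",
    "write_contours",
    "regrid_volume",
    "rasterize_contours",
]

INVALID = np.nan
"""Reserved not-a-value sentinel for invalid voxels."""


class FormatError(ValueError):
    """A file or header field violates the documented format."""


class FrameError(ValueError):
    """Two objects do not share a physical coordinate frame."""


@dataclass(frozen=True)
class GridSpec:
    """Target geometry for regridding: shape, spacing and origin in mm."""

    shape: tuple[int, int, int]
    in_plane_spacing: tuple[float, float]
    slice_spacing: float
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        if len(self.shape) != 3 or any(int(s) <= 0 for s in self.shape):
            raise ValueError(f"shape must be 3 positive integers, got {self.shape}")
        if any(s <= 0 for s in self.in_plane_spacing) or self.slice_spacing <= 0:
            raise ValueError("spacings must be strictly positive")

    @property
    def spacing(self) -> tuple[float, float, float]:
        return (*self.in_plane_spacing, self.slice_spacing)

    def voxel_volume_mm3(self) -> float:
        return float(np.prod(self.spacing))

    def axis_coords(self, axis: int) -> np.ndarray:
        """Physical coordinates of voxel centers along one axis."""
        return self.origin[axis] + np.arange(self.shape[axis]) * self.spacing[axis]


@dataclass
class ImageVolume:
    """A 3D scalar grid (row, column, slice) with axial geometry in mm."""

    data: np.ndarray
    in_plane_spacing: tuple[float, float]
    slice_spacing: float
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)
    description: str = ""

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float64)
        if self.data.ndim != 3:
            raise FormatError(f"volume data must be 3D, got {self.data.ndim}D")
        self.in_plane_spacing = (float(self.in_plane_spacing[0]), float(self.in_plane_spacing[1]))
        self.slice_spacing = float(self.slice_spacing)
        self.origin = tuple(float(o) for o in self.origin)
        if any(s <= 0 for s in self.in_plane_spacing) or self.slice_spacing <= 0:
            raise FormatError("voxel spacings must be strictly positive")

    @property
    def grid(self) -> GridSpec:
        return GridSpec(self.data.shape, self.in_plane_spacing, self.slice_spacing, self.origin)

    @property
    def valid_mask(self) -> np.ndarray:
        return np.isfinite(self.data)

    def with_data(self, data: np.ndarray, description: str | None = None) -> "ImageVolume":
        return ImageVolume(
            data,
            self.in_plane_spacing,
            self.slice_spacing,
            self.origin,
            self.description if description is None else description,
        )


@dataclass(frozen=True)
class Contour:
    """A closed planar polygon on one slice; first vertex not repeated."""

    slice_index: int
    vertices_mm: np.ndarray  # (n, 2) float, (x, y) in mm

    def __post_init__(self) -> None:
        v = np.asarray(self.vertices_mm, dtype=np.float64)
        if v.ndim != 2 or v.shape[1] != 2 or v.shape[0] < 3:
            raise FormatError(
                f"contour on slice {self.slice_index} needs >= 3 (x, y) vertices, got shape {v.shape}"
            )
        object.__setattr__(self, "vertices_mm", v)

    def polygon(self) -> shapely.Polygon:
        return shapely.Polygon(self.vertices_mm)


@dataclass
class ContourStack:
    """Ordered per-slice closed polygons delineating one structure."""

    contours: list[Contour]
    frame_spacing: float  # mm between contour planes

    def __post_init__(self) -> None:
        if self.frame_spacing <= 0:
            raise FormatError("frame_spacing must be strictly positive")
        indices = [c.slice_index for c in self.contours]
        if len(set(indices)) != len(indices):
            dup = sorted({i for i in indices if indices.count(i) > 1})
            raise FormatError(f"duplicate contour slice indices: {dup}")
        self.contours = sorted(self.contours, key=lambda c: c.slice_index)

    def __len__(self) -> int:
        return len(self.contours)

    def slice_indices(self) -> list[int]:
        return [c.slice_index for c in self.contours]

    def translated(self, dx: float, dy: float) -> "ContourStack":
        moved = [
            Contour(c.slice_index, c.vertices_mm + np.array([dx, dy]))
            for c in self.contours
        ]
        return ContourStack(moved, self.frame_spacing)


# ---------------------------------------------------------------------------
# NIfTI I/O
# ---------------------------------------------------------------------------

def write_volume(volume: ImageVolume, path: str | Path) -> None:
    """Write an :class:`ImageVolume` to a NIfTI-1 file.

    Spacing goes to ``pixdim``, origin to the affine translation, the
    description to the header ``descrip`` field (truncated to 79 bytes).
    """
    affine = np.diag([*volume.in_plane_spacing, volume.slice_spacing, 1.0])
    affine[:3, 3] = volume.origin
    img = nib.Nifti1Image(volume.data, affine)
    img.header.set_zooms((*volume.in_plane_spacing, volume.slice_spacing))
    img.header["descrip"] = volume.description.encode()[:79]
    nib.save(img, str(path))


def read_volume(path: str | Path) -> ImageVolume:
    """Read a 3D NIfTI file into an :class:`ImageVolume`.

    Raises :class:`FormatError` naming the offending header field when the
    payload is not 3D or a spacing is non-positive.
    """
    try:
        img = nib.load(str(path))
        # nibabel silently repairs zero pixdim; check the on-disk header
        with nib.openers.Opener(str(path)) as f:
            raw_hdr = nib.Nifti1Header.from_fileobj(f, check=False)
    except FormatError:
        raise
    except Exception as exc:  # nibabel raises several types for bad files
        raise FormatError(f"cannot read NIfTI file {path}: {exc}") from exc
    raw_zooms = np.asarray(raw_hdr["pixdim"][1:4], dtype=float)
    if np.any(raw_zooms <= 0):
        raise FormatError(f"{path}: header pixdim contains non-positive spacing {raw_zooms}")
    data = np.asanyarray(img.dataobj)
    if data.ndim == 4 and data.shape[3] == 1:
        data = data[..., 0]
    if data.ndim != 3:
        raise FormatError(f"{path}: expected a 3D payload, header dim gives {data.ndim}D")
    zooms = img.header.get_zooms()[:3]
    if any(z <= 0 for z in zooms):
        raise FormatError(f"{path}: header pixdim contains non-positive spacing {zooms}")
    origin = tuple(float(x) for x in img.affine[:3, 3])
    descrip = bytes(img.header["descrip"].tobytes()).split(b"\x00")[0].decode(errors="replace")
    return ImageVolume(
        np.asarray(data, dtype=np.float64),
        (float(zooms[0]), float(zooms[1])),
        float(zooms[2]),
        origin,
        descrip,
    )


# ---------------------------------------------------------------------------
# Contour JSON I/O
#
# Schema: {"frame_spacing_mm": float,
#          "contours": [{"slice": int, "vertices_mm": [[x, y], ...]}, ...]}
# ---------------------------------------------------------------------------

def write_contours(stack: ContourStack, path: str | Path) -> None:
    payload = {
        "frame_spacing_mm": stack.frame_spacing,
        "contours": [
            {
                "slice": int(c.slice_index),
                "vertices_mm": [[round(float(x), 6), round(float(y), 6)] for x, y in c.vertices_mm],
            }
            for c in stack.contours
        ],
    }
    Path(path).write_text(json.dumps(payload, indent=1))


def read_contours(path: str | Path) -> ContourStack:
    try:
        payload = json.loads(Path(path).read_text())
        contours = [
            Contour(int(c["slice"]), np.asarray(c["vertices_mm"], dtype=np.float64))
            for c in payload["contours"]
        ]
        return ContourStack(contours, float(payload["frame_spacing_mm"]))
    except (KeyError, TypeError, json.JSONDecodeError) as exc:
        raise FormatError(f"{path}: malformed contour JSON: {exc}") from exc


# ---------------------------------------------------------------------------
# Regridding
# ---------------------------------------------------------------------------

def regrid_volume(source: ImageVolume, target: GridSpec, method: str = "trilinear") -> ImageVolume:
    """Resample ``source`` onto ``target`` in physical coordinates.

    Translation + resolution change only (shared axial frame).  Trilinear
    interpolation weights the 8 surrounding source voxel centers; any
    invalid neighbor with nonzero weight invalidates the output voxel.
    Target voxels whose centers fall outside the source extent (beyond the
    outermost voxel centers) are invalid.
    """
    if method not in ("nearest", "trilinear"):
        raise ValueError(f"unknown regrid method {method!r}")
    src = source.data
    # fractional source indices of every target voxel center, per axis
    frac = []
    for axis in range(3):
        coords = target.axis_coords(axis)
        f = (coords - source.origin[axis]) / source.grid.spacing[axis]
        frac.append(f)
    fi, fj, fk = np.meshgrid(*frac, indexing="ij")
    inside = (
        (fi >= 0) & (fi <= src.shape[0] - 1)
        & (fj >= 0) & (fj <= src.shape[1] - 1)
        & (fk >= 0) & (fk <= src.shape[2] - 1)
    )

    if method == "nearest":
        idx = [np.clip(np.rint(f).astype(int), 0, n - 1) for f, n in zip((fi, fj, fk), src.shape)]
        out = src[idx[0], idx[1], idx[2]]
    else:
        lo = [np.clip(np.floor(f).astype(int), 0, n - 1) for f, n in zip((fi, fj, fk), src.shape)]
        hi = [np.minimum(l + 1, n - 1) for l, n in zip(lo, src.shape)]
        w = [np.clip(f - l, 0.0, 1.0) for f, l in zip((fi, fj, fk), lo)]
        out = np.zeros(target.shape)
        for ci in range(2):
            for cj in range(2):
                for ck in range(2):
                    wi = w[0] if ci else 1.0 - w[0]
                    wj = w[1] if cj else 1.0 - w[1]
                    wk = w[2] if ck else 1.0 - w[2]
                    weight = wi * wj * wk
                    vals = src[
                        hi[0] if ci else lo[0],
                        hi[1] if cj else lo[1],
                        hi[2] if ck else lo[2],
                    ]
                    # zero-weight corners never contribute (keeps identity
                    # regrids exact next to invalid voxels)
                    out += np.where(weight > 0, weight * vals, 0.0)
    out = np.where(inside, out, INVALID)
    return ImageVolume(
        out, target.in_plane_spacing, target.slice_spacing, target.origin, source.description
    )


# ---------------------------------------------------------------------------
# Rasterization
# ---------------------------------------------------------------------------

def rasterize_contours(stack: ContourStack, target: GridSpec) -> ImageVolume:
    """Binary mask: voxel is 1 iff its physical center lies inside (or on
    the boundary of) the polygon of its slice; contour-free slices are 0."""
    bad = [c.slice_index for c in stack.contours if not 0 <= c.slice_index < target.shape[2]]
    if bad:
        raise FrameError(
            f"contour slice indices {bad} outside target slice range [0, {target.shape[2] - 1}]"
        )
    mask = np.zeros(target.shape)
    xs = target.axis_coords(0)
    ys = target.axis_coords(1)
    gx, gy = np.meshgrid(xs, ys, indexing="ij")
    for c in stack.contours:
        poly = c.polygon()
        inside = shapely.intersects_xy(poly, gx.ravel(), gy.ravel())
        mask[:, :, c.slice_index] = inside.reshape(gx.shape)
    return ImageVolume(mask, target.in_plane_spacing, target.slice_spacing, target.origin, "mask")
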