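"""Voxel lattices, short-axis contour stacks, rasterization and mass.

The left-ventricular wall is represented two ways: as a stack of per-slice
epicardial/endocardial contours (the form in which it is delineated on
short-axis CT reformats) and as a boolean voxel mask on an axis-aligned
lattice.  Rasterization converts the former to the latter with an exact,
documented rule: a voxel belongs to the myocardium iff its *center* lies
inside the epicardial polygon and outside the endocardial polygon of its
slice, inside/outside decided by the even-odd (crossing-number) rule.

Myocardial mass follows from voxel count, voxel volume and tissue density
(default 1.055 g/mL, the standard average density of myocardium).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from shapely.geometry import Polygon as _ShapelyPolygon

#: Average density of myocardial tissue, grams per millilitre.
MYOCARDIAL_DENSITY_G_PER_ML = 1.055

#: Default in-plane voxel spacing of the analysis grid, mm.
DEFAULT_INPLANE_SPACING_MM = 1.0

#: Default short-axis inter-slice spacing, mm.
DEFAULT_SLICE_SPACING_MM = 4.0


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ImageGrid:
    """Axis-aligned voxel lattice in world millimetres.

    ``origin`` is the world position of the *center* of voxel index
    (0, 0, 0); the center of voxel (i, j, k) is ``origin + (i,j,k)*spacing``
    (voxel-center convention, 0-based indices).
    """

    dims: tuple[int, int, int]
    spacing: tuple[float, float, float]
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        dims = tuple(int(d) for d in self.dims)
        spacing = tuple(float(s) for s in self.spacing)
        origin = tuple(float(o) for o in self.origin)
        if len(dims) != 3 or len(spacing) != 3 or len(origin) != 3:
            raise ValueError("ImageGrid requires 3D dims, spacing and origin")
        if any(d < 1 for d in dims):
            raise ValueError(f"grid dims must be >= 1 per axis, got {dims}")
        if any(s <= 0 for s in spacing):
            raise ValueError(f"grid spacing must be > 0 per axis, got {spacing}")
        object.__setattr__(self, "dims", dims)
        object.__setattr__(self, "spacing", spacing)
        object.__setattr__(self, "origin", origin)

    @property
    def voxel_volume_mm3(self) -> float:
        sx, sy, sz = self.spacing
        return sx * sy * sz

    def voxel_centers_inplane(self) -> tuple[np.ndarray, np.ndarray]:
        """World (x, y) coordinates of voxel centers of one slice.

        Returns two arrays of shape (nx, ny).
        """
        nx, ny, _ = self.dims
        x = self.origin[0] + np.arange(nx) * self.spacing[0]
        y = self.origin[1] + np.arange(ny) * self.spacing[1]
        return np.meshgrid(x, y, indexing="ij")

    def slice_index(self, z_mm: float, tol: float = 1e-6) -> int:
        """Grid slice index whose plane contains world z (voxel-center z)."""
        k = (float(z_mm) - self.origin[2]) / self.spacing[2]
        k_int = int(round(k))
        if abs(k - k_int) > tol:
            raise ValueError(
                f"slice at z={z_mm} mm does not lie on the grid lattice "
                f"(origin_z={self.origin[2]}, spacing_z={self.spacing[2]})"
            )
        if not 0 <= k_int < self.dims[2]:
            raise ValueError(
                f"slice at z={z_mm} mm (index {k_int}) is outside the grid "
                f"extent of {self.dims[2]} slices"
            )
        return k_int

    def world_index(self, points_mm: np.ndarray) -> np.ndarray:
        """Nearest voxel index of world points, shape (N, 3), unclipped."""
        pts = np.asarray(points_mm, dtype=float)
        return np.rint(
            (pts - np.asarray(self.origin)) / np.asarray(self.spacing)
        ).astype(int)


@dataclass(frozen=True)
class ContourSlice:
    """Epicardial and (optional) endocardial polygon of one short-axis slice.

    Polygons are (N, 2) arrays of world-mm in-plane points, implicitly
    closed (last vertex connects back to the first).  ``endo`` is None on
    apical-cap slices where the wall is solid.
    """

    z_mm: float
    epi: np.ndarray
    endo: np.ndarray | None = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "epi", _as_polygon(self.epi, f"epi@z={self.z_mm}"))
        if self.endo is not None:
            object.__setattr__(
                self, "endo", _as_polygon(self.endo, f"endo@z={self.z_mm}")
            )
        _validate_slice(self)


@dataclass(frozen=True)
class ContourStack:
    """Ordered stack of short-axis contour slices (apex to base)."""

    slices: tuple[ContourSlice, ...]
    slice_spacing: float

    def __post_init__(self) -> None:
        if self.slice_spacing <= 0:
            raise ValueError("slice_spacing must be > 0")
        object.__setattr__(self, "slices", tuple(self.slices))

    def all_points_3d(self) -> np.ndarray:
        """Every contour vertex as a world-mm (N, 3) point cloud.

        Slices in stack order, epicardium before endocardium per slice;
        this ordering makes point clouds from equally-sampled stacks
        correspond point-by-point (used by rigid registration).
        """
        out = []
        for s in self.slices:
            for poly in (s.epi, s.endo):
                if poly is None:
                    continue
                z = np.full((len(poly), 1), s.z_mm)
                out.append(np.hstack([poly, z]))
        return np.vstack(out)


@dataclass
class VoxelMask:
    """Boolean or small-integer label volume on an ImageGrid."""

    grid: ImageGrid
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        if self.values.shape != tuple(self.grid.dims):
            raise ValueError(
                f"mask shape {self.values.shape} != grid dims {self.grid.dims}"
            )
        if self.values.dtype != bool and np.any(self.values < 0):
            raise ValueError("mask labels must be non-negative")

    @property
    def count(self) -> int:
        return int(np.count_nonzero(self.values))

    def astype_bool(self) -> np.ndarray:
        return self.values.astype(bool)


# ---------------------------------------------------------------------------
# Polygon machinery
# ---------------------------------------------------------------------------

def _as_polygon(poly: Sequence, name: str) -> np.ndarray:
    arr = np.asarray(poly, dtype=float)
    if arr.ndim != 2 or arr.shape[1] != 2 or arr.shape[0] < 3:
        raise ValueError(f"polygon {name} must be (N>=3, 2) points")
    # drop an explicitly repeated closing vertex
    if np.allclose(arr[0], arr[-1]):
        arr = arr[:-1]
    if arr.shape[0] < 3:
        raise ValueError(f"polygon {name} degenerates to fewer than 3 vertices")
    return arr


def _validate_slice(s: ContourSlice) -> None:
    epi = _ShapelyPolygon(s.epi)
    if not epi.is_simple or not epi.is_valid:
        raise ValueError(f"self-intersecting epicardial polygon at z={s.z_mm} mm")
    if s.endo is not None:
        endo = _ShapelyPolygon(s.endo)
        if not endo.is_simple or not endo.is_valid:
            raise ValueError(
                f"self-intersecting endocardial polygon at z={s.z_mm} mm"
            )
        if not epi.buffer(1e-9).contains(endo):
            raise ValueError(
                f"endocardial contour not inside epicardial contour at "
                f"z={s.z_mm} mm"
            )


def points_in_polygon(points: np.ndarray, polygon: np.ndarray) -> np.ndarray:
    """Even-odd (crossing number) point-in-polygon test, vectorized.

    ``points``: (N, 2); ``polygon``: (M, 2), implicitly closed.  A point on
    an edge resolves by the half-open ray rule (deterministic, consistent
    for adjacent polygons sharing an edge).
    """
    pts = np.asarray(points, dtype=float)
    poly = np.asarray(polygon, dtype=float)
    x, y = pts[:, 0][:, None], pts[:, 1][:, None]
    x0, y0 = poly[:, 0][None, :], poly[:, 1][None, :]
    x1, y1 = np.roll(poly[:, 0], -1)[None, :], np.roll(poly[:, 1], -1)[None, :]
    straddles = (y0 > y) != (y1 > y)
    with np.errstate(divide="ignore", invalid="ignore"):
        x_at_y = x0 + (y - y0) * (x1 - x0) / (y1 - y0)
    crossings = straddles & (x < x_at_y)
    return (crossings.sum(axis=1) % 2).astype(bool)


# ---------------------------------------------------------------------------
# Operations
# ---------------------------------------------------------------------------

def rasterize_myocardium(contours: ContourStack, grid: ImageGrid) -> VoxelMask:
    """Rasterize an epi/endo contour stack into a myocardium voxel mask.

    A voxel is myocardial iff its center is inside the slice's epicardial
    polygon and outside its endocardial polygon (even-odd rule).  Grid
    slices without a contour contribute no voxels.  A contour slice whose
    plane is off the lattice or outside the grid extent raises, naming the
    slice.
    """
    values = np.zeros(grid.dims, dtype=bool)
    gx, gy = grid.voxel_centers_inplane()
    pts = np.column_stack([gx.ravel(), gy.ravel()])
    for s in contours.slices:
        k = grid.slice_index(s.z_mm)
        inside = points_in_polygon(pts, s.epi)
        if s.endo is not None:
            inside &= ~points_in_polygon(pts, s.endo)
        values[:, :, k] = inside.reshape(gx.shape)
    return VoxelMask(grid, values)


def compute_mass(
    mask: VoxelMask, density: float = MYOCARDIAL_DENSITY_G_PER_ML
) -> float:
    """Mass in grams of the nonzero voxels of ``mask``.

    mass = count x voxel volume [mm^3] x 1e-3 [mL/mm^3] x density [g/mL].
    """
    if density <= 0:
        raise ValueError("density must be > 0")
    return mask.count * mask.grid.voxel_volume_mm3 * 1e-3 * density


def voxel_mass_g(
    grid: ImageGrid, density: float = MYOCARDIAL_DENSITY_G_PER_ML
) -> float:
    """Mass in grams of a single voxel of ``grid``."""
    return grid.voxel_volume_mm3 * 1e-3 * density


def circle_polygon(
    cx: float, cy: float, radius: float, n_vertices: int = 180
) -> np.ndarray:
    """Regular n-gon approximating a circle (counterclockwise)."""
    if radius <= 0:
        raise ValueError("radius must be > 0")
    t = np.linspace(0.0, 2.0 * np.pi, n_vertices, endpoint=False)
    return np.column_stack([cx + radius * np.cos(t), cy + radius * np.sin(t)])
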