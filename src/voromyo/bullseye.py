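"""Polar (bullseye) resampling of myocardial masks.

Short-axis quantities are conventionally displayed on a bullseye plot:
apex at the center, base at the rim, each slice a ring, each ring divided
into angular sectors about the slice's LV centroid.  Here a voxel mask
(myocardium, a lesion territory, or a defect) is binned into
(ring, sector) cells carrying mass in grams, with exact mass conservation
at every aggregation level, and optionally merged into the standard
17-segment model (6 basal / 6 mid / 4 apical / 1 apex).

Angular convention: the zero direction is configurable (phantoms place it
at the anterior RV-insertion direction), angles increase counterclockwise
in the (x, y) slice plane.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from shapely.geometry import Polygon as _ShapelyPolygon

from .geometry import (
    ContourStack,
    MYOCARDIAL_DENSITY_G_PER_ML,
    VoxelMask,
    voxel_mass_g,
)

DEFAULT_N_SECTORS = 36


@dataclass
class PolarMap:
    """Per-(ring, sector) mass in grams, rings ordered apex to base."""

    ring_z_mm: list[float]
    n_sectors: int
    zero_angle_deg: float
    values: np.ndarray  # (n_rings, n_sectors), grams
    ring_has_endo: list[bool] | None = None

    @property
    def total_mass(self) -> float:
        return float(self.values.sum())

    @property
    def sector_width_deg(self) -> float:
        return 360.0 / self.n_sectors


def polar_sample(
    mask: VoxelMask,
    contours: ContourStack,
    n_sectors: int = DEFAULT_N_SECTORS,
    zero_angle_deg: float = 0.0,
    density: float = MYOCARDIAL_DENSITY_G_PER_ML,
) -> PolarMap:
    """Bin a voxel mask into a (ring, sector) polar mass map.

    Each nonzero voxel is binned by its slice (one ring per contour slice,
    apex to base) and by the angle of its center about the epicardial
    centroid of that slice.  Mask voxels on slices without a contour are
    skipped with a warning; otherwise the sector masses sum exactly to the
    mask's mass.
    """
    if n_sectors < 4:
        raise ValueError("n_sectors must be >= 4")
    grid = mask.grid
    vm = voxel_mass_g(grid, density)
    slices = sorted(contours.slices, key=lambda s: s.z_mm)
    k_of_slice = {grid.slice_index(s.z_mm): s for s in slices}
    values = np.zeros((len(slices), n_sectors))
    ring_index = {grid.slice_index(s.z_mm): r for r, s in enumerate(slices)}
    occupied = np.unique(np.argwhere(mask.astype_bool())[:, 2])
    uncovered = [int(k) for k in occupied if k not in k_of_slice]
    if uncovered:
        warnings.warn(
            f"mask voxels on {len(uncovered)} slice(s) without a contour "
            f"(grid slices {uncovered}) are skipped",
            stacklevel=2,
        )
    width = 360.0 / n_sectors
    for k in occupied:
        if k not in k_of_slice:
            continue
        s = k_of_slice[k]
        centroid = _ShapelyPolygon(s.epi).centroid
        ij = np.argwhere(mask.values[:, :, k])
        x = grid.origin[0] + ij[:, 0] * grid.spacing[0] - centroid.x
        y = grid.origin[1] + ij[:, 1] * grid.spacing[1] - centroid.y
        ang = (np.degrees(np.arctan2(y, x)) - zero_angle_deg) % 360.0
        sec = np.minimum((ang / width).astype(int), n_sectors - 1)
        values[ring_index[k]] += np.bincount(sec, minlength=n_sectors) * vm
    return PolarMap(
        [s.z_mm for s in slices], n_sectors, zero_angle_deg, values,
        [s.endo is not None for s in slices],
    )


def _default_ring_groups(polar: PolarMap) -> list[np.ndarray]:
    """Apex / apical / mid / basal ring index groups, apex first.

    Apex-cap rings are those without an endocardial contour (solid tip);
    if none are flagged, the single most apical ring is the apex.  The
    remaining rings split into three near-equal groups (extra rings go to
    the more apical group).
    """
    n = polar.values.shape[0]
    if polar.ring_has_endo is not None and not all(polar.ring_has_endo):
        apex = np.array(
            [i for i, has in enumerate(polar.ring_has_endo) if not has]
        )
    else:
        apex = np.array([0])
    rest = np.array([i for i in range(n) if i not in set(apex.tolist())])
    thirds = np.array_split(rest, 3)  # apical, mid, basal (apex-first order)
    return [apex, *thirds]


def aggregate_17_segment(
    polar: PolarMap, ring_groups: list[np.ndarray] | None = None
) -> np.ndarray:
    """Merge a polar map into the standard 17-segment model.

    Segments 1-6: basal sextants, 7-12: mid sextants (60 deg each),
    13-16: apical quadrants (90 deg), 17: apex cap.  Sector count must be
    divisible by 12 so sextant and quadrant edges fall on sector edges.
    Returns masses in grams, ordered segment 1..17; their sum equals the
    polar map's total mass.
    """
    n_rings, n_sectors = polar.values.shape
    if n_rings < 3:
        raise ValueError("17-segment aggregation needs at least 3 rings")
    if n_sectors % 12 != 0:
        raise ValueError("sector count must be divisible by 12")
    groups = ring_groups if ring_groups is not None else _default_ring_groups(polar)
    if len(groups) != 4:
        raise ValueError("ring_groups must be [apex, apical, mid, basal]")
    apex, apical, mid, basal = groups
    out = np.zeros(17)

    def merge(rings: np.ndarray, n_segments: int) -> np.ndarray:
        per = n_sectors // n_segments
        ring_sum = polar.values[rings].sum(axis=0)
        return ring_sum.reshape(n_segments, per).sum(axis=1)

    out[0:6] = merge(basal, 6)
    out[6:12] = merge(mid, 6)
    out[12:16] = merge(apical, 4)
    out[16] = polar.values[apex].sum()
    return out


def render_bullseye(polar: PolarMap, path: str, title: str = "") -> None:
    """Write a bullseye figure (PNG/SVG by extension) of a polar map."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    n_rings, n_sectors = polar.values.shape
    theta = np.radians(
        np.linspace(0, 360, n_sectors + 1) + polar.zero_angle_deg
    )
    r = np.arange(n_rings + 1)
    fig, ax = plt.subplots(subplot_kw={"projection": "polar"})
    tt, rr = np.meshgrid(theta, r)
    pcm = ax.pcolormesh(tt, rr, polar.values, cmap="inferno")
    ax.set_yticks([])
    ax.set_title(title or "mass per (ring, sector), g")
    fig.colorbar(pcm, ax=ax, label="g")
    fig.savefig(path, dpi=120)
    plt.close(fig)
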