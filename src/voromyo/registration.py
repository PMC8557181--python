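"""Rigid alignment of the stress-perfusion frame to the rest-CT frame.

Perfusion defects are drawn on the stress acquisition but measured inside
the myocardium delineated on the resting scan, so the stress frame must be
aligned to the rest frame first.  Alignment is rigid (rotation +
translation): for corresponding point sets (equally sampled epi/endo
contour stacks) the closed-form least-squares solution (Kabsch/SVD) is
used; for unmatched sets an iterative-closest-point loop refines the
correspondence.  Defect masks are resampled with nearest-neighbor
interpolation so they stay binary.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial import cKDTree

from .geometry import ImageGrid, VoxelMask

_ICP_MAX_ITER = 100
_ICP_RMS_TOL_MM = 1e-4


@dataclass(frozen=True)
class RigidTransform:
    """Proper rigid transform x -> R x + t in world millimetres."""

    rotation: np.ndarray
    translation: np.ndarray

    def __post_init__(self) -> None:
        R = np.asarray(self.rotation, dtype=float)
        t = np.asarray(self.translation, dtype=float).reshape(3)
        if R.shape != (3, 3):
            raise ValueError("rotation must be a 3x3 matrix")
        if not np.allclose(R @ R.T, np.eye(3), atol=1e-6) or np.linalg.det(R) < 0:
            raise ValueError("rotation must be orthonormal with determinant +1")
        object.__setattr__(self, "rotation", R)
        object.__setattr__(self, "translation", t)

    @staticmethod
    def identity() -> "RigidTransform":
        return RigidTransform(np.eye(3), np.zeros(3))

    def apply(self, points: np.ndarray) -> np.ndarray:
        pts = np.asarray(points, dtype=float)
        return pts @ self.rotation.T + self.translation

    def inverse(self) -> "RigidTransform":
        return RigidTransform(self.rotation.T, -self.rotation.T @ self.translation)

    def compose(self, other: "RigidTransform") -> "RigidTransform":
        """Transform equal to applying ``other`` first, then ``self``."""
        return RigidTransform(
            self.rotation @ other.rotation,
            self.rotation @ other.translation + self.translation,
        )

    def matrix(self) -> np.ndarray:
        """4x4 homogeneous matrix."""
        m = np.eye(4)
        m[:3, :3] = self.rotation
        m[:3, 3] = self.translation
        return m

    @staticmethod
    def from_matrix(m: np.ndarray) -> "RigidTransform":
        m = np.asarray(m, dtype=float)
        if m.shape != (4, 4):
            raise ValueError("homogeneous matrix must be 4x4")
        return RigidTransform(m[:3, :3], m[:3, 3])

    def rotation_angle_deg(self) -> float:
        """Magnitude of the rotation, degrees."""
        c = (np.trace(self.rotation) - 1.0) / 2.0
        return float(np.degrees(np.arccos(np.clip(c, -1.0, 1.0))))


def _check_noncollinear(points: np.ndarray, name: str) -> None:
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 3 or pts.shape[0] < 3:
        raise ValueError(f"{name} point set must be (N>=3, 3)")
    centered = pts - pts.mean(axis=0)
    s = np.linalg.svd(centered, compute_uv=False)
    if s[1] <= 1e-9 * max(s[0], 1.0):
        raise ValueError(f"{name} point set is collinear (degenerate)")


def _kabsch(moving: np.ndarray, fixed: np.ndarray) -> RigidTransform:
    """Least-squares rigid transform mapping corresponding moving->fixed."""
    cm, cf = moving.mean(axis=0), fixed.mean(axis=0)
    H = (moving - cm).T @ (fixed - cf)
    U, _, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    R = Vt.T @ np.diag([1.0, 1.0, d]) @ U.T
    return RigidTransform(R, cf - R @ cm)


def estimate_rigid(
    moving_points: np.ndarray, fixed_points: np.ndarray
) -> RigidTransform:
    """Estimate the rigid transform aligning ``moving`` onto ``fixed``.

    Equal-length inputs are treated as corresponding point sets and solved
    in closed form (Kabsch).  Unequal-length inputs are aligned by
    iterative closest point: nearest-neighbor correspondence to the fixed
    set, Kabsch update, until the RMS residual changes by less than
    1e-4 mm or 100 iterations.
    """
    moving = np.asarray(moving_points, dtype=float)
    fixed = np.asarray(fixed_points, dtype=float)
    _check_noncollinear(moving, "moving")
    _check_noncollinear(fixed, "fixed")
    if len(moving) == len(fixed):
        return _kabsch(moving, fixed)
    # ICP with centroid initialization
    transform = RigidTransform(np.eye(3), fixed.mean(axis=0) - moving.mean(axis=0))
    kd = cKDTree(fixed)
    prev_rms = np.inf
    for _ in range(_ICP_MAX_ITER):
        warped = transform.apply(moving)
        dist, nn = kd.query(warped)
        rms = float(np.sqrt(np.mean(dist**2)))
        if abs(prev_rms - rms) < _ICP_RMS_TOL_MM:
            break
        prev_rms = rms
        transform = _kabsch(moving, fixed[nn])
    return transform


def apply_transform_mask(
    mask: VoxelMask, transform: RigidTransform, target_grid: ImageGrid
) -> VoxelMask:
    """Resample ``mask`` onto ``target_grid`` under ``transform``.

    ``transform`` maps mask (moving) world coordinates to target (fixed)
    world coordinates.  Each target voxel center is pulled back through the
    inverse transform and filled by nearest-neighbor lookup; centers
    mapping outside the source extent become background.
    """
    inv = transform.inverse()
    nx, ny, nz = target_grid.dims
    ii, jj, kk = np.meshgrid(
        np.arange(nx), np.arange(ny), np.arange(nz), indexing="ij"
    )
    centers = (
        np.asarray(target_grid.origin)
        + np.column_stack([ii.ravel(), jj.ravel(), kk.ravel()])
        * np.asarray(target_grid.spacing)
    )
    src = inv.apply(centers)
    src_idx = np.rint(
        (src - np.asarray(mask.grid.origin)) / np.asarray(mask.grid.spacing)
    ).astype(int)
    inb = np.all((src_idx >= 0) & (src_idx < np.asarray(mask.grid.dims)), axis=1)
    out = np.zeros(target_grid.dims, dtype=mask.values.dtype)
    vals = np.zeros(len(centers), dtype=mask.values.dtype)
    vals[inb] = mask.values[
        src_idx[inb, 0], src_idx[inb, 1], src_idx[inb, 2]
    ]
    out[ii.ravel(), jj.ravel(), kk.ravel()] = vals
    return VoxelMask(target_grid, out)


def rotation_about_axis(axis: np.ndarray, angle_deg: float) -> np.ndarray:
    """Rotation matrix about a (not necessarily unit) axis, Rodrigues form."""
    a = np.asarray(axis, dtype=float)
    a = a / np.linalg.norm(a)
    th = np.radians(angle_deg)
    K = np.array([[0, -a[2], a[1]], [a[2], 0, -a[0]], [-a[1], a[0], 0]])
    return np.eye(3) + np.sin(th) * K + (1 - np.cos(th)) * (K @ K)
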