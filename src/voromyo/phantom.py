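"""Parametric ground-truth phantoms: LV shells, coronary trees, defects.

No public imaging data accompany the quantification method, so every stage
is exercised on synthetic cases with recorded ground truth.  The left
ventricle is a half-ellipsoid shell (apex at z = 0, base at z = L)
discretized into short-axis contour slices; coronary branches run on the
epicardial surface along parametric (height, angle) paths with the LAD
anterior, the circumflex lateral and the RCA inferior; perfusion defects
are connected voxel blobs grown inside (or straddling) lesion territories
by seeded region growing, with exact per-territory voxel counts recorded.

Default dimensions target the population the method was applied to: LV
masses of roughly 60-260 g (default ~117 g), one to four lesions on the
13-label naming scheme, and defects of a few grams.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

from .geometry import (
    ContourSlice,
    ContourStack,
    ImageGrid,
    MYOCARDIAL_DENSITY_G_PER_ML,
    VoxelMask,
    circle_polygon,
    compute_mass,
    rasterize_myocardium,
    voxel_mass_g,
)
from .quantify import percent_distributed
from .registration import RigidTransform, apply_transform_mask, rotation_about_axis
from .territories import (
    TerritoryLabelMap,
    assign_voxels_to_tree,
    lesion_territories,
    subtended_mass_per_lesion,
    total_subtended_mass,
)
from .tree import Branch, CenterlineTree, Lesion, resample_centerlines, select_most_proximal_lesions

#: Angular position of the anterior LV wall (LAD course) in the slice
#: plane, degrees; doubles as the bullseye zero-angle reference.
ANTERIOR_ANGLE_DEG = 90.0


# ---------------------------------------------------------------------------
# Specs
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class LVGeometry:
    """Half-ellipsoid LV shell parameters, millimetres."""

    long_axis_mm: float = 80.0
    basal_epi_radius_mm: float = 33.5
    wall_thickness_mm: float = 10.5
    slice_spacing_mm: float = 4.0
    inplane_spacing_mm: float = 1.0

    def __post_init__(self) -> None:
        if self.wall_thickness_mm >= self.basal_epi_radius_mm:
            raise ValueError("wall thickness must be < basal epicardial radius")
        if min(self.long_axis_mm, self.slice_spacing_mm,
               self.inplane_spacing_mm) <= 0:
            raise ValueError("LV geometry lengths must be > 0")

    def epi_radius(self, h: np.ndarray | float) -> np.ndarray | float:
        """Epicardial radius at height h above the apex."""
        L, R = self.long_axis_mm, self.basal_epi_radius_mm
        return R * np.sqrt(np.clip(1.0 - ((L - h) / L) ** 2, 0.0, None))

    def endo_radius(self, h: float) -> float | None:
        """Endocardial radius at height h, or None below the apical cap."""
        L, R, t = self.long_axis_mm, self.basal_epi_radius_mm, self.wall_thickness_mm
        if h <= t:
            return None
        r = (R - t) * math.sqrt(
            max(0.0, 1.0 - ((L - h) / (L - t)) ** 2)
        )
        return r if r > 1e-9 else None

    @property
    def analytic_shell_volume_mm3(self) -> float:
        """Closed-form volume of the half-ellipsoid shell."""
        L, R, t = self.long_axis_mm, self.basal_epi_radius_mm, self.wall_thickness_mm
        return (2.0 * math.pi / 3.0) * (R**2 * L - (R - t) ** 2 * (L - t))


@dataclass(frozen=True)
class BranchSpec:
    """Parametric epicardial course of one branch.

    Heights are fractions of the long axis (1 = base, 0 = apex); angles in
    degrees in the slice plane.  A root gives its own start; a child starts
    at the parent path point at ``attach_frac`` of the parent's arc.
    """

    label: str
    end_h_frac: float
    end_angle_deg: float
    parent: str | None = None
    attach_frac: float = 1.0
    start_h_frac: float | None = None
    start_angle_deg: float | None = None


#: Default 13-branch tree: left main trifurcating into LAD chain (with two
#: diagonals), intermediate branch and circumflex (with marginal and
#: anterolateral branches); right system as a three-segment RCA.
DEFAULT_TREE_SPEC: tuple[BranchSpec, ...] = (
    BranchSpec("LM", 0.93, 105.0, start_h_frac=1.0, start_angle_deg=120.0),
    BranchSpec("pLAD", 0.62, 90.0, parent="LM"),
    BranchSpec("mLAD", 0.30, 90.0, parent="pLAD"),
    BranchSpec("dLAD", 0.04, 90.0, parent="mLAD"),
    BranchSpec("D1", 0.25, 45.0, parent="pLAD", attach_frac=0.5),
    BranchSpec("D2", 0.12, 60.0, parent="mLAD", attach_frac=0.5),
    BranchSpec("IM", 0.35, 140.0, parent="LM"),
    BranchSpec("Cx", 0.40, 200.0, parent="LM"),
    BranchSpec("AL", 0.25, 160.0, parent="Cx", attach_frac=0.2),
    BranchSpec("MO", 0.18, 235.0, parent="Cx", attach_frac=0.5),
    BranchSpec("pRCA", 0.80, 295.0, start_h_frac=1.0, start_angle_deg=300.0),
    BranchSpec("mRCA", 0.55, 285.0, parent="pRCA"),
    BranchSpec("dRCA", 0.08, 270.0, parent="mRCA"),
)


@dataclass(frozen=True)
class DefectSpec:
    """One planted perfusion defect.

    ``target`` is a lesion's branch label (its territory hosts the blob) or
    "background".  ``straddle`` is the mass fraction grown across the
    boundary into ``straddle_into`` (auto-chosen neighbor when None).
    """

    target: str
    mass_g: float
    straddle: float = 0.0
    straddle_into: str | None = None

    def __post_init__(self) -> None:
        if self.mass_g <= 0:
            raise ValueError("target defect mass must be > 0")
        if not 0.0 <= self.straddle < 1.0:
            raise ValueError("straddle fraction must be in [0, 1)")


@dataclass(frozen=True)
class PhantomSpec:
    """Complete parametric description of one synthetic case."""

    lv: LVGeometry = field(default_factory=LVGeometry)
    tree_spec: tuple[BranchSpec, ...] = DEFAULT_TREE_SPEC
    lesions: tuple[tuple[str, float, int], ...] = (("pLAD", 0.1, 50),)
    defects: tuple[DefectSpec, ...] = (DefectSpec("pLAD", 7.0),)
    seed: int = 0
    # rest->stress rigid perturbation: (angle deg about the long axis,
    # translation mm triple); None = stress frame already aligned
    perturbation: tuple[float, tuple[float, float, float]] | None = None

    def __post_init__(self) -> None:
        for _, frac, _ in self.lesions:
            if not 0.0 <= frac <= 1.0:
                raise ValueError("fractional lesion positions must be in [0, 1]")

    def scaled_to_lv_mass(
        self, target_g: float, density: float = MYOCARDIAL_DENSITY_G_PER_ML
    ) -> "PhantomSpec":
        """Isotropically rescale the shell so its analytic mass hits target."""
        current = self.lv.analytic_shell_volume_mm3 * 1e-3 * density
        s = (target_g / current) ** (1.0 / 3.0)
        lv = replace(
            self.lv,
            long_axis_mm=self.lv.long_axis_mm * s,
            basal_epi_radius_mm=self.lv.basal_epi_radius_mm * s,
            wall_thickness_mm=self.lv.wall_thickness_mm * s,
        )
        return replace(self, lv=lv)


# ---------------------------------------------------------------------------
# Generators
# ---------------------------------------------------------------------------

def make_grid(lv: LVGeometry) -> ImageGrid:
    """Analysis grid covering the shell, apex slice first."""
    half = lv.basal_epi_radius_mm + 2.0
    m = int(math.ceil(half / lv.inplane_spacing_mm))
    n_inplane = 2 * m + 1
    n_slices = max(1, int(lv.long_axis_mm / lv.slice_spacing_mm + 1e-9))
    return ImageGrid(
        dims=(n_inplane, n_inplane, n_slices),
        spacing=(lv.inplane_spacing_mm, lv.inplane_spacing_mm,
                 lv.slice_spacing_mm),
        origin=(-m * lv.inplane_spacing_mm, -m * lv.inplane_spacing_mm,
                lv.slice_spacing_mm / 2.0),
    )


def generate_lv_shell(
    spec: PhantomSpec, grid: ImageGrid | None = None
) -> tuple[ContourStack, VoxelMask]:
    """Discretize the half-ellipsoid shell into contours and a voxel mask.

    Slice planes sit at the grid voxel-center heights (k + 1/2) x slice
    spacing above the apex; contours are 180-gon circles at the analytic
    epi/endo radii of each plane, and the mask is their rasterization.
    """
    lv = spec.lv
    if grid is None:
        grid = make_grid(lv)
    slices = []
    for k in range(grid.dims[2]):
        h = grid.origin[2] + k * grid.spacing[2]
        r_epi = float(lv.epi_radius(h))
        if r_epi <= 0:
            continue
        r_endo = lv.endo_radius(h)
        endo = None if r_endo is None else circle_polygon(0, 0, r_endo)
        slices.append(ContourSlice(h, circle_polygon(0, 0, r_epi), endo))
    contours = ContourStack(tuple(slices), lv.slice_spacing_mm)
    return contours, rasterize_myocardium(contours, grid)


def generate_tree(spec: PhantomSpec, points_per_branch: int = 100) -> CenterlineTree:
    """Build the branch polylines on the epicardial surface.

    Each branch interpolates linearly in (height, angle) from its start —
    a root's own start, or the parent path point at the attachment
    fraction — to its end, with the radius pinned to the epicardial
    surface (+0.5 mm standoff).  Parents must precede children in the
    spec.
    """
    lv = spec.lv
    L = lv.long_axis_mm

    def surface_point(h: float, ang_deg: float) -> np.ndarray:
        r = float(lv.epi_radius(h)) + 0.5
        a = math.radians(ang_deg)
        return np.array([r * math.cos(a), r * math.sin(a), h])

    params: dict[str, np.ndarray] = {}  # per-branch (n, 2) of (h, angle)
    branches: list[Branch] = []
    by_label: dict[str, Branch] = {}
    for bs in spec.tree_spec:
        if bs.parent is None:
            if bs.start_h_frac is None or bs.start_angle_deg is None:
                raise ValueError(f"root branch {bs.label!r} needs a start")
            h0, a0 = bs.start_h_frac * L, bs.start_angle_deg
            attach = 0
        else:
            if bs.parent not in by_label:
                raise ValueError(
                    f"branch {bs.label!r}: parent {bs.parent!r} must be "
                    "generated first"
                )
            parent = by_label[bs.parent]
            arcs = parent.arclengths
            attach = int(
                np.argmin(np.abs(arcs - bs.attach_frac * arcs[-1]))
            )
            h0, a0 = params[bs.parent][attach]
        h1, a1 = bs.end_h_frac * L, bs.end_angle_deg
        t = np.linspace(0.0, 1.0, points_per_branch)
        hh = h0 + t * (h1 - h0)
        aa = a0 + t * (a1 - a0)
        pts = np.array([surface_point(h, a) for h, a in zip(hh, aa)])
        if bs.parent is not None:
            pts[0] = by_label[bs.parent].points[attach]
        params[bs.label] = np.column_stack([hh, aa])
        br = Branch(bs.label, pts, bs.parent, attach)
        branches.append(br)
        by_label[bs.label] = br
    return CenterlineTree(tuple(branches))


_NEIGHBOR_OFFSETS = np.array(
    [[1, 0, 0], [-1, 0, 0], [0, 1, 0], [0, -1, 0], [0, 0, 1], [0, 0, -1]]
)


def generate_defect(
    labels: TerritoryLabelMap,
    target: str,
    mass_g: float,
    straddle: float = 0.0,
    rng: np.random.Generator | int | None = None,
    straddle_into: str | None = None,
    density: float = MYOCARDIAL_DENSITY_G_PER_ML,
) -> tuple[VoxelMask, dict[str, int]]:
    """Grow a connected defect blob of a target mass inside a territory.

    Seeded region growing with randomized frontier selection: irregular,
    connected, mass-controllable.  With ``straddle`` > 0 the seed sits on
    the boundary to a neighboring territory and the requested mass
    fraction is grown across it.  Returns the blob mask and the exact
    per-territory voxel counts (keys: lesion branch labels and
    "background") as ground truth.
    """
    if isinstance(rng, (int, np.integer)) or rng is None:
        rng = np.random.default_rng(rng)
    if labels.lesion_label is None or labels.lesion_names is None:
        raise ValueError("territory label map has no lesion territories")
    grid = labels.grid
    vm = voxel_mass_g(grid, density)
    n_total = max(1, int(round(mass_g / vm)))
    n_other = int(round(n_total * straddle))
    n_target = n_total - n_other

    def region_of(name: str) -> np.ndarray:
        if name == "background":
            return labels.myocardium & (labels.lesion_label == 0)
        return labels.territory_mask(name).astype_bool()

    target_region = region_of(target)
    if int(target_region.sum()) < n_target:
        raise ValueError(
            f"territory {target!r} ({int(target_region.sum())} voxels) is too "
            f"small for a {mass_g} g defect ({n_target} voxels)"
        )
    names = ["background"] + list(labels.lesion_names)
    other = None
    if n_other > 0:
        if straddle_into is None:
            # neighbor with the largest shared boundary
            best, best_count = None, -1
            for cand in names:
                if cand == target:
                    continue
                reg = region_of(cand)
                touch = 0
                for off in _NEIGHBOR_OFFSETS:
                    touch += int(
                        (np.roll(target_region, off, axis=(0, 1, 2)) & reg).sum()
                    )
                if touch > best_count:
                    best, best_count = cand, touch
            straddle_into = best
        other = region_of(straddle_into)
        if int(other.sum()) < n_other:
            raise ValueError(
                f"straddle territory {straddle_into!r} too small "
                f"({int(other.sum())} < {n_other} voxels)"
            )

    allowed = target_region | (other if other is not None else False)
    # seed: boundary voxel toward the straddle neighbor, else any target voxel
    if other is not None:
        boundary = np.zeros_like(target_region)
        for off in _NEIGHBOR_OFFSETS:
            boundary |= target_region & np.roll(other, off, axis=(0, 1, 2))
        seed_pool = np.argwhere(boundary) if boundary.any() else np.argwhere(target_region)
        if not boundary.any():
            raise ValueError(
                f"territories {target!r} and {straddle_into!r} share no "
                "boundary; cannot straddle"
            )
    else:
        seed_pool = np.argwhere(target_region)
    seed = tuple(seed_pool[rng.integers(len(seed_pool))])

    quotas = {True: n_target, False: n_other}  # keyed by "is target side"
    taken = np.zeros(grid.dims, dtype=bool)
    counts = {True: 0, False: 0}
    frontier: list[tuple[int, int, int]] = [seed]
    in_frontier = {seed}
    dims = np.asarray(grid.dims)
    while frontier and (counts[True] < quotas[True] or counts[False] < quotas[False]):
        i = rng.integers(len(frontier))
        vox = frontier.pop(int(i))
        in_frontier.discard(vox)
        side = bool(target_region[vox])
        if counts[side] >= quotas[side]:
            continue
        taken[vox] = True
        counts[side] += 1
        for off in _NEIGHBOR_OFFSETS:
            nb = tuple(np.asarray(vox) + off)
            if np.any(np.asarray(nb) < 0) or np.any(np.asarray(nb) >= dims):
                continue
            if allowed[nb] and not taken[nb] and nb not in in_frontier:
                frontier.append(nb)
                in_frontier.add(nb)
    if counts[True] < quotas[True] or counts[False] < quotas[False]:
        raise ValueError(
            f"region growing stalled: placed {counts[True]}+{counts[False]} "
            f"of {n_target}+{n_other} voxels in {target!r}"
        )
    gt = {target: counts[True]}
    if other is not None:
        gt[straddle_into] = counts[False]
    return VoxelMask(grid, taken), gt


# ---------------------------------------------------------------------------
# Complete cases
# ---------------------------------------------------------------------------

@dataclass
class PhantomCase:
    """A complete pipeline input bundle plus its ground-truth record."""

    spec: PhantomSpec
    grid: ImageGrid
    contours: ContourStack
    myocardium: VoxelMask
    tree: CenterlineTree
    lesions: list[Lesion]
    labels: TerritoryLabelMap
    defect: VoxelMask | None
    ground_truth: dict
    # stress frame (present when spec.perturbation is set)
    true_transform: RigidTransform | None = None
    stress_points: np.ndarray | None = None
    defect_stress: VoxelMask | None = None


def generate_case(
    spec: PhantomSpec,
    density: float = MYOCARDIAL_DENSITY_G_PER_ML,
    sample_spacing: float = 0.5,
) -> PhantomCase:
    """Generate a full case and record every reported quantity exactly.

    The ground-truth record holds the rasterized LV mass, per-lesion
    subtended masses, total, per-territory defect voxel counts and masses,
    and the resulting percent distributed — everything the case report
    will print — computed from the generator's own bookkeeping.
    """
    rng = np.random.default_rng(spec.seed)
    grid = make_grid(spec.lv)
    contours, myocardium = generate_lv_shell(spec, grid)
    tree = resample_centerlines(generate_tree(spec), sample_spacing)
    lesions = select_most_proximal_lesions(
        [Lesion.at_fraction(b, f, tree, g) for b, f, g in spec.lesions], tree
    )
    labels = assign_voxels_to_tree(myocardium, tree)
    labels = lesion_territories(labels, tree, lesions)
    sub = subtended_mass_per_lesion(labels, density)
    vm = voxel_mass_g(grid, density)

    defect_values = np.zeros(grid.dims, dtype=bool)
    defect_counts: dict[str, int] = {}
    for ds in spec.defects:
        blob, gt = generate_defect(
            labels, ds.target, ds.mass_g, ds.straddle, rng, ds.straddle_into,
            density,
        )
        defect_values |= blob.values
        for k, v in gt.items():
            defect_counts[k] = defect_counts.get(k, 0) + v
    defect = VoxelMask(grid, defect_values) if spec.defects else None

    per_lesion_defect = {
        l.branch: defect_counts.get(l.branch, 0) * vm for l in lesions
    }
    total_defect = float(sum(defect_counts.values()) * vm)
    gt_record = {
        "lv_mass_g": compute_mass(myocardium, density),
        "analytic_lv_mass_g": spec.lv.analytic_shell_volume_mm3 * 1e-3 * density,
        "subtended_mass_per_lesion_g": sub,
        "total_subtended_mass_g": total_subtended_mass(sub),
        "defect_mass_g": total_defect,
        "defect_mass_per_lesion_g": per_lesion_defect,
        "defect_voxel_counts": defect_counts,
        "percent_distributed": (
            percent_distributed(per_lesion_defect, total_defect)
            if spec.defects else None
        ),
        "voxel_mass_g": vm,
    }

    case = PhantomCase(
        spec, grid, contours, myocardium, tree, lesions, labels, defect,
        gt_record,
    )
    if spec.perturbation is not None and defect is not None:
        angle_deg, translation = spec.perturbation
        T = RigidTransform(
            rotation_about_axis(np.array([0.0, 0.0, 1.0]), angle_deg),
            np.asarray(translation, dtype=float),
        )
        margin_xy, margin_z = 30, 3
        stress_grid = ImageGrid(
            dims=(grid.dims[0] + 2 * margin_xy, grid.dims[1] + 2 * margin_xy,
                  grid.dims[2] + 2 * margin_z),
            spacing=grid.spacing,
            origin=(grid.origin[0] - margin_xy * grid.spacing[0],
                    grid.origin[1] - margin_xy * grid.spacing[1],
                    grid.origin[2] - margin_z * grid.spacing[2]),
        )
        case.true_transform = T
        case.stress_points = T.apply(contours.all_points_3d())
        case.defect_stress = apply_transform_mask(defect, T, stress_grid)
    return case
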