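"""Labeled coronary centerline trees, lesions, and distal subtrees.

A coronary tree is a forest of labeled branch polylines (13-label clinical
vocabulary: LM, p/m/dLAD, D1, D2, Cx, MO, AL, IM, p/m/dRCA).  Each branch
except a root attaches to a point of its parent.  A lesion anchors at an
arc-length position along one branch (its most proximal extent); the
myocardium it subtends is defined by the centerline sample points whose
root-to-point path passes through the anchor.

When a vessel or its side branches carry several significant lesions, only
the most proximal one is quantified: a lesion lying within another lesion's
distal subtree is dropped.  The surviving lesions then have pairwise
disjoint distal point sets, which is what makes per-lesion territory masses
additive.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable

import numpy as np

#: The fixed clinical branch vocabulary.
VESSEL_LABELS: tuple[str, ...] = (
    "LM", "pLAD", "mLAD", "dLAD", "D1", "D2",
    "Cx", "MO", "AL", "IM", "pRCA", "mRCA", "dRCA",
)

#: Default uniform arc-length spacing after resampling, mm — finer than the
#: 1 mm in-plane voxel grid so centerline discretization does not dominate
#: territory boundaries.
DEFAULT_SAMPLE_SPACING_MM = 0.5


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Branch:
    """One labeled centerline polyline, ordered root to tip.

    ``parent`` is the label of the parent branch (None for a root);
    ``attachment_index`` is the index of the parent polyline point where
    this branch takes off.
    """

    label: str
    points: np.ndarray
    parent: str | None = None
    attachment_index: int = 0

    def __post_init__(self) -> None:
        pts = np.asarray(self.points, dtype=float)
        if pts.ndim != 2 or pts.shape[1] != 3 or pts.shape[0] < 2:
            raise ValueError(
                f"branch {self.label!r} needs an (N>=2, 3) point array"
            )
        object.__setattr__(self, "points", pts)

    @property
    def arclengths(self) -> np.ndarray:
        """Cumulative arc length at each point, starting at 0."""
        seg = np.linalg.norm(np.diff(self.points, axis=0), axis=1)
        return np.concatenate([[0.0], np.cumsum(seg)])

    @property
    def length(self) -> float:
        return float(self.arclengths[-1])


@dataclass(frozen=True)
class CenterlineTree:
    """A forest of labeled coronary branches."""

    branches: tuple[Branch, ...]
    sample_spacing: float | None = None
    extra_labels: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        object.__setattr__(self, "branches", tuple(self.branches))
        object.__setattr__(self, "extra_labels", tuple(self.extra_labels))
        self._validate()

    # -- validation ---------------------------------------------------------

    def _validate(self) -> None:
        vocab = set(VESSEL_LABELS) | set(self.extra_labels)
        labels = [b.label for b in self.branches]
        if len(labels) != len(set(labels)):
            raise ValueError("branch labels must be unique per tree")
        unknown = [lab for lab in labels if lab not in vocab]
        if unknown:
            raise ValueError(
                f"unknown branch label(s) {unknown}; known: {sorted(vocab)}"
            )
        by_label = {b.label: b for b in self.branches}
        for b in self.branches:
            if b.parent is None:
                continue
            if b.parent not in by_label:
                raise ValueError(
                    f"branch {b.label!r} references missing parent {b.parent!r}"
                )
            parent = by_label[b.parent]
            if not 0 <= b.attachment_index < len(parent.points):
                raise ValueError(
                    f"branch {b.label!r} attachment index "
                    f"{b.attachment_index} out of range on {b.parent!r}"
                )
            tol = self.sample_spacing if self.sample_spacing else 1.0
            gap = float(
                np.linalg.norm(
                    b.points[0] - parent.points[b.attachment_index]
                )
            )
            if gap > tol + 1e-9:
                raise ValueError(
                    f"branch {b.label!r} first point is {gap:.3f} mm from its "
                    f"parent attachment point (tolerance {tol} mm)"
                )
        # forest check: walking parents must terminate without revisiting
        for b in self.branches:
            seen = {b.label}
            cur = b
            while cur.parent is not None:
                if cur.parent in seen:
                    raise ValueError(f"cycle in parent links at {cur.parent!r}")
                seen.add(cur.parent)
                cur = by_label[cur.parent]

    # -- topology helpers ---------------------------------------------------

    def branch(self, label: str) -> Branch:
        for b in self.branches:
            if b.label == label:
                return b
        raise KeyError(f"no branch labeled {label!r} in tree")

    def children_of(self, label: str) -> list[Branch]:
        return [b for b in self.branches if b.parent == label]

    def root_label(self, label: str) -> str:
        """Label of the root branch of the system containing ``label``."""
        b = self.branch(label)
        while b.parent is not None:
            b = self.branch(b.parent)
        return b.label

    def root_path_arclength(self, label: str, arc_position: float) -> float:
        """Arc length from the system root to a position on a branch."""
        total = float(arc_position)
        b = self.branch(label)
        while b.parent is not None:
            parent = self.branch(b.parent)
            total += float(parent.arclengths[b.attachment_index])
            b = parent
        return total

    # -- canonical sample-point enumeration ---------------------------------

    def sample_points(self) -> tuple[list[tuple[str, int]], np.ndarray]:
        """All sample points in canonical order.

        Canonical order: branches sorted lexicographically by label, points
        in root-to-tip index order.  Returns (ids, coords) with ids
        ``(branch_label, point_index)`` and coords an (P, 3) mm array.
        This ordering is the deterministic tie-break for nearest-point
        assignment.
        """
        ids: list[tuple[str, int]] = []
        coords: list[np.ndarray] = []
        for b in sorted(self.branches, key=lambda br: br.label):
            ids.extend((b.label, i) for i in range(len(b.points)))
            coords.append(b.points)
        return ids, np.vstack(coords)


@dataclass(frozen=True)
class Lesion:
    """A significant stenosis anchored on a centerline branch.

    ``arc_position`` is mm from the branch root to the lesion's most
    proximal point — the starting point for subtended-mass computation.
    ``stenosis_grade`` is the stenosis class in percent (50 or 70, for
    >=50% and >=70% luminal narrowing).
    """

    branch: str
    arc_position: float
    stenosis_grade: int = 50

    def __post_init__(self) -> None:
        if self.arc_position < 0:
            raise ValueError("lesion arc_position must be >= 0")
        if self.stenosis_grade not in (50, 70):
            raise ValueError("stenosis_grade must be 50 or 70")

    @staticmethod
    def at_fraction(
        branch: str, fraction: float, tree: CenterlineTree,
        stenosis_grade: int = 50,
    ) -> "Lesion":
        """Lesion anchored at a fraction (0-1) of a branch's length."""
        if not 0.0 <= fraction <= 1.0:
            raise ValueError("fractional lesion position must be in [0, 1]")
        length = tree.branch(branch).length
        return Lesion(branch, fraction * length, stenosis_grade)


# ---------------------------------------------------------------------------
# Operations
# ---------------------------------------------------------------------------

def resample_centerlines(
    tree: CenterlineTree, spacing: float = DEFAULT_SAMPLE_SPACING_MM
) -> CenterlineTree:
    """Resample every branch at uniform arc length <= ``spacing``.

    Endpoints are preserved exactly; topology is unchanged.  Attachment
    indices are remapped to the nearest new parent sample.
    """
    if spacing <= 0:
        raise ValueError("sample spacing must be > 0")
    new_points: dict[str, np.ndarray] = {}
    for b in tree.branches:
        if b.length <= 0:
            raise ValueError(f"branch {b.label!r} has zero length")
        n_seg = max(1, int(np.ceil(b.length / spacing - 1e-9)))
        target = np.linspace(0.0, b.length, n_seg + 1)
        arcs = b.arclengths
        pts = np.column_stack(
            [np.interp(target, arcs, b.points[:, d]) for d in range(3)]
        )
        pts[0], pts[-1] = b.points[0], b.points[-1]
        new_points[b.label] = pts
    new_branches = []
    for b in tree.branches:
        attach = 0
        if b.parent is not None:
            parent_pts = new_points[b.parent]
            old_anchor = tree.branch(b.parent).points[b.attachment_index]
            attach = int(
                np.argmin(np.linalg.norm(parent_pts - old_anchor, axis=1))
            )
        new_branches.append(
            Branch(b.label, new_points[b.label], b.parent, attach)
        )
    return CenterlineTree(
        tuple(new_branches), sample_spacing=spacing,
        extra_labels=tree.extra_labels,
    )


def distal_point_set(
    tree: CenterlineTree, lesion: Lesion
) -> set[tuple[str, int]]:
    """Sample points whose root-to-point path passes the lesion anchor.

    These are the points of the lesion's branch at arc length >=
    ``arc_position``, plus every point of branches attached at or beyond
    the anchor and of all their descendants.
    """
    branch = tree.branch(lesion.branch)  # raises KeyError if absent
    if lesion.arc_position > branch.length + 1e-9:
        raise ValueError(
            f"lesion arc_position {lesion.arc_position:.3f} mm exceeds "
            f"branch {lesion.branch!r} length {branch.length:.3f} mm"
        )
    out: set[tuple[str, int]] = set()
    arcs = branch.arclengths
    for i in range(len(branch.points)):
        if arcs[i] >= lesion.arc_position - 1e-9:
            out.add((branch.label, i))
    stack = [
        c.label
        for c in tree.children_of(branch.label)
        if arcs[c.attachment_index] >= lesion.arc_position - 1e-9
    ]
    while stack:
        lab = stack.pop()
        out.update((lab, i) for i in range(len(tree.branch(lab).points)))
        stack.extend(c.label for c in tree.children_of(lab))
    return out


def _is_distal_to(tree: CenterlineTree, a: Lesion, b: Lesion) -> bool:
    """True iff lesion ``b`` lies in lesion ``a``'s distal subtree."""
    # walk from b's branch toward the root, tracking the arc position at
    # which b's root-path leaves each branch
    label, arc = b.branch, b.arc_position
    while True:
        if label == a.branch:
            return arc >= a.arc_position - 1e-9
        br = tree.branch(label)
        if br.parent is None:
            return False
        parent = tree.branch(br.parent)
        arc = float(parent.arclengths[br.attachment_index])
        label = parent.label


def lesion_anchor_point(tree: CenterlineTree, lesion: Lesion) -> np.ndarray:
    """World-mm coordinates of a lesion's anchor on its branch."""
    branch = tree.branch(lesion.branch)
    arcs = branch.arclengths
    s = min(lesion.arc_position, branch.length)
    return np.array(
        [np.interp(s, arcs, branch.points[:, d]) for d in range(3)]
    )


def select_most_proximal_lesions(
    lesions: Iterable[Lesion], tree: CenterlineTree
) -> list[Lesion]:
    """Keep only the most proximal lesion along any vessel path.

    A lesion is dropped iff its anchor lies distal to another lesion's
    anchor (same branch further along, or in a side branch taking off at or
    beyond the other anchor).  Lesions in disjoint systems, or in sibling
    subtrees of one system, are all kept; the survivors' distal point sets
    are pairwise disjoint.
    """
    # deterministic order: proximal first, then label
    ordered = sorted(
        lesions,
        key=lambda l: (tree.root_path_arclength(l.branch, l.arc_position),
                       l.branch),
    )
    kept: list[Lesion] = []
    for cand in ordered:
        if any(_is_distal_to(tree, k, cand) for k in kept):
            continue
        kept.append(cand)
    return kept
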