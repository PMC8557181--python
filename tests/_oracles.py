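"""Independent brute-force oracles used by the test suite.

These stay deliberately naive (explicit python loops, no vectorization, no
spatial indexing) so they are an independent check on the library's
vectorized implementations.
"""

from __future__ import annotations

import numpy as np

import voromyo as vm


def nearest_bruteforce(centers: np.ndarray, points: np.ndarray) -> np.ndarray:
    """Exhaustive nearest-point search, strict-< first-minimum tie-break.

    Squared distance accumulated component-wise in the fixed order
    (dx*dx + dy*dy) + dz*dz, matching the assignment contract.
    """
    out = np.empty(len(centers), dtype=np.int64)
    for i, c in enumerate(centers):
        best_j, best_d = -1, np.inf
        for j, p in enumerate(points):
            dx, dy, dz = c[0] - p[0], c[1] - p[1], c[2] - p[2]
            d = (dx * dx + dy * dy) + dz * dz
            if d < best_d:
                best_j, best_d = j, d
        out[i] = best_j
    return out


def distal_points_bruteforce(
    tree: vm.CenterlineTree, lesion: vm.Lesion
) -> set[tuple[str, int]]:
    """Distal point set by explicit root-path enumeration per point."""
    out = set()
    for branch in tree.branches:
        arcs = branch.arclengths
        for i in range(len(branch.points)):
            # walk the root path of point (branch, i) as (label, exit-arc)
            path = []
            lab, arc = branch.label, float(arcs[i])
            while True:
                path.append((lab, arc))
                b = tree.branch(lab)
                if b.parent is None:
                    break
                parent = tree.branch(b.parent)
                arc = float(parent.arclengths[b.attachment_index])
                lab = parent.label
            for lab, arc in path:
                if lab == lesion.branch and arc >= lesion.arc_position - 1e-9:
                    out.add((branch.label, i))
                    break
    return out


def random_small_instance(rng: np.random.Generator):
    """A random tiny mask + resampled-style tree for oracle comparison."""
    dims = tuple(int(d) for d in rng.integers(3, 13, size=3))
    spacing = tuple(float(s) for s in rng.uniform(0.5, 3.0, size=3))
    origin = tuple(float(o) for o in rng.uniform(-10, 10, size=3))
    grid = vm.ImageGrid(dims, spacing, origin)
    mask_values = rng.random(dims) < 0.4
    if not mask_values.any():
        mask_values[tuple(rng.integers(0, d) for d in dims)] = True
    labels = list(rng.choice(vm.VESSEL_LABELS, size=rng.integers(1, 4),
                             replace=False))
    branches = []
    n_left = int(rng.integers(2, 51))
    for i, lab in enumerate(labels):
        n = max(2, n_left // (len(labels) - i))
        n_left -= n
        pts = rng.uniform(-15, 25, size=(n, 3))
        branches.append(vm.Branch(lab, pts))
    tree = vm.CenterlineTree(tuple(branches), sample_spacing=1.0)
    return vm.VoxelMask(grid, mask_values), tree
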