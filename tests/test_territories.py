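"""Nearest-centerline voxel assignment and subtended mass."""

import numpy as np
import pytest

import voromyo as vm

from _oracles import nearest_bruteforce, random_small_instance


def _two_point_tree(p0, p1, label="pLAD"):
    return vm.CenterlineTree(
        (vm.Branch(label, np.array([p0, p1], float)),), sample_spacing=1.0
    )


def test_single_branch_assigns_every_myocardial_voxel():
    grid = vm.ImageGrid((6, 6, 4), (1, 1, 1))
    rng = np.random.default_rng(0)
    mask = vm.VoxelMask(grid, rng.random((6, 6, 4)) < 0.5)
    tree = _two_point_tree([0, 0, 0], [0, 0, 100])
    labels = vm.assign_voxels_to_tree(mask, tree)
    assert np.array_equal(labels.myocardium, mask.astype_bool())
    # far point (index 1) never wins inside this small grid
    assert set(labels.nearest_index[mask.astype_bool()]) == {0}


def test_assignment_matches_bruteforce_on_random_instances():
    rng = np.random.default_rng(42)
    for _ in range(30):
        mask, tree = random_small_instance(rng)
        labels = vm.assign_voxels_to_tree(mask, tree)
        m = mask.astype_bool()
        idx = np.argwhere(m)
        centers = np.asarray(mask.grid.origin) + idx * np.asarray(mask.grid.spacing)
        _, coords = tree.sample_points()
        expected = nearest_bruteforce(centers, coords)
        np.testing.assert_array_equal(labels.nearest_index[m], expected)


def test_exact_ties_break_to_lowest_canonical_index():
    # two mirror-image branches; mid-plane voxel centers are equidistant
    grid = vm.ImageGrid((5, 5, 1), (1, 1, 1), (-2, -2, 0))
    mask = vm.VoxelMask(grid, np.ones((5, 5, 1), bool))
    tree = vm.CenterlineTree(
        (
            vm.Branch("pRCA", np.array([[3.0, -2, 0], [3.0, 2, 0]])),
            vm.Branch("pLAD", np.array([[-3.0, -2, 0], [-3.0, 2, 0]])),
        ),
        sample_spacing=4.0,
    )
    labels = vm.assign_voxels_to_tree(mask, tree)
    ids, coords = labels.point_ids, labels.point_coords
    # canonical order sorts pLAD before pRCA
    assert ids[0][0] == "pLAD"
    mid_column = labels.nearest_index[2, :, 0]  # x = 0, equidistant
    assert all(ids[i][0] == "pLAD" for i in mid_column)
    idx = np.argwhere(mask.values)
    centers = np.asarray(grid.origin) + idx * np.asarray(grid.spacing)
    np.testing.assert_array_equal(
        labels.nearest_index[mask.values], nearest_bruteforce(centers, coords)
    )


def test_mirror_symmetric_branches_split_shell_equally():
    spec = vm.PhantomSpec()
    lv = spec.lv
    # lattice chosen with no voxel centers on the mirror plane y = 0, so
    # no voxel is exactly equidistant from the two branches
    base = vm.make_grid(lv)
    ny = base.dims[1] + 1  # even count: centers at +-0.5, +-1.5, ...
    grid = vm.ImageGrid(
        (base.dims[0], ny, base.dims[2]), base.spacing,
        (base.origin[0], -(ny / 2 - 0.5) * base.spacing[1], base.origin[2]),
    )
    contours, mask = vm.generate_lv_shell(spec, grid)
    L = lv.long_axis_mm
    r = lv.basal_epi_radius_mm + 1
    pts = np.array([[0, r, 0.3 * L], [0, r, 0.9 * L]])
    tree = vm.resample_centerlines(
        vm.CenterlineTree(
            (vm.Branch("pLAD", pts), vm.Branch("pRCA", pts * [1, -1, 1])),
        ),
        0.5,
    )
    labels = vm.assign_voxels_to_tree(mask, tree)
    labels = vm.lesion_territories(
        labels, tree, [vm.Lesion("pLAD", 0.0), vm.Lesion("pRCA", 0.0)]
    )
    masses = vm.subtended_mass_per_lesion(labels)
    assert abs(masses["pLAD"] - masses["pRCA"]) <= vm.voxel_mass_g(mask.grid)


def test_root_lesions_partition_entire_myocardium(default_case):
    tree, myo = default_case.tree, default_case.myocardium
    roots = [b.label for b in tree.branches if b.parent is None]
    lesions = [vm.Lesion(r, 0.0) for r in roots]
    labels = vm.lesion_territories(
        vm.assign_voxels_to_tree(myo, tree), tree, lesions
    )
    masses = vm.subtended_mass_per_lesion(labels)
    total = vm.total_subtended_mass(masses)
    lv = vm.compute_mass(myo)
    assert abs(total - lv) < 1e-6
    assert (labels.lesion_label[labels.myocardium] > 0).all()


def test_remote_branch_gets_empty_territory():
    grid = vm.ImageGrid((8, 8, 2), (1, 1, 1))
    mask = vm.VoxelMask(grid, np.ones((8, 8, 2), bool))
    tree = vm.CenterlineTree(
        (
            vm.Branch("pLAD", np.array([[3.0, 3, 0], [3.0, 3, 2]])),
            vm.Branch("pRCA", np.array([[200.0, 0, 0], [200.0, 0, 2]])),
        ),
        sample_spacing=2.0,
    )
    labels = vm.lesion_territories(
        vm.assign_voxels_to_tree(mask, tree), tree,
        [vm.Lesion("pLAD", 0.0), vm.Lesion("pRCA", 0.0)],
    )
    masses = vm.subtended_mass_per_lesion(labels)
    assert masses["pRCA"] == 0.0
    assert masses["pLAD"] == pytest.approx(vm.compute_mass(mask))


def test_subtended_mass_never_exceeds_lv_and_sum_bounded(default_case):
    rep_masses = vm.subtended_mass_per_lesion(default_case.labels)
    lv = vm.compute_mass(default_case.myocardium)
    assert sum(rep_masses.values()) <= lv + 1e-9


def test_moving_lesion_distally_never_gains_mass(default_case):
    tree, myo = default_case.tree, default_case.myocardium
    base = vm.assign_voxels_to_tree(myo, tree)
    prev = np.inf
    for frac in (0.0, 0.3, 0.6, 0.9):
        lesion = vm.Lesion.at_fraction("pLAD", frac, tree)
        labels = vm.lesion_territories(base, tree, [lesion])
        mass = vm.subtended_mass_per_lesion(labels)["pLAD"]
        assert mass <= prev + 1e-12
        prev = mass


def test_assignment_invariant_under_joint_translation():
    rng = np.random.default_rng(5)
    mask, tree = random_small_instance(rng)
    shift = np.array([3.7, -1.2, 8.9])
    labels = vm.assign_voxels_to_tree(mask, tree)
    grid2 = vm.ImageGrid(
        mask.grid.dims, mask.grid.spacing,
        tuple(np.asarray(mask.grid.origin) + shift),
    )
    tree2 = vm.CenterlineTree(
        tuple(
            vm.Branch(b.label, b.points + shift, b.parent, b.attachment_index)
            for b in tree.branches
        ),
        sample_spacing=tree.sample_spacing,
    )
    labels2 = vm.assign_voxels_to_tree(vm.VoxelMask(grid2, mask.values), tree2)
    np.testing.assert_array_equal(labels.nearest_index, labels2.nearest_index)


def test_nested_lesions_rejected(lad_tree):
    tree = vm.resample_centerlines(lad_tree, 1.0)
    grid = vm.ImageGrid((5, 5, 5), (2, 2, 2))
    mask = vm.VoxelMask(grid, np.ones((5, 5, 5), bool))
    base = vm.assign_voxels_to_tree(mask, tree)
    with pytest.raises(ValueError, match="nested"):
        vm.lesion_territories(
            base, tree, [vm.Lesion("pLAD", 0.0), vm.Lesion("mLAD", 5.0)]
        )


def test_total_subtended_mass_is_plain_sum():
    assert vm.total_subtended_mass({"mLAD": 22, "dRCA": 29}) == 51
    assert vm.total_subtended_mass({"pLAD": 62, "pRCA": 24}) == 86
    assert vm.total_subtended_mass({}) == 0


def test_assignment_precondition_errors():
    grid = vm.ImageGrid((4, 4, 4), (1, 1, 1))
    mask = vm.VoxelMask(grid, np.ones((4, 4, 4), bool))
    unsampled = vm.CenterlineTree(
        (vm.Branch("Cx", np.array([[0, 0, 0], [0, 0, 5.0]])),)
    )
    with pytest.raises(ValueError, match="resampled"):
        vm.assign_voxels_to_tree(mask, unsampled)
    tree = vm.resample_centerlines(unsampled, 1.0)
    with pytest.raises(ValueError, match="empty"):
        vm.assign_voxels_to_tree(
            vm.VoxelMask(grid, np.zeros((4, 4, 4), bool)), tree
        )
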