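"""Centerline tree topology, resampling, lesions and distal subtrees."""

import math

import numpy as np
import pytest

import voromyo as vm

from _oracles import distal_points_bruteforce


# -- resampling --------------------------------------------------------------

def test_resample_straight_segment_uniform_subdivision():
    tree = vm.CenterlineTree(
        (vm.Branch("pLAD", np.array([[0, 0, 0], [0, 0, 10.0]])),)
    )
    r = vm.resample_centerlines(tree, 1.0).branch("pLAD")
    assert len(r.points) == 11
    np.testing.assert_allclose(np.diff(r.points[:, 2]), 1.0, atol=1e-12)


def test_resample_idempotent_on_uniform_polyline():
    pts = np.column_stack([np.zeros(21), np.zeros(21), np.linspace(0, 10, 21)])
    tree = vm.CenterlineTree((vm.Branch("Cx", pts),))
    r = vm.resample_centerlines(tree, 0.5).branch("Cx")
    np.testing.assert_allclose(r.points, pts, atol=1e-9)


def test_resample_preserves_arc_length_of_quarter_circle():
    t = np.linspace(0, np.pi / 2, 400)
    pts = np.column_stack([20 * np.cos(t), 20 * np.sin(t), np.zeros_like(t)])
    tree = vm.CenterlineTree((vm.Branch("Cx", pts),))
    spacing = 1.0
    r = vm.resample_centerlines(tree, spacing).branch("Cx")
    analytic = 2 * math.pi * 20 / 4
    assert abs(r.length - analytic) < spacing / 2
    np.testing.assert_allclose(r.points[0], pts[0])
    np.testing.assert_allclose(r.points[-1], pts[-1])


def test_resample_rejects_zero_length_branch():
    tree = vm.CenterlineTree(
        (vm.Branch("D1", np.array([[1.0, 1, 1], [1, 1, 1]])),)
    )
    with pytest.raises(ValueError, match="zero length"):
        vm.resample_centerlines(tree, 0.5)


# -- distal point sets -------------------------------------------------------

def test_distal_point_set_matches_bruteforce_enumeration(lad_tree):
    cases = [
        vm.Lesion("pLAD", 0.0),    # whole system
        vm.Lesion("pLAD", 5.0),    # proximal to D1 takeoff at arc 10
        vm.Lesion("pLAD", 15.0),   # distal to D1 takeoff
        vm.Lesion("pLAD", 20.0),   # at tip, mLAD attached there
        vm.Lesion("mLAD", 10.0),
        vm.Lesion("D1", 0.0),
    ]
    for lesion in cases:
        assert vm.distal_point_set(lad_tree, lesion) == distal_points_bruteforce(
            lad_tree, lesion
        )


def test_distal_set_proximal_includes_side_branch_distal_excludes(lad_tree):
    proximal = vm.distal_point_set(lad_tree, vm.Lesion("pLAD", 5.0))
    distal = vm.distal_point_set(lad_tree, vm.Lesion("pLAD", 15.0))
    assert any(b == "D1" for b, _ in proximal)
    assert any(b == "mLAD" for b, _ in proximal)
    assert not any(b == "D1" for b, _ in distal)
    assert any(b == "mLAD" for b, _ in distal)


def test_lesion_at_branch_tip_without_children_is_single_point(lad_tree):
    pts = vm.distal_point_set(lad_tree, vm.Lesion("D1", lad_tree.branch("D1").length))
    assert pts == {("D1", 2)}


def test_lesion_at_root_covers_every_system_point(lad_tree):
    pts = vm.distal_point_set(lad_tree, vm.Lesion("pLAD", 0.0))
    ids, _ = lad_tree.sample_points()
    assert pts == set(ids)


def test_distal_set_antitone_in_arc_position(lad_tree):
    prev = None
    for arc in np.linspace(0, lad_tree.branch("pLAD").length, 9):
        cur = vm.distal_point_set(lad_tree, vm.Lesion("pLAD", float(arc)))
        if prev is not None:
            assert cur <= prev
        prev = cur


def test_lesion_off_tree_or_past_tip_rejected(lad_tree):
    with pytest.raises(KeyError):
        vm.distal_point_set(lad_tree, vm.Lesion("dRCA", 1.0))
    with pytest.raises(ValueError, match="exceeds"):
        vm.distal_point_set(lad_tree, vm.Lesion("pLAD", 99.0))


# -- most-proximal filtering -------------------------------------------------

def test_filter_keeps_only_most_proximal_on_one_vessel_path(lad_tree):
    kept = vm.select_most_proximal_lesions(
        [vm.Lesion("mLAD", 5.0), vm.Lesion("pLAD", 2.0)], lad_tree
    )
    assert [l.branch for l in kept] == ["pLAD"]


def test_filter_keeps_sibling_subtree_lesions(lad_tree):
    # a mid-LAD and a diagonal lesion lie on different vessel paths
    kept = vm.select_most_proximal_lesions(
        [vm.Lesion("mLAD", 5.0), vm.Lesion("D1", 3.0)], lad_tree
    )
    assert sorted(l.branch for l in kept) == ["D1", "mLAD"]
    # but a pLAD lesion proximal to the D1 takeoff shadows both
    kept = vm.select_most_proximal_lesions(
        [vm.Lesion("mLAD", 5.0), vm.Lesion("D1", 3.0), vm.Lesion("pLAD", 2.0)],
        lad_tree,
    )
    assert [l.branch for l in kept] == ["pLAD"]


def test_filter_keeps_lesions_in_disjoint_systems():
    tree = vm.generate_tree(vm.PhantomSpec())
    kept = vm.select_most_proximal_lesions(
        [vm.Lesion("pLAD", 5.0), vm.Lesion("dRCA", 5.0)], tree
    )
    assert sorted(l.branch for l in kept) == ["dRCA", "pLAD"]


def test_single_lesion_passes_unchanged(lad_tree):
    lesion = vm.Lesion("mLAD", 7.5, 70)
    assert vm.select_most_proximal_lesions([lesion], lad_tree) == [lesion]


def test_filtered_distal_sets_pairwise_disjoint():
    tree = vm.resample_centerlines(vm.generate_tree(vm.PhantomSpec()), 2.0)
    rng = np.random.default_rng(11)
    labels = [b.label for b in tree.branches]
    for _ in range(25):
        lesions = [
            vm.Lesion.at_fraction(
                str(rng.choice(labels)), float(rng.random()), tree
            )
            for _ in range(int(rng.integers(1, 6)))
        ]
        kept = vm.select_most_proximal_lesions(lesions, tree)
        sets = [vm.distal_point_set(tree, l) for l in kept]
        for i in range(len(sets)):
            for j in range(i + 1, len(sets)):
                assert not (sets[i] & sets[j])


# -- construction and validation --------------------------------------------

def test_fractional_position_converts_to_mm(lad_tree):
    lesion = vm.Lesion.at_fraction("pLAD", 0.5, lad_tree)
    assert lesion.arc_position == pytest.approx(10.0)
    with pytest.raises(ValueError, match=r"\[0, 1\]"):
        vm.Lesion.at_fraction("pLAD", 1.5, lad_tree)


def test_lesion_grade_restricted():
    with pytest.raises(ValueError, match="50 or 70"):
        vm.Lesion("pLAD", 1.0, 60)


def test_tree_validation_rejects_bad_topology():
    a = np.array([[0, 0, 0], [0, 0, 10.0]])
    with pytest.raises(ValueError, match="unknown branch label"):
        vm.CenterlineTree((vm.Branch("XX", a),))
    with pytest.raises(ValueError, match="unique"):
        vm.CenterlineTree((vm.Branch("Cx", a), vm.Branch("Cx", a + 1)))
    with pytest.raises(ValueError, match="missing parent"):
        vm.CenterlineTree((vm.Branch("Cx", a, parent="LM"),))
    far = np.array([[50, 50, 50], [50, 50, 60.0]])
    with pytest.raises(ValueError, match="attachment point"):
        vm.CenterlineTree(
            (vm.Branch("Cx", a), vm.Branch("MO", far, parent="Cx",
                                           attachment_index=1))
        )


def test_extra_labels_extend_vocabulary():
    a = np.array([[0, 0, 0], [0, 0, 10.0]])
    tree = vm.CenterlineTree((vm.Branch("PDA", a),), extra_labels=("PDA",))
    assert tree.branch("PDA").length == pytest.approx(10.0)
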