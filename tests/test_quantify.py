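"""Defect attribution, percent distributed, correlation, case reports."""

import numpy as np
import pytest

import voromyo as vm


# -- defect mass -------------------------------------------------------------

def _halfspace_setup():
    grid = vm.ImageGrid((20, 20, 4), (1, 1, 4))
    myo = np.zeros((20, 20, 4), bool)
    myo[:10] = True  # myocardium occupies x-index < 10
    blob = np.zeros((20, 20, 4), bool)
    blob[6:14, 5:9, 1:3] = True  # straddles the border at x-index 10
    return grid, vm.VoxelMask(grid, myo), vm.VoxelMask(grid, blob)


def test_defect_clipped_to_myocardium_voxel_by_voxel():
    grid, myo, blob = _halfspace_setup()
    inside = np.count_nonzero(blob.values & myo.values)
    with pytest.warns(UserWarning, match="outside the myocardium"):
        mass = vm.defect_mass(blob, myo)
    assert mass == pytest.approx(inside * vm.voxel_mass_g(grid))


def test_defect_fully_inside_needs_no_warning_and_outside_is_zero():
    grid, myo, _ = _halfspace_setup()
    inside = np.zeros((20, 20, 4), bool)
    inside[2:5, 2:5, 1:3] = True
    m = vm.defect_mass(vm.VoxelMask(grid, inside), myo)
    assert m == pytest.approx(vm.compute_mass(vm.VoxelMask(grid, inside)))
    outside = np.zeros((20, 20, 4), bool)
    outside[15:18, 2:5, 1:3] = True
    with pytest.warns(UserWarning):
        assert vm.defect_mass(vm.VoxelMask(grid, outside), myo) == 0.0
    with pytest.raises(ValueError, match="empty"):
        vm.defect_mass(
            vm.VoxelMask(grid, outside),
            vm.VoxelMask(grid, np.zeros((20, 20, 4), bool)),
        )


def test_defect_split_across_territories_recovers_planted_fractions(default_case):
    case = default_case
    gt = case.ground_truth
    per = vm.defect_mass_per_lesion(case.defect, case.labels)
    vmass = gt["voxel_mass_g"]
    assert per["pLAD"] == pytest.approx(gt["defect_voxel_counts"]["pLAD"] * vmass)
    # the straddled share fell into no-lesion myocardium, not another lesion
    assert per["dRCA"] == 0.0
    assert sum(per.values()) <= gt["defect_mass_g"] + 1e-9


def test_defect_in_background_territory_attributed_to_none(default_case):
    case = default_case
    bg = case.labels.myocardium & (case.labels.lesion_label == 0)
    idx = np.argwhere(bg)[:40]
    values = np.zeros(case.grid.dims, bool)
    values[tuple(idx.T)] = True
    per = vm.defect_mass_per_lesion(vm.VoxelMask(case.grid, values), case.labels)
    assert set(per.values()) == {0.0}


def test_grid_mismatch_rejected(default_case):
    other = vm.ImageGrid((4, 4, 4), (1, 1, 1))
    with pytest.raises(ValueError, match="grid"):
        vm.defect_mass_per_lesion(
            vm.VoxelMask(other, np.zeros((4, 4, 4), bool)), default_case.labels
        )


# -- percent distributed -----------------------------------------------------

@pytest.mark.parametrize(
    "per_lesion,total,expected",
    [
        ({"pLAD": 10, "Cx": 0}, 11, 91),
        ({"pLAD": 7}, 8, 88),
        ({"mLAD": 10, "dRCA": 1}, 11, 100),
        ({"mLAD": 5}, 9, 56),
        ({"pLAD": 1}, 5, 20),
        ({"dLAD": 1, "D2": 1}, 4, 50),
    ],
)
def test_percent_distributed_rounds_half_away_from_zero(per_lesion, total, expected):
    assert vm.percent_distributed(per_lesion, total) == expected


def test_percent_undefined_for_zero_defect():
    assert vm.percent_distributed({"pLAD": 0.0}, 0.0) is None


def test_percent_rejects_attribution_exceeding_total():
    with pytest.raises(ValueError, match="exceeds"):
        vm.percent_distributed({"pLAD": 12.0}, 11.0)


# -- Pearson correlation -----------------------------------------------------

def test_pearson_limits_and_hand_computed_value():
    x = [1.0, 2.0, 4.0, 5.0, 8.0]
    assert vm.pearson_r(x, x) == pytest.approx(1.0)
    assert vm.pearson_r(x, [-v for v in x]) == pytest.approx(-1.0)
    y = [2.0, 1.0, 5.0, 7.0, 9.0]
    n = len(x)
    sx, sy = sum(x), sum(y)
    sxx = sum(v * v for v in x)
    syy = sum(v * v for v in y)
    sxy = sum(a * b for a, b in zip(x, y))
    expected = (n * sxy - sx * sy) / (
        ((n * sxx - sx * sx) ** 0.5) * ((n * syy - sy * sy) ** 0.5)
    )
    assert vm.pearson_r(x, y) == pytest.approx(expected, abs=1e-12)


def test_pearson_input_validation():
    with pytest.raises(ValueError, match="n >= 3"):
        vm.pearson_r([1, 2], [3, 4])
    with pytest.raises(ValueError, match="zero-variance"):
        vm.pearson_r([1, 1, 1], [1, 2, 3])


# -- published-table regression ---------------------------------------------

def test_reference_table_percentages_all_reproduce():
    stats = vm.reference_cohort_stats()
    cases = stats["cases"]
    assert (cases["percent_distributed"] == cases["percent_printed"]).all()


def test_reference_table_case_totals():
    table = vm.load_reference_table()
    g = table[table["case"] == 1]
    total = vm.total_subtended_mass(
        dict(zip(g["vessel"], g["subtended_mass_g"].astype(float)))
    )
    assert total == 51
    g = table[table["case"] == 18]
    assert g["subtended_mass_g"].sum() == 86


# -- case reports ------------------------------------------------------------

def test_case_report_matches_phantom_ground_truth(default_case):
    case = default_case
    rep = vm.build_case_report(
        "phantom", case.contours, case.grid, case.tree, case.lesions,
        case.defect, pre_aligned=True,
    )
    gt = case.ground_truth
    vmass = gt["voxel_mass_g"]
    assert rep.lv_mass == pytest.approx(gt["lv_mass_g"])
    for k, v in gt["subtended_mass_per_lesion_g"].items():
        assert rep.subtended_mass_per_lesion[k] == pytest.approx(v, rel=0.05)
    assert rep.defect_mass == pytest.approx(gt["defect_mass_g"], abs=vmass)
    for k, v in gt["defect_mass_per_lesion_g"].items():
        assert rep.defect_mass_per_lesion[k] == pytest.approx(v, abs=vmass)
    assert rep.percent_distributed == gt["percent_distributed"]
    assert rep.total_subtended_mass == pytest.approx(
        sum(rep.subtended_mass_per_lesion.values())
    )


def test_zero_defect_report_has_undefined_percent():
    spec = vm.PhantomSpec(lesions=(("pLAD", 0.1, 50),), defects=())
    case = vm.generate_case(spec)
    rep = vm.build_case_report(
        "nodefect", case.contours, case.grid, case.tree, case.lesions, None
    )
    assert rep.defect_mass == 0.0
    assert rep.percent_distributed is None
    assert set(rep.defect_mass_per_lesion.values()) == {0.0}


def test_root_lesion_report_total_equals_lv_mass():
    spec = vm.PhantomSpec(
        lesions=(("LM", 0.0, 50), ("pRCA", 0.0, 50)), defects=()
    )
    case = vm.generate_case(spec)
    rep = vm.build_case_report(
        "roots", case.contours, case.grid, case.tree, case.lesions, None
    )
    assert rep.total_subtended_mass == pytest.approx(rep.lv_mass, abs=1e-6)


def test_report_invariant_violations_rejected():
    with pytest.raises(ValueError, match="lesion sum"):
        vm.QuantReport("x", [("pLAD", 50)], 100.0, {"pLAD": 40.0}, 50.0,
                       5.0, {"pLAD": 5.0}, 0.0, 100)
    with pytest.raises(ValueError, match="exceed"):
        vm.QuantReport("x", [("pLAD", 50)], 100.0, {"pLAD": 40.0}, 40.0,
                       5.0, {"pLAD": 6.0}, 0.0, 100)
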