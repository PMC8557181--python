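import numpy as np
import pytest

import voromyo as vm
from voromyo.geometry import circle_polygon


@pytest.fixture(scope="session")
def lad_tree() -> vm.CenterlineTree:
    """Hand-built 3-branch LAD system: pLAD -> mLAD, D1 off mid-pLAD."""
    pLAD = vm.Branch("pLAD", np.array([[0, 0, 0], [0, 0, 10], [0, 0, 20]], float))
    mLAD = vm.Branch(
        "mLAD", np.array([[0, 0, 20], [0, 0, 30], [0, 0, 40]], float), "pLAD", 2
    )
    d1 = vm.Branch(
        "D1", np.array([[0, 0, 10], [0, 10, 15], [0, 20, 20]], float), "pLAD", 1
    )
    return vm.CenterlineTree((pLAD, mLAD, d1))


@pytest.fixture(scope="session")
def default_case() -> vm.PhantomCase:
    """Two-lesion phantom with a defect straddling into background."""
    spec = vm.PhantomSpec(
        lesions=(("pLAD", 0.1, 50), ("dRCA", 0.2, 50)),
        defects=(vm.DefectSpec("pLAD", 7.0, 0.3),),
        seed=3,
    )
    return vm.generate_case(spec)


def annulus_stack(
    r_out: float = 30.0,
    r_in: float | None = 20.0,
    zs: tuple[float, ...] = (2.0,),
    n_vertices: int = 360,
    slice_spacing: float = 4.0,
) -> vm.ContourStack:
    slices = tuple(
        vm.ContourSlice(
            z,
            circle_polygon(0, 0, r_out, n_vertices),
            None if r_in is None else circle_polygon(0, 0, r_in, n_vertices),
        )
        for z in zs
    )
    return vm.ContourStack(slices, slice_spacing)


def annulus_grid(
    half_extent: float = 32.0,
    dxy: float = 1.0,
    n_slices: int = 1,
    dz: float = 4.0,
    z0: float = 2.0,
) -> vm.ImageGrid:
    m = int(np.ceil(half_extent / dxy))
    return vm.ImageGrid(
        (2 * m + 1, 2 * m + 1, n_slices), (dxy, dxy, dz), (-m * dxy, -m * dxy, z0)
    )
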