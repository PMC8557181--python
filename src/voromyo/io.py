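"""Readers and writers for the standard interchange formats.

Masks travel as NIfTI (.nii/.nii.gz, via nibabel) or MetaImage (.mha/.mhd,
via SimpleITK), both restricted to axis-aligned geometry (short-axis
reformatting happens upstream).  Centerline trees travel as legacy ASCII
VTK polydata (polylines with branch/parent/attachment cell arrays) or as a
JSON dialect; contour stacks and rigid transforms as JSON; lesions as JSON
or CSV; quantification results as JSON/CSV with the clinical table's
column names.  Segmented structures export as 3D objects in VTK format
(territory and defect surfaces, tree polylines, lesion anchor markers).

All writers are deterministic: fixed float formatting, fixed ordering.
"""

from __future__ import annotations

import csv
import json
import warnings
from pathlib import Path

import nibabel as nib
import numpy as np
import SimpleITK as sitk
from skimage import measure as _sk_measure

from .geometry import ContourSlice, ContourStack, ImageGrid, VoxelMask
from .quantify import QuantReport
from .registration import RigidTransform
from .territories import TerritoryLabelMap
from .tree import Branch, CenterlineTree, Lesion, VESSEL_LABELS, lesion_anchor_point

_F = "%.17g"  # lossless float formatting for text formats


def _fmt(x: float) -> str:
    return _F % float(x)


# ---------------------------------------------------------------------------
# Voxel masks: NIfTI and MetaImage
# ---------------------------------------------------------------------------

def write_mask(mask: VoxelMask, path: str | Path) -> None:
    path = Path(path)
    values = mask.values.astype(np.uint8 if mask.values.dtype == bool else np.int16)
    if path.name.endswith((".nii", ".nii.gz")):
        affine = np.diag(list(mask.grid.spacing) + [1.0])
        affine[:3, 3] = mask.grid.origin
        nib.save(nib.Nifti1Image(values, affine), str(path))
    elif path.suffix in (".mha", ".mhd"):
        img = sitk.GetImageFromArray(np.ascontiguousarray(values.T))
        img.SetSpacing(tuple(float(s) for s in mask.grid.spacing))
        img.SetOrigin(tuple(float(o) for o in mask.grid.origin))
        sitk.WriteImage(img, str(path))
    else:
        raise ValueError(f"unsupported mask format: {path.name}")


def read_mask(path: str | Path) -> VoxelMask:
    path = Path(path)
    if path.name.endswith((".nii", ".nii.gz")):
        img = nib.load(str(path))
        affine = img.affine
        rot = affine[:3, :3]
        if not np.allclose(rot - np.diag(np.diag(rot)), 0, atol=1e-6) or np.any(
            np.diag(rot) <= 0
        ):
            raise ValueError(
                f"{path.name}: non-axis-aligned orientation matrix; "
                "reformat to short-axis before loading"
            )
        grid = ImageGrid(
            img.shape[:3], tuple(np.diag(rot)), tuple(affine[:3, 3])
        )
        values = np.asarray(img.dataobj).astype(np.int16)
    elif path.suffix in (".mha", ".mhd"):
        img = sitk.ReadImage(str(path))
        if not np.allclose(np.asarray(img.GetDirection()).reshape(3, 3), np.eye(3),
                           atol=1e-6):
            raise ValueError(
                f"{path.name}: non-axis-aligned orientation matrix; "
                "reformat to short-axis before loading"
            )
        values = sitk.GetArrayFromImage(img).T.astype(np.int16)
        grid = ImageGrid(values.shape, img.GetSpacing(), img.GetOrigin())
    else:
        raise ValueError(f"unsupported mask format: {path.name}")
    if set(np.unique(values)) <= {0, 1}:
        values = values.astype(bool)
    return VoxelMask(grid, values)


# ---------------------------------------------------------------------------
# Contour stacks: JSON dialect
# ---------------------------------------------------------------------------

def write_contours(contours: ContourStack, path: str | Path) -> None:
    """JSON dialect: slice world z and epi/endo point lists in mm."""
    doc = {
        "format": "voromyo-contours-v1",
        "slice_spacing_mm": contours.slice_spacing,
        "slices": [
            {
                "z_mm": s.z_mm,
                "epicardial_mm": np.asarray(s.epi).tolist(),
                "endocardial_mm": (
                    None if s.endo is None else np.asarray(s.endo).tolist()
                ),
            }
            for s in contours.slices
        ],
    }
    Path(path).write_text(json.dumps(doc, indent=1))


def read_contours(path: str | Path) -> ContourStack:
    doc = json.loads(Path(path).read_text())
    if doc.get("format") != "voromyo-contours-v1":
        raise ValueError(f"{path}: not a voromyo contour file")
    slices = tuple(
        ContourSlice(
            float(s["z_mm"]),
            np.asarray(s["epicardial_mm"], dtype=float),
            None
            if s.get("endocardial_mm") is None
            else np.asarray(s["endocardial_mm"], dtype=float),
        )
        for s in doc["slices"]
    )
    return ContourStack(slices, float(doc["slice_spacing_mm"]))


# ---------------------------------------------------------------------------
# Centerline trees: JSON dialect and legacy ASCII VTK polydata
# ---------------------------------------------------------------------------

def write_centerlines(tree: CenterlineTree, path: str | Path) -> None:
    path = Path(path)
    if path.suffix == ".json":
        doc = {
            "format": "voromyo-centerlines-v1",
            "sample_spacing_mm": tree.sample_spacing,
            "extra_labels": list(tree.extra_labels),
            "branches": [
                {
                    "label": b.label,
                    "parent": b.parent,
                    "attachment_index": b.attachment_index,
                    "points_mm": b.points.tolist(),
                }
                for b in tree.branches
            ],
        }
        path.write_text(json.dumps(doc, indent=1))
    elif path.suffix == ".vtk":
        _write_tree_vtk(tree, path)
    else:
        raise ValueError(f"unsupported centerline format: {path.name}")


def read_centerlines(path: str | Path) -> CenterlineTree:
    path = Path(path)
    if path.suffix == ".json":
        doc = json.loads(path.read_text())
        if doc.get("format") != "voromyo-centerlines-v1":
            raise ValueError(f"{path}: not a voromyo centerline file")
        branches = tuple(
            Branch(
                b["label"],
                np.asarray(b["points_mm"], dtype=float),
                b.get("parent"),
                int(b.get("attachment_index", 0)),
            )
            for b in doc["branches"]
        )
        return CenterlineTree(
            branches,
            sample_spacing=doc.get("sample_spacing_mm"),
            extra_labels=tuple(doc.get("extra_labels", ())),
        )
    if path.suffix == ".vtk":
        return _read_tree_vtk(path)
    raise ValueError(f"unsupported centerline format: {path.name}")


def _vtk_header(title: str) -> list[str]:
    return ["# vtk DataFile Version 3.0", title, "ASCII", "DATASET POLYDATA"]


def _write_tree_vtk(tree: CenterlineTree, path: Path) -> None:
    """Polylines with branch-label, parent and attachment cell arrays.

    Branch labels are encoded as indices into the fixed vessel vocabulary;
    trees with custom extra labels need the JSON dialect.
    """
    for b in tree.branches:
        if b.label not in VESSEL_LABELS:
            raise ValueError(
                f"VTK export supports only the fixed vocabulary; "
                f"{b.label!r} requires the JSON dialect"
            )
    spacing = "none" if tree.sample_spacing is None else _fmt(tree.sample_spacing)
    lines = _vtk_header(f"voromyo centerline tree; sample_spacing_mm={spacing}")
    n_pts = sum(len(b.points) for b in tree.branches)
    lines.append(f"POINTS {n_pts} double")
    offsets, off = [], 0
    for b in tree.branches:
        offsets.append(off)
        off += len(b.points)
        for p in b.points:
            lines.append(" ".join(_fmt(c) for c in p))
    n_cells = len(tree.branches)
    size = sum(len(b.points) + 1 for b in tree.branches)
    lines.append(f"LINES {n_cells} {size}")
    for b, o in zip(tree.branches, offsets):
        lines.append(
            " ".join(str(v) for v in [len(b.points)] + list(range(o, o + len(b.points))))
        )
    label_index = {lab: i for i, lab in enumerate(VESSEL_LABELS)}
    cell_index = {b.label: i for i, b in enumerate(tree.branches)}
    lines.append(f"CELL_DATA {n_cells}")
    lines.append("SCALARS branch_label int 1")
    lines.append("LOOKUP_TABLE default")
    lines.append(" ".join(str(label_index[b.label]) for b in tree.branches))
    lines.append("SCALARS parent int 1")
    lines.append("LOOKUP_TABLE default")
    lines.append(
        " ".join(
            str(-1 if b.parent is None else cell_index[b.parent])
            for b in tree.branches
        )
    )
    lines.append("SCALARS attachment int 1")
    lines.append("LOOKUP_TABLE default")
    lines.append(" ".join(str(b.attachment_index) for b in tree.branches))
    path.write_text("\n".join(lines) + "\n")


def _read_tree_vtk(path: Path) -> CenterlineTree:
    tokens_by_section: dict[str, list[str]] = {}
    text = path.read_text().splitlines()
    if len(text) < 4 or "POLYDATA" not in text[3]:
        raise ValueError(f"{path}: not a legacy ASCII VTK polydata file")
    title = text[1]
    spacing: float | None = None
    if "sample_spacing_mm=" in title:
        val = title.split("sample_spacing_mm=")[1].split(";")[0].strip()
        spacing = None if val == "none" else float(val)
    i = 4
    points: np.ndarray | None = None
    cells: list[list[int]] = []
    scalars: dict[str, list[int]] = {}
    while i < len(text):
        line = text[i].strip()
        if line.startswith("POINTS"):
            n = int(line.split()[1])
            vals: list[float] = []
            i += 1
            while len(vals) < 3 * n:
                vals.extend(float(t) for t in text[i].split())
                i += 1
            points = np.asarray(vals).reshape(n, 3)
            continue
        if line.startswith("LINES"):
            n_cells = int(line.split()[1])
            vals = []
            i += 1
            while len(text) > i and len(cells) < n_cells:
                row = [int(t) for t in text[i].split()]
                cells.append(row[1 : 1 + row[0]])
                i += 1
            continue
        if line.startswith("SCALARS"):
            name = line.split()[1]
            i += 2  # skip LOOKUP_TABLE line
            vals = []
            while len(vals) < len(cells):
                vals.extend(int(t) for t in text[i].split())
                i += 1
            scalars[name] = vals
            continue
        i += 1
    if points is None or not cells:
        raise ValueError(f"{path}: polydata has no polyline cells")
    if "branch_label" not in scalars:
        raise ValueError(
            f"{path}: polydata is missing the 'branch_label' cell array"
        )
    labels = [VESSEL_LABELS[k] for k in scalars["branch_label"]]
    parents = scalars.get("parent", [-1] * len(cells))
    attach = scalars.get("attachment", [0] * len(cells))
    branches = tuple(
        Branch(
            labels[c],
            points[cells[c]],
            None if parents[c] < 0 else labels[parents[c]],
            int(attach[c]),
        )
        for c in range(len(cells))
    )
    return CenterlineTree(branches, sample_spacing=spacing)


# ---------------------------------------------------------------------------
# Lesions, transforms, reports
# ---------------------------------------------------------------------------

def write_lesions(lesions: list[Lesion], path: str | Path) -> None:
    path = Path(path)
    rows = [
        {"branch": l.branch, "arc_position_mm": l.arc_position,
         "grade": l.stenosis_grade}
        for l in lesions
    ]
    if path.suffix == ".json":
        path.write_text(json.dumps(rows, indent=1))
    elif path.suffix == ".csv":
        with path.open("w", newline="") as f:
            w = csv.DictWriter(f, ["branch", "arc_position_mm", "grade"])
            w.writeheader()
            w.writerows(rows)
    else:
        raise ValueError(f"unsupported lesion format: {path.name}")


def read_lesions(path: str | Path, tree: CenterlineTree | None = None) -> list[Lesion]:
    """Lesions from JSON/CSV; positions in mm, or as a branch-length
    fraction (column ``fraction``, requires ``tree``)."""
    path = Path(path)
    if path.suffix == ".json":
        rows = json.loads(path.read_text())
    elif path.suffix == ".csv":
        with path.open() as f:
            rows = list(csv.DictReader(f))
    else:
        raise ValueError(f"unsupported lesion format: {path.name}")
    out = []
    for r in rows:
        grade = int(r.get("grade", 50))
        if r.get("fraction") not in (None, ""):
            if tree is None:
                raise ValueError("fractional lesion positions require the tree")
            out.append(
                Lesion.at_fraction(r["branch"], float(r["fraction"]), tree, grade)
            )
        else:
            out.append(Lesion(r["branch"], float(r["arc_position_mm"]), grade))
    return out


def write_transform(transform: RigidTransform, path: str | Path) -> None:
    Path(path).write_text(
        json.dumps({"matrix_4x4": transform.matrix().tolist()}, indent=1)
    )


def read_transform(path: str | Path) -> RigidTransform:
    doc = json.loads(Path(path).read_text())
    return RigidTransform.from_matrix(np.asarray(doc["matrix_4x4"]))


def write_report(report: QuantReport, path: str | Path) -> None:
    path = Path(path)
    if path.suffix == ".json":
        path.write_text(json.dumps(report.to_dict(), indent=1))
    elif path.suffix == ".csv":
        write_report_csv([report], path)
    else:
        raise ValueError(f"unsupported report format: {path.name}")


def read_report(path: str | Path) -> dict:
    return json.loads(Path(path).read_text())


def write_report_csv(reports: list[QuantReport], path: str | Path) -> None:
    """One row per lesion, clinical table column names."""
    cols = [
        "Case", "Relevant coronary artery lesion(s)",
        "Left ventricular mass (grams)", "Subtended mass per lesion (grams)",
        "Total subtended mass (grams)", "Perfusion defect mass (grams)",
        "Perfusion defect mass per lesion (grams)", "Percent distributed",
    ]
    with Path(path).open("w", newline="") as f:
        w = csv.writer(f)
        w.writerow(cols)
        for r in reports:
            disp = r.rounded()
            for (vessel, grade) in r.lesions:
                w.writerow(
                    [
                        r.case_id, f"{vessel} >={grade}%", disp["lv_mass_g"],
                        disp["subtended_mass_g"][vessel],
                        disp["total_subtended_mass_g"], disp["defect_mass_g"],
                        disp["defect_mass_per_lesion_g"][vessel],
                        "" if disp["percent_distributed"] is None
                        else disp["percent_distributed"],
                    ]
                )


# ---------------------------------------------------------------------------
# 3D object export (legacy ASCII VTK)
# ---------------------------------------------------------------------------

def _write_surface_vtk(verts: np.ndarray, faces: np.ndarray, path: Path,
                       title: str) -> None:
    lines = _vtk_header(title)
    lines.append(f"POINTS {len(verts)} double")
    for p in verts:
        lines.append(" ".join(_fmt(c) for c in p))
    lines.append(f"POLYGONS {len(faces)} {4 * len(faces)}")
    for f in faces:
        lines.append("3 " + " ".join(str(int(v)) for v in f))
    path.write_text("\n".join(lines) + "\n")


def _write_points_vtk(points: np.ndarray, path: Path, title: str) -> None:
    lines = _vtk_header(title)
    lines.append(f"POINTS {len(points)} double")
    for p in points:
        lines.append(" ".join(_fmt(c) for c in p))
    lines.append(f"VERTICES {len(points)} {2 * len(points)}")
    for i in range(len(points)):
        lines.append(f"1 {i}")
    path.write_text("\n".join(lines) + "\n")


def mask_surface(mask: VoxelMask) -> tuple[np.ndarray, np.ndarray]:
    """Closed triangle surface of a mask's nonzero region, world mm."""
    vol = np.pad(mask.astype_bool().astype(float), 1)
    verts, faces, _, _ = _sk_measure.marching_cubes(
        vol, level=0.5, spacing=mask.grid.spacing
    )
    verts = verts + np.asarray(mask.grid.origin) - np.asarray(mask.grid.spacing)
    return verts, faces


def mesh_volume_mm3(verts: np.ndarray, faces: np.ndarray) -> float:
    """Enclosed volume of a closed triangle mesh (divergence theorem)."""
    v0, v1, v2 = verts[faces[:, 0]], verts[faces[:, 1]], verts[faces[:, 2]]
    return float(abs(np.einsum("ij,ij->", v0, np.cross(v1, v2))) / 6.0)


def export_vtk_objects(
    labels: TerritoryLabelMap,
    defect: VoxelMask | None,
    tree: CenterlineTree,
    lesions: list[Lesion],
    out_dir: str | Path,
) -> list[Path]:
    """Export quantification results as 3D objects in VTK format.

    One surface per lesion territory, one for the defect, the centerline
    polylines, and point-glyph markers at the lesion anchors.  An empty
    territory gets its marker only, with a warning.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []
    if labels.lesion_names is None:
        raise ValueError("territory label map has no lesion territories")
    for name in labels.lesion_names:
        territory = labels.territory_mask(name)
        p = out_dir / f"territory_{name}.vtk"
        if territory.count == 0:
            warnings.warn(
                f"territory of lesion {name!r} is empty; writing its anchor "
                "marker only", stacklevel=2,
            )
            continue
        verts, faces = mask_surface(territory)
        _write_surface_vtk(verts, faces, p, f"subtended territory {name}")
        written.append(p)
    if defect is not None and defect.count > 0:
        p = out_dir / "defect.vtk"
        verts, faces = mask_surface(defect)
        _write_surface_vtk(verts, faces, p, "perfusion defect")
        written.append(p)
    p = out_dir / "tree.vtk"
    _write_tree_vtk(tree, p)
    written.append(p)
    anchors = np.array([lesion_anchor_point(tree, l) for l in lesions])
    if len(anchors):
        p = out_dir / "lesion_markers.vtk"
        _write_points_vtk(anchors, p, "lesion anchor markers")
        written.append(p)
    return written


# ---------------------------------------------------------------------------
# Config files
# ---------------------------------------------------------------------------

def parse_config(path: str | Path) -> dict[str, str]:
    """Simple ``key = value`` config format, '#' comments."""
    out: dict[str, str] = {}
    for raw in Path(path).read_text().splitlines():
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        if "=" not in line:
            raise ValueError(f"malformed config line: {raw!r}")
        k, v = line.split("=", 1)
        out[k.strip()] = v.strip()
    return out
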