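# Methods

## Model and procedure

`voromyo` quantifies, for each significant coronary lesion, the
left-ventricular myocardium that lies downstream of it, and attributes a
delineated stress-perfusion defect to lesions by territory intersection.
The pipeline runs in six stages:

1. **Rasterization.** Epi/endocardial contour stacks (short-axis planes)
   become a boolean myocardium mask: a voxel is myocardial iff its center
   is inside the epicardial polygon and outside the endocardial polygon of
   its slice, decided by the even-odd (crossing-number) rule on voxel
   centers. This rule is implemented directly rather than through a
   library fill because the boundary semantics are part of the contract:
   the same half-open ray rule resolves points on shared edges
   deterministically, and the analytic-annulus convergence tests pin it.
2. **Lesion filtering.** When one vessel path (a branch or its side
   branches) carries several lesions, only the most proximal is kept: a
   lesion is dropped iff its anchor lies in another lesion's distal
   subtree. Lesions in sibling subtrees (e.g. a mid-LAD and a diagonal
   lesion) are both kept. The survivors' distal point sets are provably
   pairwise disjoint, which makes per-lesion territory masses additive.
3. **Nearest-centerline assignment.** Every myocardial voxel center is
   assigned the closest centerline sample point in world-mm Euclidean
   distance — a point-sampled Voronoi partition. The tree is first
   resampled to uniform ≤ 0.5 mm arc spacing so point sampling
   approximates the continuous segment distance to within 0.25 mm, finer
   than the 1 mm in-plane voxel grid.
4. **Subtended mass.** A lesion's territory is the set of voxels whose
   owner point lies in its distal point set; its mass is
   count × voxel volume × density. Total subtended mass is the plain sum
   over lesions.
5. **Registration.** The stress frame is aligned to the rest frame
   rigidly: corresponding contour point sets solve in closed form
   (centroid + Kabsch SVD); non-corresponding sets iterate closest-point
   correspondence (RMS change < 1e-4 mm or 100 iterations). Defect masks
   resample by nearest neighbor so they stay binary. A `pre_aligned`
   bypass skips the stage.
6. **Defect attribution.** The registered defect is clipped to the
   myocardium (clipped-away voxels are warned about, since they usually
   reflect drawing or registration slack at the border), intersected with
   each territory, and the percent distributed is
   round(100 × attributed/total), half away from zero; a zero-mass defect
   has an undefined (None) percent rather than 0. Defect voxels inside
   the myocardium but in no lesion territory are reported as an
   unattributed mass — this is precisely what makes real cases fall below
   100%.

## Parameters that matter

| parameter | default | unit | rationale |
|---|---|---|---|
| tissue density ρ | 1.055 | g/mL | standard average myocardial density; configurable |
| in-plane voxel spacing | 1.0 | mm | analysis-grid default; rasterization error < 0.5% for LV-sized annuli |
| slice spacing | 4.0 | mm | the short-axis reformat convention this tool targets |
| centerline sample spacing | 0.5 | mm | half the in-plane spacing, so centerline discretization does not dominate territory boundaries |
| bullseye sectors | 36 × 10° | — | divisible by 12, so 17-segment sextant/quadrant edges fall on sector edges |
| bullseye zero angle | anterior direction | deg | supplied by config; phantoms place the LAD there (90° in phantom coordinates) |

Voxel convention: 0-based indices, world position = origin + index ×
spacing (voxel-center). All distances in world millimetres.

## Determinism and tie-breaking

Assignment evaluates squared distances exhaustively (chunked, vectorized)
with component accumulation in fixed order ((dx² + dy²) + dz²) and
first-minimum tie-break over a canonical point ordering (branch labels
lexicographic, then arc length). A KD-tree would be faster asymptotically
but does not document tie behaviour; at this problem's scale (~10⁴–10⁵
myocardial voxels × ~10³ centerline points) exhaustive evaluation runs in
seconds and is bit-identical to the naive per-pair search, which the test
suite verifies on random instances.

Voxels exactly equidistant from two branches (e.g. a mirror-symmetric
configuration whose symmetry plane is a lattice plane) all go to the
lexicographically lower branch; symmetry-based tests therefore use
lattices whose voxel centers avoid the symmetry plane.

## The synthetic phantom

No public imaging data accompany this kind of quantification, so the
phantom module generates fully ground-truthed cases:

- **LV shell**: half-ellipsoid (apex at z = 0), semi-axes
  (R, R, L) = (33.5, 33.5, 80) mm with 10.5 mm wall, sliced every 4 mm.
  The defaults give ≈ 117 g, matching the ~118 g population average the
  method targets; `scaled_to_lv_mass` rescales isotropically across the
  observed 60–260 g range. The closed-form shell volume
  (2π/3)[R²L − (R−t)²(L−t)] anchors rasterization accuracy (< 3% error at
  the default grid, dominated by in-plane discretization of the small
  apical contours).
- **Coronary tree**: 13 labeled branches on the epicardial surface
  (+0.5 mm standoff), LAD anterior, circumflex lateral, RCA inferior; the
  left main trifurcates into the LAD chain, intermediate branch and
  circumflex. Paths interpolate linearly in (height, angle).
- **Defects**: seeded region growing with randomized frontier selection —
  irregular, connected, mass-controlled blobs inside one territory, or
  grown across a chosen boundary at a requested mass fraction. Exact
  per-territory voxel counts are recorded as ground truth.
- **Stress frame** (optional): a known rigid perturbation about the long
  axis produces stress-frame contour points and a resampled stress-frame
  defect for exercising registration.

What the phantom does *not* emulate: CT intensities and noise, papillary
muscles and trabeculation, the right ventricle, coronary tortuosity and
lumen taper, deformable (beat-to-beat) motion between frames, and
observer variability in contouring. Passing the phantom suite therefore
demonstrates that the geometric pipeline is correct and self-consistent,
not that territory assignment reflects true microvascular supply in a
patient; the nearest-centerline model itself is a geometric surrogate for
perfusion territories.

## Numerical choices and degenerate inputs

- Masses are computed and stored as raw floats; integer-gram rounding
  (half away from zero) is display-only, so totals always equal sums of
  parts pre-rounding.
- A contour slice off the grid lattice or outside its extent is an error
  naming the slice; self-intersecting polygons and endocardial contours
  not inside the epicardial contour are rejected at construction.
- Zero-width annuli rasterize to empty masks; empty myocardium is an
  error for assignment and defect measurement.
- Nested lesions (overlapping distal sets) are rejected by the territory
  stage rather than silently merged; `select_most_proximal_lesions` is
  the sanctioned way to resolve them.
- Rigid transforms are validated orthonormal (det +1); collinear point
  sets are rejected by registration.
- Empty territories export an anchor marker but no surface, with a
  warning; a defect territory intersection of zero is a legitimate 0 g.
- Double nearest-neighbor resampling on the anisotropic 1 × 1 × 4 mm grid
  can move a few percent of a small blob's mass across slice boundaries;
  the stated < 2% resampling stability refers to a single resampling at
  1 mm isotropic spacing, and end-to-end stress-frame phantoms are judged
  against that tolerance only at that spacing.

## Problem sizes used in validation

The automated checks run the default phantom (≈ 105 × 105 × 20 grid,
≈ 28k myocardial voxels, ≈ 1.4k centerline samples) and a 20-case sweep
spanning 60–260 g LVs with 1–3 lesions and 1–13 g defects; Voronoi oracle
equivalence uses 100 random instances on grids up to 12³ with trees up to
50 points. These sizes exercise every code path at full fidelity while
keeping the whole validation run within a few minutes.

## Known limitations

- Rigid-only registration; real rest/stress pairs deform. The
  unattributed-defect mechanism surfaces the resulting mismatch but does
  not correct it.
- Point-sampled (not segment-exact) Voronoi distance, bounded by half the
  sample spacing.
- The bullseye angular reference and sector count are documented package
  conventions, not reconstructions of any particular clinical software;
  ring grouping for the 17-segment model (apex = endo-less rings,
  remaining thirds apical/mid/basal) is likewise a convention.
- On a square lattice, per-sector voxel counts of a perfectly circular
  annulus vary by a few voxels between sectors (only quarter-turn
  symmetry is exact); sector-level comparisons should allow for this
  lattice jitter.
- VTK export encodes branch labels as indices into the fixed 13-label
  vocabulary; trees with custom labels round-trip through the JSON
  dialect only.
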