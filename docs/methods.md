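# Methods

## The planning problem

A pedicle screw corridor is modeled as a cylinder of fixed diameter D and
length L (default 6 × 30 mm), described by an entry point on the posterior
bone surface and a unit direction. Its quality score is the mean Hounsfield
value over the cylinder volume, on the premise that CT attenuation is
linearly related to bone mineral density and therefore to the bone stock the
screw thread engages. The automatic planner maximizes this score subject to
three hard constraints:

1. **Containment** — the whole cylinder stays inside bone (cortical shell,
   cancellous body or pedicle);
2. **Pedicle passage** — the cylinder intersects the marked
   narrowest-section ROI of its pedicle (the mandatory anatomical corridor);
3. **Anterior margin** — the screw tip lies inside the vertebral body with
   at least one screw radius of bone beyond it.

The screw is deliberately allowed to run arbitrarily close to (and inside)
cortical bone: cortex is the densest bone available, and only leaving the
bone mask counts as a breach. A configurable safety margin (default 0 mm)
can add clearance to both the containment and anterior checks.

## Corridor scoring

The cylinder is sampled on a deterministic equal-volume lattice: axial
stations at the midpoints of equal segments (default step: half the minimum
voxel spacing), and per station the disk is split into `rings` (default 3)
equal-area zones — a central point plus annuli carrying 8·j points at their
equal-area mid-radius. HU values are read by trilinear interpolation; the
score is the weighted mean. A centerline-only variant exists behind a flag,
since it is unknown whether deployed planners weight by volume; the volume
mean is the default because screw purchase depends on all the bone the
thread occupies. Sampling a point outside the scanned grid is an error, not
padding — a corridor outside the scan is meaningless. The default lattice
agrees with a 10× denser one to well under 0.5 % on the phantom.

## Constraints via distance maps

Containment is decided by interpolating the Euclidean distance transform
(anisotropy-aware, voxel-center to voxel-center) of the bone mask along the
screw centerline at half-voxel steps: contained iff the minimum distance
covers the screw radius plus the safety margin, with boundary equality
counting as contained (a deterministic tie rule). The first
0.75 diameters behind the entry point are excluded from the check: the
screw necessarily crosses the posterior cortical surface there, and the
breach of interest is the shaft leaving bone beyond the entry, not the
entry hole itself. A brute-force voxel-classification oracle (every voxel
within one radius of the centerline must be bone) is kept in the package
and cross-checked in the tests; the two routes agree whenever the margin is
larger than one voxel diagonal, the honest resolution limit of either
decision.

## Manual baseline

The minimal pedicle cross-section is found by sweeping cutting planes
perpendicular to the pedicle's principal axis (SVD of its voxel cloud,
oriented anteriorly) at half-voxel steps; the area at a station is estimated
from a two-voxel-thick slab, ties broken toward mid-length. The manual
trajectory runs through the slab centroid along the principal axis projected
parallel to the lower endplate, entering at the posterior bone surface
(found by ray casting with sub-voxel bisection). On phantoms with a
pronounced waist the section centroid localizes to within half a voxel; on
the default shallow waist the along-axis position is soft by design
(≈ 1–2 mm), which the planner tolerates since the ROI disk is a hard
constraint anyway.

## Automatic search

The optimizer is a two-stage deterministic scheme, chosen over stochastic
metaheuristics for bit-reproducibility and oracle-testability:

* **Stage 1 (grid):** entry points on the posterior surface patch around
  the pedicle-axis entry (default ± 3 mm at 1 mm steps, re-projected onto
  the surface by ray casting), crossed with directions in a cone around the
  pedicle axis (default half-angle 20° at 2° steps on a tangent-plane
  grid). Every candidate is feasibility-checked and, if feasible, scored.
* **Stage 2 (refinement):** compass pattern search over the four continuous
  degrees of freedom (two entry offsets, two direction tilts), halving
  steps from half the grid step down to 0.25 mm/0.25°, rejecting
  infeasible moves and accepting only strict improvements.

Exact score ties are broken lexicographically by (entry index, direction
index) — first visited wins — so flat objectives still yield identical
results across runs. With refinement disabled, stage 1 is provably
identical to the brute-force enumeration oracle (same candidate set, same
tie rule), which the tests assert exactly. The search cone default covers
the axial/sagittal deviations such planners exhibit in practice (≈ 5–16°)
with margin. Pattern search is a local method: it refines the best grid
candidate and cannot hop between distant basins, which is the intended
division of labor with the global stage-1 grid.

The screw-size recommendation (largest standard diameter ≤ 0.8 × the
minimal caliper width of the pedicle section; largest standard length
≤ 0.8 × the bone chord along the pedicle axis) is an invented,
clearly-labeled heuristic: deployed planners compute a recommendation, but
no formula is published.

## Densitometry

`T′ = (CT − CT_ref)/SD_ref`, with the reference statistics either supplied
directly (e.g. a printed reference population of untreated vertebrae,
2767.87 ± 26.15 Hu) or computed from raw untreated means with the n−1
sample SD. The osteoporosis threshold is inclusive (`T′ ≤ −2.5`): reported
study definitions mix `≤` and `<`, the formula-defining statement uses `≤`,
and the boundary behavior is unit-tested. Group T′ statistics follow by
linearity (mean transforms affinely, SD scales by 1/SD_ref). When scoring
against printed group means rather than per-specimen data, agreement is
expected only to ±0.01 from rounding of the inputs, and the tests tolerate
exactly that.

The comparative study report derives percent differences
(`100·(a−b)/b`) and ratios (`100·a/b`) between planning groups. One derived
quantity needs care: the "control exceeds decalcified-manual" pull-out
comparison is computed relative to the *decalcified-manual* baseline (the
form consistent with the published 48.6 % figure), and its report key names
that baseline explicitly.

## Synthetic vertebra phantom

The phantom is an idealized geometric vertebra rather than an atlas mesh,
so every test has an analytic oracle: an elliptical-cylinder body (half
axes 18 × 14 mm, height 30 mm) with a voxelized cortical shell
(1.5 mm, via the distance transform of the body mask), a circular spinal
canal (radius 7 mm), a posterior bone block standing in for the lamina
(the screw entry surface), and two oblique pedicle cylinders
(radius 4.5 mm, length 18 mm, convergence 15°) with a mild hourglass waist
(radius reduced 15 % at mid-length) and a cortical-HU sleeve. The pedicle
channel overrides block/body labels so its cross-section remains a full
hourglass disk along the whole axis — as with a real pedicle, it merges
continuously into its neighbors. One-voxel-thick ROI disks at the waist
carry the narrowest-section labels. Default sizes leave a 6 × 30 mm screw
a ~0.8 mm analytic containment margin through the waist: tight enough to
exercise the constraint machinery, loose enough to survive 0.5 mm
voxelization.

HU defaults (cortical 3100, cancellous 2650 ± 60, soft tissue 30 Hu) sit on
the micro-CT scale of embalmed porcine specimens, giving a whole-vertebra
mean near 2790 Hu. Cancellous noise is i.i.d. Gaussian, seeded, and
mirrored about the midline so the noise-free mirror symmetry of the
geometry extends to the HU field — left/right planner symmetry then has an
exact oracle. Identical spec + seed is bit-identical by construction. An
optional planted corridor adds a fixed HU boost inside a cylinder anchored
at the pedicle waist (default: tilted 6° toward the upper endplate, radius
3.2 mm, +600 Hu), restricted to bone voxels; it is the recovery target for
optimizer tests. The waist anchor is deliberate: a corridor offset
laterally *at* the waist would be unreachable by any contained screw, so
the offset grows away from the waist instead.

**Decalcification** is modeled as uniform multiplicative attenuation of
bone HU toward water (0 HU): `HU → f·HU` on bone voxels, `f ∈ [0, 1]`.
This is the direct computational translation of the linear CT–BMD premise;
EDTA transport chemistry, demineralisation gradients and trabecular
microstructure are explicitly not modeled. Consequences used by the code
and tests: composition multiplies factors, the whole-vertebra mean scales
linearly, T′ is strictly decreasing in attenuation, and the factor hitting
a target T′ has the closed form `f = (CT_ref + T′·SD_ref)/CT_mean` (exact
to float precision, verified to 1e-3 after re-measurement).

### What the phantom does and does not show

Passing tests on the phantom demonstrate correctness of the geometry,
constraint logic, optimizer and densitometry arithmetic against analytic
ground truth. They do not demonstrate performance on real CT: the phantom
has no trabecular texture, no spatially correlated noise, no beam-hardening
or partial-volume artifacts, no segmentation error (labels are exact), and
an idealized symmetric anatomy. Absolute pull-out forces are physical
measurements outside computational scope; the package reproduces only the
comparative arithmetic between group summaries.

## Numerical choices and problem sizes

* Trilinear interpolation for HU and distance-map sampling; nearest-voxel
  lookup for labels.
* World ↔ voxel transforms via the NIfTI affine; round trips are identity
  to 1e-9 mm.
* Degenerate projections (screw axis parallel to a projection-plane
  normal) raise instead of returning NaN, so optimizer loops fail loudly.
* Default phantom resolution 0.5 mm (≈ 0.7 M voxels); planner tests use
  entry patches of ± 1–2 mm and cones of 6–12° so a full grid stage stays
  at a few thousand candidates and a complete suite run takes well under a
  minute per phantom. These sizes were chosen once as representative of
  the geometry; the search machinery is identical at larger settings.

## Known limitations

* The entry-inset containment rule is a modeling decision; planners that
  model the screw head/cortical entry explicitly may grade near-entry
  breaches differently.
* `estimate_frame` (used when no frame is supplied to the CLI) assumes the
  package's fixed RAS-like orientation; arbitrarily oriented scans need an
  explicit frame.
* Medial vs lateral pedicle walls are treated symmetrically; asymmetric
  safety margins are not implemented.
* Single-level, single-screw planning only; no bilateral joint optimization
  and no guide-plate solid modeling (only entry/tip coordinate export).
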