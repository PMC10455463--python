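# Methods

`craniofab` re-creates, at desk scale, the complete workflow behind a
patient-specific porous PEEK cranial implant: CT-derived bone model →
mirror-reconstruction design → diamond-lattice scaffold at a target
porosity → linear static strength check → fitting-accuracy analysis.
Because no patient CT can ship with the package, a synthetic skull
phantom with controlled ground truth stands in for the patient, which
turns every stage of the workflow into a testable computation.

## The skull phantom

The phantom is the region between two concentric triaxial ellipsoids:
outer semi-axes `(a, b, c)` (default 70 × 85 × 60 mm — an adult cranial
vault: breadth 140 mm, length 170 mm, height 120 mm) and inner semi-axes
`(a−t, b−t, c−t)` with shell thickness `t = 6` mm, at the upper end of
the 4–7 mm cortical-shell range. The world frame puts the midsagittal
plane at `x = 0` (left negative), `y` anterior–posterior, `z`
inferior–superior, all in mm. An optional smooth random bump field
(sum of seeded cosine modes, correlation ≈ 40 mm) can displace the outer
surface radially on the left side only, breaking bilateral symmetry by a
controlled amplitude; at amplitude 0 the sampling grid is itself
mirror-symmetric, so the mesh is exactly symmetric — the property the
mirror-reconstruction stage exploits, and the reason its error can be
driven to the resolution floor here.

The ellipsoid was chosen over an anatomical surface deliberately: every
procedure under test depends only on bilateral symmetry and two-surface
shell topology, and the ellipsoid provides closed-form volumes
(`4π/3·(abc − a′b′c′)`) that anchor the oracles.

The segmental defect is a sphere (default radius 22 mm, centred on the
left parietal mid-surface) boolean-subtracted from the shell — a clean
stand-in for a resected calvarial window.

What the phantom does *not* emulate: anatomical curvature variation,
sutures, diploë (the shell is homogeneous cortical bone), soft tissue,
and CT physics beyond Gaussian intensity noise (no beam hardening or
partial-volume bias). Passing tests therefore demonstrate that the
*procedures* are correct and self-consistent, not that their numerical
outputs transfer to any particular patient.

## Simulated measurements

* **CT synthesis** rasterizes the shell into a volume at 1 mm isotropic
  spacing with bone at 1200 HU, air at −1000 HU and Gaussian noise of
  30 HU — contrast far above the 226 HU segmentation threshold, as in
  clinical bone windows.
* **Manufacturing error**: additively manufactured parts end up slightly
  proud of their design (over-extrusion, staircase build-up), and the
  study quantity is explicitly a mean deviation *in the outward
  direction*. The simulator therefore displaces vertices outward along
  their normals by a strictly non-negative smooth random field
  (|seeded cosine field|, correlation 15 mm) rescaled so its
  area-weighted mean equals the requested amplitude (default 0.33 mm,
  the scale reported for FFF-printed PEEK). The mean outward deviation
  of the part against its design then recovers the amplitude directly,
  giving the fitting stage a known answer.
* **Scanning** samples the surface area-uniformly at a chosen density
  (default 1 pt/mm²), adds isotropic Gaussian noise (default 0.05 mm, an
  articulated-arm laser scanner's scale) and applies a rigid pose.
* **Aesthetic scores** are drawn per expert × replicate from a normal
  (default mean 3.66, SD 0.5) rounded to the 1–5 integer scale and
  clipped; ten experts × five replicates by default.

All generators take a seed and are bit-reproducible.

## Geometry backend: anti-aliased voxel occupancy

No exact mesh-boolean engine is part of the dependency set, and boolean
robustness on marching-cubes meshes is notoriously fragile anyway, so
every boolean-style operation (difference, union/wrap, plane split,
defect carving, screw drilling) runs on a fractional occupancy grid:

1. a numba parity rasterizer casts a 2 × 2 bundle of +z rays per (x, y)
   cell and records exact crossing intervals, giving each cell a solid
   *fraction* (exact along z, 2× supersampled in x and y);
2. fractions combine by fuzzy logic — `max` for unions, `min(a, 1−b)`
   for differences, saturating *sum* for parts that abut along a shared
   face (the mirror-merge case, where `max` would read the half/half
   seam as empty);
3. analytic primitives (balls, halfspaces, cylinders, the lattice
   distance field) contribute anti-aliased fractions directly;
4. surfaces come back via a Gaussian-smoothed (σ = 0.5 cell) 0.5-level
   marching cubes, which recovers sub-voxel surface position from the
   fractions: measured mean surface error is ≈ 3 % of the pitch on
   smooth solids, and volume bias ≈ 0.1–0.3 %.

Sharp edges are rounded over ~1 cell and features thinner than ~2 cells
cannot survive a round trip; per-operation pitches are chosen so stated
tolerances hold (0.5 mm for skull-scale booleans, 0.8 mm for the wrap,
0.15 mm for the lattice, with automatic refinement for small inputs).
Marching-cubes output is deliberately *not* vertex-merged (merging can
pinch the surface open); extrusions of ragged patches may pinch at
isolated "butterfly" vertices, so closedness is validated by the
even-edge-count criterion rather than strict two-manifoldness — parity
rasterization and divergence-theorem volumes are exact under it.

## Mirror reconstruction

The midsagittal plane is found without a manual datum: initialize from
the principal axis closest to lateral, then iterate "reflect surface
samples across the current plane → rigidly register them onto the skull
by point-to-plane ICP → replace the plane by the fixed plane of the
nearest pure reflection to the composite motion". Point-to-plane steps
matter: point-to-point ICP stalls on tangential sliding over smooth
near-ellipsoidal surfaces and leaves ~1° errors, while the point-to-plane
variant recovers the plane of a symmetric phantom to < 10⁻⁴ degrees.
A residual symmetry RMS above 2 mm raises a warning (the anatomy may not
be bilateral); a user-supplied plane always overrides.

The defective skull is split at the plane, the healthy half mirrored,
and both fused by union + one-voxel morphological closing at the wrap
voxel (default 0.8 mm) — the closing seals the seam and interior slivers
the way commercial "wrap" operations do. Boolean subtraction of the
defective skull from the rebuilt one, restricted to a box around the
defect, leaves the implant template (largest component; voxel crumbs
from coincident surfaces are dropped).

On the symmetric phantom the rebuilt skull deviates outward from the
clean anatomy by ≈ 0.03 mm at a 0.8 mm wrap and ≈ 0.015 mm at 0.4 mm —
the zero-asymmetry limit of mirror-reconstruction modelling error, an
order of magnitude below the ~0.11 mm seen with real anatomy.

## Implant design

* **Outer surface**: template faces within 1 mm of the skull surface
  whose normals point away from the skull centre (radial dot > 0.5) —
  this keeps the outer table and rejects the inner table and cut walls;
  largest connected patch wins.
* **Offset shell**: the patch swept 4 mm inward along its vertex
  normals, side walls stitched from the boundary loops (Eulerian cycle
  decomposition of the directed boundary edges, robust to butterfly
  vertices).
* **Rim/core split**: the rim is the band within `rim_width` (default
  6 mm) of the swept side wall, kept solid for four 2 mm fixation screw
  holes drilled along local surface normals; the core becomes the
  scaffold.
* **Diamond lattice**: struts of radius `r` along the tetrahedral bond
  directions of the diamond crystal (two interpenetrating FCC
  sublattices), cell edge 2.5 mm. The periodic distance-to-skeleton
  field is precomputed once on a 128³ table, so lattice geometry at any
  radius is a table lookup. The scaffold surface is the zero level of
  `max(d(x) − r, φ_core(x))` (φ = signed distance of the core) on a
  0.15 mm grid — an *analytic* field, so strut surfaces are sub-voxel
  accurate and untouched by the thin-feature limits above.
* **Porosity targeting**: porosity is `(V1 − V2)/V1 × 100` with `V1` the
  core bulk volume and `V2` the strut material volume, both counted on
  the anti-aliased grid. The strut radius is bisected (≤ 30 iterations)
  until the target 70 % is met within 0.5 percentage points; since the
  distance field is radius-independent, each iteration is a threshold
  count. Whether the published 70 % refers to the lattice-filled core or
  the whole implant including the solid rim is ambiguous, so both
  numbers are reported (`porosity_core_percent`,
  `porosity_assembly_percent`).
* **Pore metrology** emulates gauging pores on a few micrographs: random
  void probes hill-climb the distance-to-surface field to the locally
  largest inscribed sphere; five probes and their mean are reported in
  µm. With the 2.5 mm cell at 70 % porosity the mean lands near 1.3 mm,
  the bone-ingrowth scale targeted by diamond-lattice implants — this is
  why 2.5 mm is the default cell edge.

## Finite-element strength check

The assembly (cortical-bone skull, PEEK rim + explicit lattice struts,
four titanium screws placed at the screw sites crossing the
implant–skull wall) is meshed on one shared voxel grid: a cell belongs
to a part when the part covers its majority, labels prioritized
screw > implant > skull, and each occupied cell splits into six linear
tetrahedra (Freudenthal subdivision, face-conforming across the
lattice). Abutting regions therefore share nodes — exactly the bonded
contact condition — without any external mesher. The cost is a staircase
boundary; the benefit is unconditional conformity. A uniform grid at the
chosen element size (default 1.5 mm, within the customary 0.5–3 mm
range) is used rather than a graded one: conforming transitions between
octree levels would require hanging-node constraints out of proportion
to a linear verification model, and the uniform mesh already passes the
constant-strain patch test exactly and lands within 7 % of the
Euler–Bernoulli cantilever closed form at 1 mm elements.

Materials are isotropic linear elastic (mm–N–MPa): PEEK E = 3738 MPa,
ν = 0.4, yield 99.9 MPa; cortical bone 13 700 / 0.3 / 122; titanium
120 000 / 0.3 / 930. The default load case clamps a 5 mm basal slab and
distributes 50 N (a resting head's weight) over a face patch grown from
the implant's outer-surface centre until its area reaches 200 mm²
(0.25 MPa); the traction direction is the area-weighted mean inward
normal, so nodal forces sum to the total load exactly. The reduced
system is solved directly (sparse Cholesky-like factorization) up to
120 k free DOF and by Jacobi-preconditioned conjugate gradients above
(rtol 10⁻⁸); element-constant stresses yield von Mises values and
per-region safety factors.

At 1.5 mm voxels the 2 mm lattice struts are resolved only coarsely, and
rasterization strands a small number of disconnected strut fragments.
Unloaded fragments with no path to a fixed node are pinned at zero
displacement (their correct equilibrium) and counted in the result; a
*loaded* floating component raises an error naming the regions involved.
Assembled this way, the phantom assembly (~600 k elements / 140 k nodes)
carries the 50 N load at a peak implant von Mises of a few MPa —
a safety factor of well over 10 against PEEK yield, consistent with the
qualitative conclusion that a porous PEEK cranioplasty is structurally
benign under resting loads. The headline stress of a real patient
geometry is not reproducible from a phantom and is not claimed.

## Fitting analysis

Signed point-to-surface distance uses exact point-triangle distances on
KD-tree candidates, with the sign taken from the interpolated
vertex-normal field at the closest point. The headline statistic is the
**mean outward deviation**: the mean of strictly positive signed
distances after best-fit (point-to-plane ICP) alignment — points at or
inside the reference are excluded, zeros contributing nothing either
way. Total fitting error is reported as the sum of a modelling component
(designed implant vs. clean anatomy) and a manufacturing component
(aligned scan of the as-built part vs. its design) — the decomposition
convention in which 0.1114 + 0.3322 = 0.4436 mm — alongside the directly
measured scan-vs-anatomy value, which need not coincide (inner/lattice
scan points fall inward of the anatomy and dilute the direct statistic).
The region-of-interest variant restricts to the defect's bounding box
dilated by 5 mm, or compares the implant side against the mirrored
healthy side. Gap analysis reports axis-aligned x/y extents of implant
versus cavity (the resected wall piece) and their differences.

The aesthetic-score test is a one-sided one-sample t-test of
H₀: MAS ≤ 3 vs. Hₐ: MAS > 3 at α = 0.05. The observation unit is the
per-expert mean across replicates, so ten experts give n = 10 regardless
of the replicate count (a per-rating variant, n = 50, sits behind a
flag). A zero-variance table has no defined t; the decision then falls
back to comparing the mean with μ₀, flagged as such.

## Pipeline, sizes and determinism

`run_pipeline` chains the stages, writes STL/NIfTI/XYZ/CSV/VTK artifacts
plus a JSON manifest with SHA-256 checksums, per-stage timings and every
metric, and fails fast naming the broken stage. Default problem sizes —
1 mm phantom and CT grids, 0.5 mm booleans, 0.8 mm wrap, 0.15 mm lattice
grid, 1.5 mm FE voxels, 1 pt/mm² scans — run the full workflow in a few
minutes on one core; `scripts/acceptance.py` re-runs it end to end and
writes the headline numbers. All randomness flows from the single
config seed through fixed per-stage offsets, so identical config + seed
reproduces the metric block bit for bit.

## Known limitations

* Geometry tolerances are voxel-bound: booleans are accurate to a
  fraction of their pitch, not exact; knife-edge intersections (a ball
  grazing a surface) can locally pinch and are patched by hole filling.
* The FE boundary is a staircase; stresses at re-entrant voxel corners
  are mesh-dependent and should be read as scale estimates, not local
  truth. Lattice struts at the default element size are under-resolved.
* The symmetry-plane fit assumes approximate bilateral symmetry; heavily
  asymmetric anatomy degrades the mirror-reconstruction premise itself.
* The ICP basin is roughly ±30° of rotation; the simulated scan pose
  stays within it. Symmetric objects admit flip-equivalent alignments.
* Simulated expert scores are i.i.d. across experts and replicates; real
  panels correlate within experts.
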