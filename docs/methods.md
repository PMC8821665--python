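# Methods

## The measurement model

axonatlas treats a traced neuron as a forest of polylines and its length
per brain region as a counting measure: after resampling all cable at a
fixed arclength spacing *s*, the length assigned to structure *r* and
neurite class *c* is

  L(r, c) = s · #{ resampled points of class c whose containing atlas
                   voxel carries label r }.

Two consequences are load-bearing and are asserted by the test suite
rather than documented as approximations:

* **Exact conservation.** Σᵣ L(r, c) over all structures, including the
  "unassigned" bucket for points outside the atlas, equals (point count of
  class c) × s bit-exactly, because every point receives exactly one label.
* **Bounded discretization error.** With midpoint placement (one point at
  arclength (k + ½)s, k = 0 … round(L/s) − 1 per path), the count of a path
  of length L errs from L/s by at most ½, and the count falling inside any
  contiguous arclength interval errs by at most 1. Hence a region touched
  by P paths with B cable-boundary crossings is recovered within
  ½·s·P + s·B of its true cable. Vertex-anchored placement (points at
  0, s, 2s, …) would instead overcount by ≈ 1 point per path — across the
  thousands of paths of a ~70 mm arbor, a millimetre-scale bias — which is
  why the midpoint rule is the default and only rule.

Neurite classes pool the SWC type codes: 2 → axon, 3 and 4 → dendrite
(basal and apical are not reported separately), 1 (soma) and unknown codes
are excluded from cable totals by default (`include_soma` re-admits soma
points; excluded counts are recorded in the table metadata). Paths break at
type-code changes so no resampled point straddles an axon/dendrite
boundary.

## Coordinate conventions

* ESWC coordinates are continuous positions in a 0-based imaging-voxel
  frame; physical conversion multiplies componentwise by the imaging voxel
  size (0.8, 0.8, 5) µm by default, with no half-voxel offset. Conversion
  is a one-way state change (`voxel` → `micron`); re-converting raises
  rather than silently rescaling.
* Atlas lookup uses the half-open convention: point **x** belongs to voxel
  ⌊(**x** − origin)/v⌋, so a point exactly on the plane k·v goes to the
  higher voxel. The brute-force equivalence of this rule is part of the
  acceptance suite.
* Anatomical axes are (AP, DV, ML) with DV = 0 at the pial surface in the
  synthetic atlas. The grid-axis ↔ anatomical-axis mapping of a loaded
  volume is declared (`axis_order`), not guessed: deposited volumes do not
  reliably encode it.
* Whether a deposited ESWC is in voxel units or already in µm is likewise
  not guessed: `NeuronReconstruction.coordinate_ranges()` reports per-axis
  ranges so the caller can decide what `space` to declare.

## Registration transforms

The package consumes transform chains (ordered affines and dense
displacement fields, µm units); it never estimates them — registration
belongs to external tools. Labels are never numerically interpolated:
warping a parcellation inverse-maps each output voxel center and reads the
source label with the same half-open rule. Equivalently, the resampled
points can be mapped atlas-ward through the inverse chain and the unwarped
parcellation queried directly; this point route is the default because it
is cheaper and avoids committing to an output grid. The two routes agree
except at nearest-neighbour ties where a point and its voxel center
inverse-map into different source voxels.

Displacement fields invert by fixed-point iteration x ← y − d(x)
(tolerance 0.01 µm, 50 iterations max, divergence is an error with the
residual reported), which converges for the smooth, small-displacement
fields that brain registration produces. Affines invert exactly.
Downsampling to atlas resolution groups input voxels by the output voxel
containing their center — this accommodates the anisotropic, non-integer
ratio of a 0.8 × 0.8 × 5 µm stack onto a 25 µm grid — with block mean for
intensities and block mode for labels (ties to the smallest label; the
mode can only return labels present in the input).

## Barrel columns and somata

The barrel-column map is a second label volume in the atlas frame with
named columns (row letter A–E + arc number). A soma (centroid of soma-type
nodes, or the unique root) in a labeled voxel reports that column; in an
unlabeled voxel it reports the up-to-two nearest distinct columns with
labeled voxels within `septum_radius` (default 150 µm, about half an
inter-column pitch) as a septal position, else "outside the barrel field".
Septal somata are reported as septal rather than force-assigned to the
nearest column, because the septum is a real anatomical compartment.

## Cohort statistics

Per-structure cohort summaries impute 0 for neurons lacking a region, so
n equals the cohort size in every row; SD is the sample SD (n − 1
denominator, 0 by convention for n = 1); rows order by descending mean
with acronym tie-break, the ordering the bar-chart views use. Mixing
tables produced against different atlas versions is an error.
Millimetre-precision reporting rounds half-to-even at 0.1 mm.

## Figure views

All views are orthographic drops of one anatomical axis of the resampled
cloud; the tangential barrel-field view first rotates the cloud about the
AP axis (30° by default; axis and angle are configurable because published
tangential views do not state their exact convention). Serial overlays
partition the AP span into `section_count` half-open slabs of thickness
span/count (five sections is the default — the figure convention this
package renders uses five sections per panel at 250–825 µm each). Tests
assert on exported coordinate arrays, never on encoded image bytes.

## The synthetic-data generator

`synthetic` builds everything the pipeline reads, with exact ground truth:

* **Atlas** — a 6 × 2 × 6 mm block at 25 µm: a 1 mm cortical sheet tiled by
  nine areas (SSp-bfd at the center), each subdivided into layers L1/L2-3/
  L4/L5/L6 whose boxes tile the parent exactly; a white-matter slab
  (cc, scwm) beneath the cortex; a caudoputamen block below that; a nested
  ontology root → {Isocortex, fiber tracts, STRd} → region → layer. Region
  boxes must align to the voxel grid so voxelized and analytic membership
  coincide.
* **Barrel map** — 5 rows × 3 arcs of vertical cylinders (radius 140 µm,
  pitches 350/500 µm) inside SSp-bfd, with unlabeled septal gaps.
* **Neurons** — straight cable segments at ≤ 5 µm node spacing, written in
  imaging-voxel units (0.8, 0.8, 5 µm). Ground truth clips every segment
  against the leaf region boxes analytically, recording per-region cable,
  interval counts and boundary crossings — so end-to-end pipeline error is
  attributable entirely to resampling/lookup discretization and must obey
  the bound above. Optional orthogonal sinusoidal jitter is off by
  default; when on, the truth carries an arclength-inflation bound
  (½(2πA/λ)² per unit length) instead of being recomputed.
* **Cohort** — ten layer 2/3 barrel-cortex neurons by default: total axon
  drawn from N(67.9, 13.0) mm and dendrite from N(7.2, 0.8) mm (the
  published cohort statistics for this cell class); soma in a named column,
  every third neuron in a septum; ~50–65 % of axon as dense local cable in
  the home area; 2–4 long-range intracortical branches that travel in
  layer 2/3 gray matter (crossing area boundaries en route); a callosal
  white-matter branch for half the cohort and a descending striatal branch
  for a third. All generators are seed-deterministic down to byte-identical
  output files.

What the generator does **not** emulate: curved/tortuous cable (segments
are straight between way-points), tracing errors and gaps, radius
variation, fluorescence or imaging noise, curved laminar surfaces, and a
realistic whole-brain geometry. Passing tests therefore demonstrate the
correctness of the measurement machinery — conversion, resampling,
lookup, aggregation, transforms — not robustness to reconstruction error
or registration misfit in real data.

## Numerical and design choices

* round(L/s) uses half-up at the exact half-step boundary; the boundary is
  measure-zero for real data and covered by the ±½ per-path bound either way.
* Zero-length edges (duplicate consecutive coordinates) are collapsed
  before resampling and flagged by the validator.
* Multiple roots are accepted (tracing tools export forests); every
  operation works per connected component.
* Compartment classification (gray matter / fiber tract / striatum) walks
  ancestor chains to subtree roots named by acronym in `CompartmentRoots`
  ("Isocortex", "fiber tracts", "STRd"), so alternative atlas versions
  load without code changes; ids are never hard-coded.
* Out-of-atlas cable is always reported in a named "unassigned" row, never
  dropped, and per-neuron totals include it by default.
* Layer-resolved rows are emitted as given by the parcellation; users
  should treat layer assignment as registration-sensitive since a few tens
  of µm of registration error moves cable across laminar boundaries.
* Problem sizes: the default synthetic brain is 240 × 80 × 240 voxels and
  the default cohort ten neurons of ~60–80 mm cable each — large enough
  that every code path (long-range branches, white matter, striatum,
  septal somata) is exercised, while a full cohort generation plus
  quantification completes in well under a minute on one core.

## Known limitations

* The exact endpoint semantics of other resampling implementations vary;
  totals computed here can differ from tools that anchor points at path
  vertices by up to ~1 point per path (the midpoint rule is the unbiased
  choice, and comparisons against externally computed totals should allow
  a ~2 % margin).
* Displacement-field inversion assumes the field is a contraction
  (‖∇d‖ < 1); violently folded fields are rejected rather than silently
  mis-inverted.
* The septal soma report depends on `septum_radius`; with a radius far
  larger than the inter-column pitch the "nearest two columns" become
  ambiguous for deep septa.
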