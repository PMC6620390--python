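# Methods

`sasmorph` re-implements, as a tested pipeline, the quantitative
morphometry workflow used in 3D FIB/SEM studies of cortical neuropil:
synaptic junctions segmented in an anisotropic voxel volume are reduced
to their synaptic apposition surface (SAS), measured, classified by
type, shape and postsynaptic target, counted inside an unbiased 3D
counting frame, and compared with partitioned chi-square contingency
statistics.  Because the original human transentorhinal-cortex (TEC)
image stacks are not publicly deposited, the pipeline is exercised on
(a) seeded synthetic neuropil volumes with known ground truth and
(b) the published count tables, re-entered as raw counts.

## The synthetic neuropil model

A scene is a dense uint16 label grid at the acquisition geometry of the
source study: 5 nm/pixel in-plane, 20 nm section thickness.  Objects:

* **Dendritic shafts** — capsules running roughly along x, radius
  110–140 nm, laid out on a jittered grid of the (y, z) cross-section
  with mild tilt.  A configurable fraction (default 0.5) is aspiny.
* **Spines** — cylindrical neck (radius 50 nm, length 150–250 nm) plus
  spherical head (radius 100–140 nm) grown from spiny shafts.  Every
  spiny dendrite receives at least one spine, so the spininess of a
  shaft is decidable from the volume itself.
* **Junctions** — shells of thickness *t* conforming to the target
  surface (sphere cap on heads, cylinder patch on necks and shafts).
  The PSD thickness encodes the type: at a 20 nm section pitch a thin
  (symmetric) density spans one section and a prominent (asymmetric)
  one two, so the defaults are *t* = 20 nm (SS) and 40 nm (AS) — the
  physical correlate the type classifier thresholds (default 30 nm).
  The in-chart footprint encodes the shape class: a full ellipse
  (macular), an ellipse minus a central hole of 0.42 of its radius
  (perforated), minus an 80° wedge reaching inward to 0.3 of the radius
  (horseshoe), or two disjoint patches (fragmented).

Default mixes are the control-group study conditions: AS:SS = 95:5;
target mix per type and shape mix per type taken from the published
control count tables.  SAS areas are drawn log-normally per shape class
(right-skewed, macular smallest and fragmented largest, matching the
published size ordering); the log-normal family is an assumption made
from the published frequency histograms, and is configurable.  Drawn
areas are clipped to what the carrying surface can hold (e.g. a head
cap cannot exceed ~1.35 head radii), so synthetic absolute sizes sit
below the human-tissue means; only the class structure, not absolute
size, is claimed.

Placement is rejection sampling against the already-painted volume:
an object is voxelised only into background voxels and rejected on any
overlap with a foreign object.  Under persistent crowding a junction's
footprint backs off geometrically (factor 0.7 every 10 failed attempts,
floored at 0.3 of the drawn area) so that dense scenes fill rather than
fail; the realised area is what enters the ground truth.  A hard retry
cap (default 500 attempts per object) turns impossible densities into
an explicit error.  Spines are kept wholly inside the stack (the head
plus a guard band must clear every face), so spine tracing chains and
the junctions they carry are unbroken; dendrites still cross the stack
borders, as real dendrites do.  All randomness flows through a single
`numpy` generator seeded from the config; identical configs give
voxel-identical volumes.  The voxelisation kernels are numba-compiled
single-pass loops; the first call in a fresh process compiles them
(a few seconds).

What the generator does **not** emulate: EM texture and membrane
contrast, segmentation errors, vesicles and boutons, somata, glia and
blood vessels, mitochondria, and realistic synapse spatial statistics
(density analyses are out of scope).  Passing recovery tests therefore
demonstrate correctness of the measurement/classification chain on
clean labeled geometry, not robustness to segmentation noise.

## SAS extraction and metrics

The SAS of a junction is taken as the mid-surface of its voxel slab:
voxel centers are projected onto the slab's principal (PCA) plane,
occupancy is rasterised at the in-plane pitch (5 nm), morphologically
closed with a 2-cell disk to bridge the 20 nm section-sampling gaps,
cleaned of sampling specks (< 32 cells) and pinholes (< 5000 nm²,
well below the ~100 nm-scale biological perforations), and the
per-cell mean offset along the normal — smoothed over a 5-cell window
to suppress section-quantisation roughness that would otherwise
inflate the area — is triangulated as a height field.  A
distance-transform ridge was considered for the mid-surface but is
degenerate on 1–2 voxel thick anisotropic slabs; the projection
mid-surface is robust there and exact for gently curved patches.

Metrics on the mesh: area = summed triangle areas; perimeter = summed
lengths of *all* boundary loops (holes add perimeter); curvature = RMS
orthogonal deviation of the surface from its area-weighted least-squares
plane divided by sqrt(area).  The curvature ratio definition is an
operationalisation chosen here: it is dimensionless, zero for flat
patches, invariant under rigid motion and uniform scaling, and grows
monotonically as a flat disk is isometrically bent (property-tested).
Tissue shrinkage: the processing shrinkage factor is an area ratio
p² = 0.933, so corrected areas are area/p² and corrected lengths
length/√p².  Mean PSD thickness is voxel volume / mid-surface area;
objects too small to measure are flagged indeterminate and excluded
downstream with a logged count.

## Shape classification

A fixed decision tree on mesh topology and boundary geometry:
≥ 2 edge-connected components → fragmented (multiplicity dominates,
matching the taxonomy's "no connection between them"); else ≥ 1
interior hole (a closed interior boundary loop; holes are counted via
the Euler characteristic, χ = V − E + F = 2 − 2g − b) → perforated;
else a deep boundary indentation → horseshoe; else macular.  The
indentation depth is the maximal distance from the convex hull of the
flattened outline to the outline, normalised by the equivalent radius
sqrt(area/π).  The original study classified shapes by visual
inspection; no quantitative horseshoe criterion exists to match, so the
threshold (default 0.3) is a declared operationalisation, configurable,
with generator horseshoes sitting at ratios ≥ 0.5 and voxelised macular
patches below 0.1.

## Target assignment and counting frame

The postsynaptic partner is the object with the largest voxel-face
contact area (ties → lowest ID).  Spine targets must trace
head → neck → shaft within the volume; a failed trace on a
border-touching spine yields "unknown", the same rule the source
protocol applied to truncated elements.  Shafts are split spiny/aspiny
by the presence of an attached spine neck *inside the volume* — a
truncated dendrite whose spines all lie outside would be misjudged, a
bias shared with the source method and documented rather than patched.
Contacts spanning head and neck are adjudicated by the larger contact
area (the original text does not specify a rule).

The counting frame is a rectangular prism with three acceptance faces
(at the axis minima, by convention) and three exclusion faces (at the
maxima), tested in that order: touching any exclusion face excludes the
object; otherwise touching an acceptance face or the interior counts
it.  Faces are finite rectangles — no infinite plane extensions, since
the source description mentions none; with exclusion tested first this
still counts each convex interior object exactly once under a tiling
(property-tested), and the tiling guarantee is claimed only away from
the outer border.

## Statistics

Omnibus 2×k Pearson chi-square with E_ij = T_i·T_j/T and no continuity
correction; partitioning into 2×2 tables (each retained category vs the
pooled others; an orthogonal sequential scheme is available behind a
flag) after discarding categories whose minimum *observed* count is
below 5 — keyed to observed counts exactly as the source applied it.
No multiple-testing correction by default (none was reported); raw
p-values are returned.  Size comparisons use Kruskal–Wallis (≥ 3
groups), Mann–Whitney U (2 groups) and Kolmogorov–Smirnov
(distribution shape) with scipy's midrank tie handling, withheld for
groups below a configurable minimum n (default 10).

The published count tables ship with the package as raw counts; the
reproduction report recomputes every percentage (to the printed one
decimal), the omnibus statistics and all retained partition shares from
those counts and flags any printed value inconsistent with its own
parenthesized count.  One such cell exists (the Alzheimer-group
symmetric-synapse macular percentage prints 92.5 where its counts give
110/119 = 92.4); the report flags exactly this cell.

## Problem sizes and recovery studies

Real stacks of this kind reach hundreds of µm³; voxelising those at
5×5×20 nm is out of desk-scale reach, so the package works with
~17 µm³ stacks (512×512×128 voxels, a 2.56 µm cube) and pools stacks
per analysis — mirroring
how the source study pooled 30 stacks across cases.  The
parameter-recovery study uses 15 stacks of ~134 synapses per replicate
(≈ 2010 synapses at 8 junctions/µm³, a packing-feasible density chosen
for the synthetic geometry; tissue density analysis is explicitly out
of scope) and 20 seeded replicates.  Each replicate is scored with one
combined chi-square goodness-of-fit (type + target + shape components
summed, df = 7) of classified proportions against the configured mixes.
On clean scenes the classifier chain recovers type, shape and target
for 100% of non-truncated synapses in every seed examined, so the
recovery test is essentially a calibration check of multinomial noise.

## Known limitations

* Curvature and SAS extraction are stated operationalisations, not
  reconstructions of the (unpublished) algorithms of the original
  toolchain; absolute SAS means of the human tissue are out of reach by
  construction and only ordering/inequality properties are asserted.
* The generator's geometric realism is limited (straight dendrites,
  spherical heads); it provides class structure and ground truth, not
  biophysics.
* Junction footprint back-off under crowding biases realised sizes
  downward in very dense scenes.
* The spininess call and the unknown-target rule inherit the border
  biases of the source method by design.
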