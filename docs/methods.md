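# Methods

This note records the models, numerical choices and open design decisions
behind `leafatlas`, and what the synthetic-data tests do and do not
demonstrate about real digitizer data.

## Input model and raw meshing

A digitized leaf is an ordered grid: `n` transects of 5 points each
(left → right, perpendicular to the midvein, base → tip) plus a single
tip point, `5n + 1` points total, coordinates in centimetres. Column 0 is
the left margin, column 2 the midvein, column 4 the right margin. Files
with a row count not of this form, fewer than two transects, or exactly
coincident points are rejected.

The acquisition protocol does not prescribe a triangulation, so the raw
mesh is built deterministically: each quad between consecutive transects
is split along its lower-left → upper-right diagonal (consistent
orientation), and the tip is joined to the last transect by a 4-triangle
fan, giving `8(n−1) + 4` faces and disk topology with a single boundary
loop. The fixed diagonal is chirality-breaking: a mirrored leaf produces
a combinatorially different mesh, so left/right feature pairs swap only
approximately (to ~0.1% for lengths and areas, a few percent for
turning-angle sums). This is an accepted artefact of deterministic
meshing.

## Replicate screening

Four per-sample features (midvein length, maximum transect width, their
ratio, and the mean adjacent-face normal angle — the same statistic as
the folding feature FA) are min-max scaled to [0, 1] over the whole
dataset so the screening margin is dimensionless. Within a 3-replicate
line, a sample whose scaled Euclidean distances to both siblings exceed
the siblings' mutual distance by more than 0.1 is excluded; 1- and
2-sample groups are never screened. The margin, the scaling, and the
one-vs-rest reading of "similarity difference" are the documented
operationalization of an informally stated rule; the threshold is
configurable.

## Normalization

Principal axes from the vertex SVD map to x/y/z by descending variance.
Sign ambiguities are fixed deterministically: tip at positive x, the
base left-margin vertex at positive y, z completing a right-handed
frame. The centroid moves to the origin and coordinates are divided by
the maximum absolute coordinate, so the mesh fills [-1, 1] with equality
attained; the inverse scale is carried as `scale_to_cm` so every length
feature is reported in centimetres. A near-collinear vertex cloud
(second singular value below 1e-12 of the first) is rejected.

## sqrt(3) subdivision

Per iteration: one vertex at each face centroid joined to the face
corners, every interior original edge flipped to the centroid–centroid
diagonal, and interior original vertices relaxed by
`p' = (1−α_n) p + (α_n/n) Σ neighbours` with
`α_n = (4 − 2 cos(2π/n))/9`. Boundary vertices are held fixed and
boundary edges never flipped: margin fidelity matters more for leaf
contours than limit smoothness at the boundary, so the scheme's special
boundary refinement is deliberately omitted. Faces triple per iteration
(9x after the standard two); original vertex indices and role tags are
preserved, which is what lets width features find the digitizer
transects after refinement. Planar meshes stay exactly planar (all steps
are affine combinations), and surface area drifts by well under 5% per
iteration on leaf-like geometry.

## ARAP planar flattening

Energy: `E(u, L) = Σ_t A_t ‖J_t(u) − L_t‖²_F` with `A_t` the 3D triangle
area and `L_t` constrained to 2D rotations. Each triangle is expressed
in an isometric 2D reference frame obtained by projecting a fixed global
axis into the triangle plane (falling back to a second axis where the
normal is nearly parallel). Aligned frames mean a planar mesh maps to
itself with `J_t = I`, which makes the identity-rotation global step
reproduce planar inputs exactly — a property used by the tests.

* **Initialization**: least-squares conformal map with the two most
  distant boundary vertices pinned at their geodesically honest
  separation; fallback to principal-plane projection if the conformal
  solve fails or inverts triangles. Rotations start at the identity.
* **Local step**: closed-form nearest rotation,
  `θ = atan2(J21 − J12, J11 + J22)` — the exact 2D polar projection, so
  the energy cannot increase.
* **Global step**: with rotations fixed the x and y coordinates decouple
  into two least-squares problems sharing one sparse normal matrix,
  factorized once per mesh; one vertex is pinned to remove the
  translation nullspace and the solution re-centred. Exact minimization,
  so again monotone.
* **Stopping**: relative energy decrease below 1e-6 or 200 iterations
  (meshes are ~10³ faces; both limits are cheap). Hitting the cap is
  reported, not fatal.
* **Canonical output**: PCA re-orientation of the 2D map, tip → +x, left
  margin → y > 0 (this rule also undoes a globally reflected solution),
  centroid at the origin.

The distortion report carries total and per-face 2D/3D area ratios and
the per-face Frobenius residual. On developable inputs (pure midvein
bend) the flattening recovers the analytic unrolling: area ratio 1 to
within 1e-3. On the synthetic population with folds and twist the ratio
stays within (0.990, 1.000).

Fold visualization paints the 3D per-face fold angle (mean
absolute-dot-product angle to edge-neighbour normals, range [0, π/2]) on
the flattened layout with a blue-to-red colormap.

## Contour model

Boundary edges (incident to exactly one face) are chained into the
single closed loop and oriented counter-clockwise. 600 rays from the
origin (the pinned mesh centroid) are intersected with every boundary
segment; the **farthest** intersection is kept, yielding the outer
silhouette — the nearest would clip marginal serrations inward. Ray
count 600 resolves the tip and base, which lie far from the centre.
Degenerate rays grazing a vertex use an inclusive segment test with
tolerance 1e-12. Averaged models are point-wise means at each ray index
(well-defined because every contour shares the ray directions), grouped
by line or over all leaves.

The six contour sectors are defined on the wrapped ray angle: tip
|a| ≤ 15°, base |a| ≥ 165°, the left half split at 90° into upper
(tip-ward) and lower, mirrored on the right. The 15° half-angles and the
90° split are configurable constants chosen to give the tip and base
narrow dedicated sectors; the half-open bounds assign every sampled
point exactly once (the 90° ray belongs to the upper sector).

## Features

All 17 mesh features are measured on the flattened leaf except FA/FV,
which are 3D-surface properties (they vanish identically on any planar
mesh — asserted in the tests as a guard against computing them on the
wrong mesh). Conventions that the source tables leave open:

* Offset angles (LOA/ROA/MOA) sum **absolute** exterior angles: a signed
  sum would cancel alternating wiggle, and total wiggliness is what the
  feature is meant to capture.
* Tortuosity (MTA/MTV) uses unsigned angles between each midvein segment
  and the base-to-tip chord.
* Variances (WV, MTV, FV) use the population convention (divide by N):
  these are shape descriptors, not estimators.
* Widths are measured between the left/right margin vertices of each
  original digitizer transect, tracked through subdivision by role tags,
  rather than re-sliced against a fitted midvein: deterministic, and
  perpendicular to the midvein by construction of the acquisition grid.
  WP ties resolve to the station nearest the base.
* RLP is implemented symmetrically to LLP (its table row is missing but
  the width combination references it — a clear typo).
* The tip angle uses the two boundary vertices adjacent to the tip on
  the (subdivided) mesh.

The identities `LWR = ML/WA`, `LW = L/W`, `UL = UP − LP` hold exactly by
construction, and the whole vector is dimensionally covariant: uniform
2x scaling doubles lengths, quadruples areas, fixes angles and ratios.

## Semantic model, weights, atlas, identification

Feature redundancy is pruned by average-linkage hierarchical clustering
on the correlation distance `1 − r`, cut at 0.25; each cluster is
represented by its medoid (smallest mean intra-cluster distance) — the
representative rule is a package choice, and an override lets users
force a fixed feature list such as the 11-feature reference set
(WP, LWR, L, LTA, WV, W, FA, MTV, MTA, LOA, ROA).

Because the features mix cm, cm² and rad, semantic vectors are min-max
standardized to [0, 1] over the atlas population before weighting,
cosine similarity, and L2D; queries are clipped into the atlas range.
This makes `L2D = Σ w_i f_i` (weights ≥ 0, summing to 1, raw values on
the grid {0, 0.5, …, 3}) a [0, 1] index that grows monotonically as
every trait becomes more pronounced. The weighted *sum* is implemented
as the primary definition with the Euclidean modulus of the weighted
vector available as an option — the two readings coexist in the field
and the sum is the more precise statement.

The greedy weight search scores each candidate raw weight (7 grid
values per feature, others held at 1) by the mean of Top-1 … Top-10
leave-one-replicate-out accuracy: each leaf of a multi-replicate line
queries a gallery of per-line means with itself removed from its own
line's mean, so self-matching cannot inflate the objective; ties go to
the smaller weight. Lines with a single replicate are never queried.
The per-feature winners are assembled and normalized to sum to 1.

Identification ranks lines by cosine similarity between element-wise
weighted vectors; ties break by line id. Semantic lookup returns the
top entry (with its averaged contour, for drawing) only when the
similarity reaches the 0.9 match threshold, otherwise the queried shape
is declared absent from the population.

## Synthetic leaves and populations

The generator builds an arc-length parameterized midvein with constant
curvature in the vertical plane (ear leaves arch downward), places 5
points per station across a lanceolate width profile
`w(t) ∝ (t₀+t)^a (1−t)^b` (positive at the base, vanishing at the tip,
maximum at a controllable `widest_frac`), applies cumulative twist,
sinusoidal margin waves on the edge columns (phase drawn from the leaf
seed), and a transverse cosine fold field with a Gaussian envelope
centred at 30% of the blade — echoing the observed concentration of
folds in the lower-middle region of real ear leaves. Transects sit at
fractions `t/n` so the last keeps positive width; the tip terminates the
midvein at full length. With all deformations zero the grid is exactly
planar; with bend only, the surface is developable and the ARAP
unrolling is exact — both serve as oracles.

Population defaults: 100 lines x 3 replicates; line-level parameters
uniform over length 60–105 cm, width 6–12 cm, widest position 0.30–0.50,
bend 0.005–0.045 rad/cm, twist ±0.3 rad, wave amplitude ≤ 0.4 cm, fold
amplitude ≤ 2% of width — magnitudes a field digitizer campaign on
silking-stage ear leaves would plausibly produce, with transect counts
following leaf length at ~5 cm probe spacing (66–91 points). Replicates
jitter each line parameter by a Gaussian with σ = 0.15 of the parameter
range, keeping within-line spread well below between-line spread, as in
a real inbred panel. Every leaf's generator is seeded from
(master seed, line, replicate), so populations are bitwise reproducible.

What the synthetic suite does **not** show: real digitizer noise
(probe slip, operator variation), serrated or damaged margins,
asymmetric width profiles, or the specific feature correlation
structure of any real panel. Identification accuracies measured here
characterize the machinery on a population whose separability is
controlled by construction, not any real panel's accuracy; only the
structural properties (self-query Top-1 = 1, monotone Top-X, weighted ≥
unweighted, chance-level dominance) and the area-preservation band
transfer as claims about the method.

## Problem sizes and runtime

Default test problem sizes — 50-leaf single-replicate population for
the area-ratio band, 100 lines x 3 replicates for selection, weights and
identification, 30 leaves for parameter recovery — run the full suite in
under two minutes on one CPU; the package scales to hundreds of lines
linearly in leaf count (each leaf: one sparse factorization of ~500
unknowns and ≤ 200 back-substitutions).

## Known limitations

* The flattening assumes disk topology; torn or overlapping blades are
  rejected rather than seam-cut.
* Screening presumes at most 3 replicates per line, per the acquisition
  design.
* The greedy weight search optimizes each feature independently around
  the all-ones vector; it is not a joint optimum (by design — it mirrors
  the enumerate-and-fix procedure appropriate for small samples).
* Contour sector bounds are fixed angles; extremely asymmetric leaves
  whose centroid shifts far toward one margin may place unexpected
  boundary points in the tip/base sectors.
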