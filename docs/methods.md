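# Methods

## Geometry and coordinate conventions

Arrays are indexed `[ix, iy, iz]` with X = lateral (LAT), Y =
anterior–posterior (AP), Z = superior–inferior (SI); the phantom cylinder
axis is Z. Coordinates are voxel-center based (`position = origin +
index × spacing`) and a voxel belongs to a region iff its center is
inside. For the cylinder and the avoidance prisms inclusion is strict on
the "upper" face (half-open intervals): the 30 cm × 18 cm phantom puts
voxel centers exactly on its faces at 2 and 4 mm spacing, and the
half-open convention keeps the voxel count an unbiased volume estimator
(a closed test double-counts grid-aligned faces, +2 % at 2 mm).

The lattice has `counts` (default 3×3×3) spherical vertices of diameter
*d* at center-to-center pitch *d + s*, with *s* the edge-to-edge
separation. Centers are ordered Z-major, then Y, then X. Derived ROIs:
coreballs (concentric, diameter *d*/2 — empty at coarse spacing when the
radius is sub-voxel), the avoidance prisms (bounding box of the vertex
union expanded 1.0 cm per face, minus the vertices; both named prisms use
the same geometric rule since they differ only by optimizer objectives
that a planning system would attach), and Eval_Normal. For normal-tissue
metrics Eval_Normal excludes both the prisms and the vertex spheres: the
vertices are tumor surrogates, and leaving them inside would make the
≥10 Gy intersecting volume trivially equal to the whole vertex union.
Without vertex masks the function returns the plain set difference
phantom ∖ prisms.

The default grid spacing is 2.0 mm (1.0 mm available) — a deliberate
trade of sub-millimetre accuracy for desk-scale runtime; the convergence
tests guard the discretization error.

## Synthetic dose model

The study's dose grids come from a commercial optimizer and are not
deposited, so the pipeline runs on phenomenological stand-ins:

```
D(x) = peak · max( max_k K_k(x), max_t T_t(x) ) + bath
```

- **Vertex kernels** `K_k`: 1 inside the sphere, Gaussian falloff
  `exp(−(dist − r)² / 2σ²)` outside (σ = `penumbra_sigma`, default 3 mm).
- **Corridor tubes** `T_t` connect the 54 axis-adjacent vertex pairs
  (6-neighborhood only, matching the three analyzed profile directions):
  flat amplitude out to the vertex radius, the same Gaussian edge
  falloff beyond. The flat core is essential: a purely Gaussian tube of
  scale σ would decay to a few percent at the edge of the valley search
  cylinder, and the extracted valley minimum would always sit at the
  region edge near the bath level, decoupling VPDR from the corridor
  amplitude.
- **Amplitude decay**: the per-axis amplitude is scaled by
  `exp(−(gap − 20 mm)/60 mm)` (capped at 0.95), so valleys deepen as the
  separation grows — the dominant trend in the measured sweep. The 20 mm
  reference gap pins the presets to the 2.0 cm separation rows of the
  published comparison.
- **Bath**: `background + scatter_fraction · peak · V_struct/V_phantom`,
  with `V_struct` the analytic vertex + corridor volume. The scatter term
  makes the Eval_Normal mean dose grow with vertex diameter and
  separation, as measured.
- **Noise**: voxelwise multiplicative `(1 + ε)`, ε ~ N(0, σ_n), clipped
  at −1, seeded; default σ_n = 0.02. Spatially independent — the
  simplest model that produces nonzero profile-to-profile SDs.

Structures combine by voxelwise maximum so every local dose maximum stays
inside a vertex, as the extraction assumes. Prescription normalization
uniformly rescales the field so the median dose over the pooled vertex
voxels (D50%) equals 20.0 Gy.

Delivery-mode presets (a calibration to the reported directional VPDR
ranges, not physics): coplanar corridor amplitudes (0.40, 0.40, 0.12) for
(X, Y, Z), non-coplanar (0.25, 0.25, 0.25). At the representative
configuration (d = 1.5 cm, s = 2.0 cm) these land at ≈ 38/38/15 % vs
≈ 26/26/26 %. The penumbra σ default of 3 mm keeps the inter-vertex
penumbra overlap at 1.0 cm separation (≈ 0.21 of peak, worst case) below
every preset amplitude; at 4 mm the overlap (≈ 0.46) would flood the
corridor signal and the two modes would become indistinguishable at the
smallest separation.

### What the generator does and does not emulate

It reproduces the *structure* the analysis consumes — 27 flat-core
peaks, axis-dependent corridor valleys, separation trends, a dose bath,
profile-level variability — and therefore supports qualitative claims:
directional ordering, significance patterns, CV contrast between modes,
monotone trends, recovery of the generating anisotropy. It does not model
beam transport, MLC segmentation, or optimizer behavior, so absolute
valley doses, the measured SDs (which fold in optimizer variability), and
normal-tissue hot-spot spill are not reproduced; in particular the ≥10 Gy
isodose stays inside the 1 cm avoidance prisms, so the synthetic
intersecting volume is ~0 nearly everywhere, unlike the measured values
for 2.0 cm vertices. Statistics tied to those absolute values are
computed from the packaged reference tables instead. Passing tests on
synthetic fields validate the pipeline's correctness and the mechanism's
direction, not planning-system dosimetry.

## VPDR extraction

Per direction, each of the nine lattice lines contributes one profile:
the per-vertex dose maxima (argmax over the vertex mask) and the minima
of the two inter-vertex regions. The inter-vertex search region is a
finite cylinder between the facing sphere boundaries — projection onto
the center-connecting segment strictly between boundaries, perpendicular
distance ≤ vertex radius (a `lateral_radius_mm` option narrows it toward
a line search). The cylinder cross-section is a choice: the width of "the
region between two vertices" is not fixed by the measurement description,
and a full-radius cylinder is robust to off-axis minima, consistent with
extraction that does not assume collinearity. Argmax/argmin ties break to
the lowest linear voxel index for bit-reproducibility.

The five anchors (peak–valley–peak–valley–peak, generally non-collinear)
are joined into a polyline, resampled at 101 uniform arc-length stations
with trilinear interpolation, and each anchor's exact dose overwrites its
nearest station — so the profile statistic is independent of resampling
density. Per profile, `VPDR = 100 · min(valleys) / max(peaks)`, giving
nine values per direction; per-gap ratios would give eighteen and are not
what the per-profile definition implies.

## Statistics

Directional uniformity is `CV = 100 · SD / mean` across the three
directional mean VPDRs, with the sample SD (n − 1): that convention
exactly reproduces both published bounds (3.4 % and 17.1 %). Pairwise
direction comparisons use the classical pooled-variance two-sample t-test
(Welch optional), with conventions p = 1 / p = 0 for degenerate
zero-variance samples with equal/unequal means. Multiplicity is handled
by Bonferroni: α = 0.05/60 for 3 pairs × 20 configurations. Reported
precision follows the published tables: 1 decimal for VPDR/CV, integers
for percent increases.

## Modulation complexity score

The MCS combines leaf-sequence variability (LSV) and aperture-area
variability (AAV), both in [0, 1], with 1 = least modulated. Per control
point and bank, `LSV = Σ (pos_max − |p_n − p_{n+1}|) / ((N−1) · pos_max)`
over the leaf pairs open anywhere in the arc (a zero-spread bank
contributes 1), and the control-point LSV is the product over the two
banks. `AAV` is the control point's summed leaf-pair aperture divided by
the arc's maximal per-leaf aperture envelope. Per arc, adjacent
control-point pairs are averaged and weighted by their MU share; a
single static rectangular aperture scores exactly 1. The plan-level
default is the MU-weighted mean over arcs (an unweighted mean is
exposed). Leaf geometry defaults to the Millennium 120 layout (60 pairs:
40 central at 5 mm, 20 outer at 10 mm).

The synthetic plan generator produces four arcs with the study's
couch/gantry/collimator geometry; a complexity level in [0, 1] blends a
smooth per-bank traveling wave (positional spread with small neighbor
differences) with leaf-by-leaf jitter and per-control-point aperture
breathing. Pure i.i.d. jitter alone would leave LSV scale-invariant; the
fixed smooth component is what makes MCS strictly decreasing in the
level. The scaling is calibrated so mid-range levels (0.25–0.75) land in
the reported 0.28–0.47 clinical band.

## Problem sizes and reproducibility

The default sweep runs 20 configurations × 2 modes on the 2 mm phantom
grid (151×151×91 voxels); per-structure computations are restricted to
tight bounding boxes, so a configuration takes well under a second and
the full sweep well under a minute. Sweep determinism: each
configuration's noise seed derives from a `SeedSequence` spawned from
(sweep seed, mode, diameter, separation), and report CSVs are written
with fixed float formatting, making same-seed reruns byte-identical. The
anisotropy-recovery study uses 20 seeded replicates of the representative
configuration and inverts measured VPDRs through the field model
(`A ≈ VPDR/100 · (1 + f) − f`, f = bath/peak) to classify the SI vs
transverse corridor ordering.

## Known limitations

- The dose model is phenomenological; no claim about absolute dosimetry.
- Valley SDs across the nine profiles are small (the extraction minimum
  concentrates), so synthetic per-direction SDs undershoot measured ones.
- Masks are binary voxel sets; small spheres at coarse spacing carry
  discretization bias (e.g. +24 % volume for r = 10 mm at 4 mm spacing),
  guarded by convergence tests rather than removed.
- Only Bonferroni multiplicity control and independent-sample tests; no
  modeling of within-configuration profile correlation.
- No DICOM RT import/export; plan summaries are JSON/CSV-level objects.
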