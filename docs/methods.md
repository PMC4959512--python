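# Methods

## Scope and model

`etsim` simulates the room-temperature, plastic-section ET workflow:
semi-thick (default 275 nm) sections imaged in projection over a limited
tilt range, aligned on colloidal-gold fiducials, reconstructed by
weighted back-projection (WBP), optionally combined across two
orthogonal tilt axes, and quantified by virtual reslicing, meshing, and
closed-form sectioning stereology.  Contrast is idealized linear
density: a projection is the straight line integral of the density
volume along the beam.  There is no electron-optics model — no CTF,
multiple scattering, or detector physics — so tests of the pipeline
measure geometry and reconstruction algebra, not imaging physics.

### Conventions

* Units are nanometres throughout; micrometre CLI inputs are converted
  at the boundary (`50um` → 50 000 nm).
* Volumes are arrays indexed `[z, y, x]`; z is the beam direction at
  zero tilt and the section-thickness axis.  The voxel with index `i`
  is centred at `origin + (i + 0.5)·voxel`.
* Axis A tilts about the image y axis.  A point at centred physical
  coordinates (x, z) projects to detector coordinate
  `x' = x·cos θ − z·sin θ`.  Axis B is realized by physically rotating
  the specimen 90° in-plane (an exact array quarter-turn), not by a
  second holder model.
* Overlapping phantom primitives sum their densities, matching linear
  projection physics.

## Phantoms

Primitives (solid cylinders, hollow tubes, boxes, spheres) carry
closed-form volume and surface area, so every downstream measurement has
an exact oracle.  Rasterization samples occupancy on a 2×2×2
supersampled grid per voxel and averages, keeping sub-voxel membranes
(tube walls thinner than one voxel) representable; rasterized volume
converges to the closed form within 2% once the voxel is ≤ r/10.
Organelle densities are free parameters (they are not physically
calibrated anywhere); defaults are order-1 contrasts.

Fiducials are spheres centred exactly on the two section surfaces.
Their default density is 25× the maximum structural density: what makes
gold trackable is that its *projection* dominates locally, and a 15 nm
bead must outshine a 100+ nm column of stained structure along the beam.
Beads are placed ≥ 1 diameter apart, and optionally so that every pair
stays ≥ 1.5 diameters apart *in projection* across the ±60° sweep — two
beads on opposite surfaces with similar x-y positions cross in
projection at some tilt and cannot be tracked apart; a microscopist
selecting trackable markers applies the same resolvability criterion.
The standard experiments use this placement with 6 beads: alignment
needs only ≥ 3 tracks, and since every erased marker footprint destroys
the structure beneath it, more markers actively reduce structural
fidelity.

## Acquisition simulation

The forward projector rotates the volume in the z–x plane (bilinear
interpolation, zero padding) and sums along z; images are voxel sums, so
total projected intensity is conserved to interpolation tolerance.
Beam-induced drift is modelled as iid Gaussian per-image shifts (nm),
in-plane rotations (deg), and a cumulative isotropic shrinkage
(≤ 1%/image), all seeded and logged as alignment ground truth.  Counting
noise is Poisson at a stated mean dose per pixel (images are scaled so
the series mean maps to the dose, sampled, and scaled back).

Image warps apply pure translations as padded Fourier shifts (exact,
no interpolation loss) and rotations/magnifications by cubic B-spline
resampling.  Cubic rather than bilinear because the perturb-then-align
round trip resamples every image twice and the doubled bilinear blur
measurably degrades downstream reconstruction fidelity.

## Fiducial alignment

Detection is Laplacian-of-Gaussian blob detection at the bead scale
followed by an iterative Gaussian-weighted centroid on a band-passed
(difference-of-Gaussians) patch; the band-pass removes slowly varying
structural background under the window, and the iterated re-centred
weights remove window-truncation bias (≈ 0.05 px on clean spots).

Tracking links detections across adjacent tilts by nearest neighbour to
a constant-velocity prediction within a gate.  Linking runs in
drift-corrected coordinates — the inter-frame translation estimated by
phase correlation is subtracted first — because iid per-image shifts
otherwise defeat the constant-velocity prediction.  A track may bridge
one undetected image; longer gaps split it.

The solver alternates linear least squares for each bead's 3D position
with per-image restricted Procrustes fits (shifts only by default;
shifts+rotation; shifts+rotation+magnification), to 1e-4 px RMS change
or 100 iterations.  Per-image estimation is robust (component-wise
median for shifts; observations > 3× the median residual dropped), and
tracks whose own reprojection RMS is far above the median are discarded
and the model refit — this rejects tracks corrupted by identity swaps.
`align_series` additionally iterates model-guided reassignment:
fragmented tracks leave the least-squares system with near-singular
drift modes (we observed 7 px shift errors at 0.26 px residual), so the
solved 3D beads are reprojected into every image, detections near the
predictions are reclaimed into full-length tracks, and the model refit.

**Gauge freedom.**  Translating the whole bead model by (ΔX, ΔY, ΔZ)
changes predicted detector positions by (ΔX cos θ − ΔZ sin θ, ΔY) —
exactly absorbable into the per-image shifts.  No fiducial method can
recover that component.  The solver canonicalises to minimum-norm
shifts (the cos/sin component of x-shifts and the mean of y-shifts are
moved into the bead coordinates), and all recovery comparisons are made
in this gauge; rotations are compared after removing the analogous
constant offset.

Before reconstruction the solved beads are erased from the aligned
images (a disc of 1.2× the bead radius filled with the annulus median),
optionally restricted to beads whose solved |Z| lies at the section
surfaces so that structural features mistakenly tracked as markers are
left untouched.  Without erasure the dense markers streak through the
tomogram and fidelity metrics measure marker artifacts, not structure.

## Reconstruction and dual-axis combination

WBP ramp-filters each image along x (frequency response 2|f|, optional
raised-cosine rolloff, default none) and smears it back along its beam
direction with the adjoint of the forward projector, scaled by
π/(2·n_angles); a dense ±90° sweep then reproduces density values, and
a per-slice cross-check against scikit-image's filtered back-projection
agrees at r ≥ 0.95.  Dual-axis combination averages the two Fourier
transforms with coverage-indicator weights (one axis → that axis; both
→ mean; neither → zero).  A frequency direction is covered by a sweep
when some beam orientation is orthogonal to it: |atan2(|k_z|, |k_x|)| ≤
θ_max for axis A, with k_y in place of k_x for axis B.  Coverage
reports give the closed-form planar fraction (tilt range / 180°; the
second axis adds only a measure-zero line in the x–z plane) and a
seeded Monte-Carlo 3D direction fraction.

PSF elongation is the z/x ratio of full-width-half-maximum profiles
through a reconstructed bead's maximum.  Fidelity is Pearson
correlation inside the section mask (|z| ≤ thickness/2, 5-voxel border
excluded).  Both are orientation-sensitive diagnostics of the missing
wedge: structures running along z (the T-tubule geometry this workflow
follows through the section) reconstruct at r ≥ 0.9 under a ±60° sweep,
while an in-plane cylinder caps near 0.8 because its edge spectrum
falls inside the wedge.  The standard fidelity phantom therefore uses
section-spanning z-oriented tubes — which is also the biologically
canonical orientation — with the section thickness matched to the tube
length so the mask contains structure everywhere.

## Reslicing and stereology

Slices average over the slab thickness (so homogeneous media give
thickness-independent intensity) on an in-plane grid at the volume's
voxel size; axis-aligned extraction reduces to grid indexing.  Masks are
cut at half-maximum above background (parameter-free for synthetic
contrast), reduced to the largest connected component, and fitted with
moment-based equivalent ellipses.

The identification model treats the cutting angle α (plane vs filament
axis) as uniform on [0°, 90°]; p = arcsin(d/l_req)/90°, equivalently
(90° − arccos(d/l_req))/90° — the cutting angle divided by 90°.  This is
*not* an isotropic 3D orientation model; it is the implicit
one-angle model of the worked examples, and reproduces both printed
values (0.03% for a full-length 50 µm microtubule of 20 nm diameter;
12.8% for a 5:1 aspect).  Reported percentages use two decimals below
0.1% and one decimal otherwise.  A seeded Monte-Carlo oracle (uniform
angles, apparent major d/sin α) validates the closed form to 3 standard
errors across aspect ratios 1–2500.  Section-thickness truncation of
the visible length is deliberately ignored, matching the model's
assumptions.  The sub-volume budget is exact arithmetic: whole cell =
product of cell dimensions; representative wedge = axial period ×
wedge fraction × cross-section area.

## Meshing

Contour stacks are resampled to 64 boundary points per polygon by arc
length, matched across planes by footprint overlap (nearest centroid
with a logged warning when footprints do not overlap; a polygon left
unmatched starts a new chain, so branching yields multiple closed
components), stitched with triangle bands after cyclic alignment, and
fan-capped at chain ends — watertight by construction for simple
stacks; fan caps assume star-shaped end contours.  Isosurfaces use
marching cubes at a user threshold strictly inside the data range.
Volume is the absolute signed-tetrahedron sum (watertight meshes only),
area the triangle-area sum; both are rotation/translation invariant to
1e-9 and cross-checked against trimesh.  Smoothing is Taubin
shrink/inflate with the pass-band condition 1/λ − 1/ν = 0.05; at the
default (λ = 0.5, 10 iterations) sphere volume drifts < 0.1%, well
inside the ≤ 1% contract.  End-to-end, rasterize → isosurface → measure
recovers analytic volumes within 3% and areas within 5%.

## Problem sizes and determinism

The validation experiments run at desk scale by choice: fidelity on a
96³ phantom with the full ±60°/1° (121-image) schedule; the 20-trial
shift/rotation recovery on analytically rendered Gaussian-bead series
(160², 31 angles) — alignment accuracy is a property of the solver and
bead geometry, not of volume size; oblique-section geometry on a 128³
rasterized 200 nm tube; coverage Monte-Carlo at 10⁶ directions.  Every
stochastic step takes an explicit seed (NumPy `default_rng`), and every
CLI run with fixed seed and inputs is byte-reproducible.

## What passing tests do and do not show

The generator emulates geometry, acquisition kinematics, and counting
noise — not stained-section texture, CTF, beam-induced nonuniform
deformation, or segmentation ambiguity on real contrast.  Passing tests
therefore demonstrate that the geometry, alignment algebra,
reconstruction operators, and quantification are correct and
self-consistent at the stated scales; they do not certify performance
on real micrographs.  Known limitations: marker-free alignment is out
of scope; no iterative reconstruction (SIRT/ART); the dual-axis merge
is a coverage-weighted average without residual warping; fan caps
require star-shaped end contours; the stereology model ignores section
thickness.
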