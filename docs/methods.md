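# Methods

## Model

The segmentation is an implicit active surface: the tumor boundary is the
zero level set of a scalar field φ(x) defined on the image grid, negative
inside, evolved by the normal-speed law ∂φ/∂t + F|∇φ| = 0 with the hybrid
speed

    F = α·S_e + β·S_r + γ·S_s,        α + β + γ = 1.

The model assumes a single connected target whose interior is
distinguishable from its surroundings by mean intensity (the region term)
and/or bounded by intensity edges (the edge term), imaged with roughly
stationary noise. It is a single-label method: one component (enhancing
lesion, necrotic core, or edema) per run.

### Term definitions and normalization

* **Edge term** `S_e = 1/(1 + (|∇(G_σ*I)|/c)²)` with σ = `edge_scale`
  (default 1 mm) and contrast scale `c`. By default `c` is the **median
  smoothed-gradient magnitude over the whole volume** — the flat-tissue
  noise floor. Real boundaries and strong intratumoral texture, several
  times that level, then register as S_e ≈ 0. A seed-local scale was
  rejected: it calibrates to whatever texture the seed sits in, which
  blinds the edge term to exactly the edges it must stop at.
* **Region term** `S_r = [(I − c_out)² − (I − c_in)²]/(c_in − c_out)²`,
  clipped to [−1, 1]. The `(c_in − c_out)²` scale makes S_r exactly +1 at
  interior-mean intensity regardless of outlier voxels; normalizing by the
  maximum of the raw force instead lets a small dark necrotic core or a
  few noise spikes deflate the force everywhere (observed: front stall and
  collapse at the recommended weights). `c_in`/`c_out` are recomputed
  every iteration over an analysis region — the interior bounding box
  dilated by 16 voxels — so distant anatomy does not bias `c_out`; S_r is
  zero outside that region.
* **Smoothing term** `S_s = −κ`, κ = div(∇φ/|∇φ|) (positive for a convex
  interior), ε-regularized (ε = 1e−8 in quadrature) and clamped to
  |κ| ≤ 1/h_min — curvature beyond the grid scale is not resolvable, and a
  larger clamp lets γ crush the one-slice initial slab before the region
  force can round it into 3D.

### Discretization

All finite differences use physical (mm) spacing, so anisotropic voxels
are handled. Per iteration:

* the **edge term** is Godunov-upwinded on the sign of the local speed;
* the **region term** is applied as the variational two-phase force,
  φ ← φ − dt·β·S_r, with no gradient factor. At a reinitialized front
  |∇φ| = 1, so the front's normal speed is β·S_r, identical to the
  hybrid-speed form; away from the front the direct force lets the model
  seize detached interior-like regions. (A strictly upwinded F|∇φ| is
  exactly zero at any local minimum of φ — it can *never* create an
  isolated component, which contradicts the region-dominant behavior this
  tool is meant to reproduce.)
* the **curvature term** uses central differences on |∇φ|.

The time step is `dt_safety` (default 0.5) times the smaller of the
hyperbolic bound h_min/max(|speeds|) and the parabolic bound h_min²/(6γ),
so no iteration moves the front more than one voxel.

### Reinitialization

Every `reinit_interval` (default 20) iterations, and once at the end, φ is
restored to a signed Euclidean distance. Inside a narrow band
(`band_width` = 8 voxels) the distance is exact: the zero crossings are
linearly interpolated along grid axes, face diagonals and cube diagonals
(13 edge directions — dense enough that nearest-point "scallop" error
stays below 0.1 voxel), and band voxels query the crossing cloud through a
k-d tree. Outside the band a voxelized Euclidean distance transform is
used. This keeps the front displacement under half a voxel, makes the
operation idempotent to ~0.03 voxel, and restores |∇φ| ≈ 1 in the band
(away from the interior medial axis, where any distance function kinks).
The 20-iteration interval (rather than a more aggressive 10) matters for
the two-phase far-field behavior: each full reinitialization resets φ at
detached candidate regions to true distance, so the region force needs a
full cycle of uninterrupted integration to pull a look-alike lesion
through zero.

### Initialization and convergence

The user's polygon (≥ 3 vertices, simple, on one slice) is rasterized by
pixel-center membership with boundary ties counted as interior, and φ0 is
the signed 3D distance to that one-slice slab — the front then lies midway
between opposite-sign voxel centers, so the seed slice reproduces the
rasterization exactly and the adjacent slice starts at dz/2. Out-of-plane
growth is driven purely by the speed terms (with `use_3d = False`, growth
is clamped to the seed slice).

The run stops early when the relative interior-volume span over a trailing
window of 30 iterations falls below `convergence_tol` = 1e−3. The window
spans 1.5 reinitialization cycles deliberately: a volume plateau shorter
than one cycle cannot distinguish true convergence from a pending
far-field zero crossing. A vanished interior is reported as
`collapsed = True` (never an exception), so parameter sweeps record it as
an outcome. Interior voxels touching the volume boundary are clamped back
to exterior with a warning.

## Parameters that matter

| parameter | default | units | why |
|---|---|---|---|
| α, β, γ | component preset | – | regime selection; β ≥ 0.5 for edema, γ ≤ 0.3 always (violations warn, never fail) |
| edge_scale (σ) | 1.0 | mm | gradient pre-smoothing; ~noise correlation length |
| contrast_scale (c) | volume-median gradient | intensity/mm | S_e = 0.5 at this gradient |
| max_iterations | 300 | – | desk-scale budget; runs usually converge in 100–250 |
| dt_safety | 0.5 | – | CFL fraction |
| reinit_interval | 20 | iterations | see above |
| convergence_tol / window | 1e−3 / 30 | – | volume-plateau stop |
| band_width | 8 | voxels | exact-distance band; wide enough that a CFL-bounded front cannot outrun it between reinitializations |

Presets (`presets.yaml`): contrast_enhancing and necrotic (0.3, 0.5, 0.2),
edema (0.2, 0.5, 0.3) — the recommended general-purpose set.

## Synthetic phantoms

The generator emulates post-contrast T1/FLAIR glioblastoma contrast
structure: nested star-convex components (necrotic core ⊂ enhancing lesion
⊂ edema halo) on uniform parenchyma, with intensity ordering
necrotic (150) < parenchyma (400) < edema (550) < enhancing (800) in
arbitrary MR units. Shapes are spheres radially modulated by a seeded
band-limited spherical-harmonic perturbation (orders ≤ 4), so truth masks
are exact radius comparisons and nesting is guaranteed. The edema/
parenchyma transition is Gaussian-blurred (fuzzy boundary); optional
continuous intensity texture (correlation ~2 mm, clipped at ±1.3 sd) fills
the core for heterogeneous cases; an optional detached bright distractor
mimics a satellite enhancing lesion. Intensities are rounded to integers,
which makes DICOM round trips exact. Default grid 96×96×48 at (1, 1, 2) mm
— anisotropic like typical MR and small enough for minute-scale runs.

Standard fixtures (fixed seeds are part of the study definition):
`clear` (seed 1) — high contrast, low noise; `heterogeneous` (seed 2) —
strong core texture (sd 0.11×800), noise sd 20, distractor of radius 6 mm
centered 26.5 mm along +x (≈5 mm surface gap); `fuzzy_edema` (seed 3) —
large halo, 3 mm boundary blur, noise sd 80 so the edema/background
contrast-to-noise ratio is below 2.

What the phantoms do **not** emulate: real brain anatomy (gyri, ventricles,
skull), bias fields, motion/ghosting artifacts, multi-sequence appearance,
non-star-convex or infiltrative growth patterns, and partial-volume
effects beyond simple blurring. Passing phantom tests therefore
demonstrates the numerical and behavioral correctness of the machinery —
not clinical-grade accuracy on patient data.

## Evaluation protocol

* Dice similarity `2|A∩B|/(|A|+|B|)`; two empty masks score 1 (vacuous
  perfect agreement, documented and tested).
* Bland-Altman: bias = mean(a−b), sample SD (n−1), limits of agreement
  bias ± 1.96 SD.
* Tumor features: `area` = masked voxel count × in-plane pixel area summed
  over slices; `edge_sharpness` = mean unsmoothed gradient magnitude over
  surface voxels (≥ 1 background 6-neighbor); `slope` = mean intensity
  change per mm along outward surface normals over a ±2 mm trilinear probe
  (normals from the smoothed signed distance transform of the mask). The
  feature definitions are operational choices of this package; "area" is
  deliberately the summed in-plane area (volume / slice spacing), and
  "slope" is a signed boundary-contrast measure (negative when the
  interior is brighter).

## Known limitations

* No advective ∇g·∇φ edge attraction: with a nonzero α the front creeps
  slowly even across strong edges instead of locking onto them; the region
  term provides the stable equilibrium.
* Single-label: overlapping components are segmented in separate runs.
* Full-grid dense updates (no sparse narrow-band optimization): fine at
  desk scale (~0.5 M voxels), not tuned for whole-head 1 mm³ volumes.
* The distractor-capture behavior depends on the interplay of reinit
  interval, weights and distance; it demonstrates the regime contrast on
  the standard fixtures rather than a calibrated detection property.
* No mask editing; re-run with tuned weights instead.
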