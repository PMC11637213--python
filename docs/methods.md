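# Methods

`phmsr` fuses two views of the same tooth crown — an intraoral-scan
surface cloud and a CBCT-derived crown + pulp cloud — by a rigid
registration designed to preserve the pose of the pulp chamber, which
only the CBCT sees. This note records the models, the parameter choices,
and the limits of what the synthetic experiments demonstrate.

## Registration model

All registrations move the scan (free) cloud onto the CBCT (fixed)
cloud. A pose is a proper rigid motion `p -> R p + t` with `R` in SO(3),
coordinates in mm.

### Pulp-horn feature mapping (PHFM)

Each pulp horn — the spike of the pulp chamber under a cusp — gets a
*feature direction*: the unit vector from the pulp-cloud centroid to the
horn apex. Apexes are found as the `n_horns` highest local maxima of the
pulp cloud along the occlusal axis, with a minimum lateral separation
(default 1 mm, measured in the plane perpendicular to the axis so flank
points of a claimed horn cannot found a second one). Manual apex
overrides pass through untouched; horn picking is clinically a manual
step and the automatic detector is a convenience for phantoms and clean
segmentations.

A crown CBCT point is a *mapping point* when the angle between its
outward surface normal and the best-matching horn direction is at most
`gamma_max`. These are the crown points whose local geometry most
constrains the pulp pose. Published settings: `gamma_max` = 20° for
small initial deviations, 25° for large ones.

### Mapping surfaces (MLS quadrics)

Around a mapping point `c_h` a local quadric
`z' = a0 + a1 x' + a2 y' + a3 x'^2 + a4 x' y' + a5 y'^2`
is fitted to its `k_c`-nearest neighbourhood (restricted to the fit
radius `r`) by weighted least squares with Gaussian weights
`exp(-d^2/h^2)`, `h = r/2`, in the tangent frame from neighbourhood PCA.
The patch is sampled on a grid of span `d_s` inside a disk of radius
`r_s` and the *nearest sample* replaces the nearest raw point as the
correspondence target. Free points whose nearest fixed point is not in
the mapping set (or its `k_y`-neighbourhood) keep plain point-point
matching, as do points whose patch cannot be fitted (fewer than six
usable neighbours — the quadric has six coefficients). A free point that
exactly coincides with a fixed point keeps that exact correspondence.

Patches depend only on the fixed cloud, so each is fitted and sampled at
most once per registration and cached.

Parameter semantics and defaults:

| parameter | meaning | default |
|---|---|---|
| `gamma_max` | normal-to-horn angle bound (deg) | 20 (small) / 25 (large) |
| `r = r_fit = r_sample` | patch fit/sampling radius (mm) | 0.1 (small) / 0.3 (large), floored — see below |
| `d_sample` | patch sample span (mm) | median fixed-cloud spacing / 3 |
| `k_y`, `k_c` | mapping-neighbourhood / fit-set sizes | 16 / 48 (`k_c >= 3 k_y`) |
| `mapping_weight` | confidence weight of surface pairs | 3 |

The published radii (0.1 / 0.3 mm) presuppose clinical cloud densities
(~150k-vertex scan meshes, ~0.03 mm spacing). A fit radius far below the
point spacing leaves no neighbourhood to fit, so `register_phmsr` floors
`r` at 3.5x the fixed cloud's median nearest-neighbour spacing
(`adaptive_radius=True`; disable to get the literal radii). The radius
plays its role *relative to density*: on 0.25 mm-voxel-limited clouds the
floor restores the intended behaviour. `d_sample` follows the rule that
the sampling span tracks the average span of the target cloud, divided
by 3 so the patch is effectively continuous for the nearest-sample
search. Surface pairs carry a confidence weight (default 3) in the
solver — the mapping points and their neighbours are deliberately
weighted up, since patch targets average the fixed cloud's quantisation
noise over ~`k_c` points while raw targets carry it in full.

### Sparse l_p alignment (ADMM)

Correspondences are solved by minimising `sum_h w_h ||R y_h + t - c'_h||_2^p`
with `p = 0.5` by default (an l_p, p<1, penalty rejects gross outliers).
Splitting residuals into auxiliary variables `z_h` with multipliers
`lambda_h` and penalty weight `mu` gives the augmented Lagrangian; one
inner pass alternates:

1. `z`-update: the proximal operator of `||.||^p` applied to each shifted
   residual magnitude — closed form for p = 2 and p = 1, a safeguarded
   Newton solve (20 iterations, tol 1e-10, plus the zero-vs-interior
   objective comparison) for fractional p;
2. rigid update: weighted Procrustes (SVD, `det R = +1` enforced) against
   the ADMM-shifted targets;
3. multiplier update `lambda_h += mu * delta_h`.

`p = 2` needs no splitting and reduces to the closed-form Procrustes
solution exactly; this is also what makes the sparse solver collapse
onto classic ICP per-iteration at `p = 2`, a property the tests assert.
Because the objective is nonconvex for p < 1, each pass carries a
monotone-descent safeguard: a rigid update that would increase the
alignment cost is rejected (multipliers still advance, so later passes
can escape). The *alignment cost* is the monotone quantity; the
augmented Lagrangian itself necessarily rises at every multiplier ascent
step.

Published solver settings: `p = 0.5`, `mu = 10`, `n2 = 2` correspondence
refreshes per outer iteration (the "intermediate point" re-matching),
`ns = 3` inner passes per refresh. Multipliers are reset when
correspondences are rebuilt. The outer loop stops when one outer
iteration changes the pose by less than 0.01° and 1e-3 mm (measured at
the source centroid), or after 50 iterations.

### Baselines

* **ICP**: nearest-neighbour correspondences + Kabsch update; stops at
  a mean residual below the allowable error (0.1 mm), on stagnation, or
  at 100 iterations. The allowable error is read as an absolute residual
  target: a residual-*change* threshold of 0.1 mm would stop after ~2
  iterations and produce an uninformatively coarse baseline.
* **Sparse ICP**: the identical ADMM solver with plain nearest-neighbour
  correspondences (no surfaces, no PHFM, no weighting).
* **Rigid CPD**: EM over a Gaussian mixture with the moving points as
  centroids, a shared isotropic variance, a uniform outlier component
  (weight 0.1 by default) and no scale estimation. The rotation comes
  from an SVD each M-step; iterations stop when the negative
  log-likelihood stagnates (ECM, so the NLL is non-increasing, asserted
  in tests) or sigma^2 underflows. CPD is O(N·M); benchmark harnesses
  subsample both clouds to <=1500 points and apply the estimated
  transform to the full cloud.

## Accuracy metrics

* **Crown RMSE**: for every fixed CBCT point, the distance to its
  nearest registered-scan point; report the root mean square. The
  pairing direction (CBCT -> scan) follows the metric's definition.
* **CPPD / CPOD** (crown-pulp position / orientation deviation):
  principal-component frames are fitted to the pulp cloud and to the
  crown cloud in its ground-truth and registered poses. Per-axis
  position deviations are the difference of crown-minus-pulp centre
  offsets, expressed in the pulp frame; per-axis orientation deviations
  are differences of the crown frames' Euler angles (intrinsic ZYX,
  degrees) relative to the pulp frame. CPPD/CPOD are the Euclidean norms
  of those triples. Axis signs are canonicalised against the pulp frame
  for the truth pose and against the *truth crown frame* for the
  registered pose: the two crown poses are nearly parallel, so the sign
  choice is stable, whereas canonicalising both against the pulp frame
  occasionally flipped an axis that happened to be near-perpendicular
  and produced spurious ~180° deviations. Both conventions leave the
  metrics invariant under a common rigid motion of all three clouds.
  The Euler convention (ZYX intrinsic) is a package choice; no standard
  exists for reporting the decomposition.

## CBCT preprocessing

* **Hybrid filter**: per-slice wavelet shrinkage (sym4, universal
  threshold from the MAD of the finest diagonal band, soft) followed by
  non-local means with block size 2, search window 5, decay 10. Output
  intensities are clipped to the input range.
* **Adaptive SCM segmentation**: each pixel is an SCM neuron
  `U(n) = f·U(n-1) + S·(1 + beta·V_L·(W ⊛ Y(n-1)))`,
  `Y(n) = [U(n) > E(n-1)]`,
  `E(n) = e^{-alpha_e}·E(n-1) + V_E·Y(n)`,
  with slice-adaptive parameters `alpha_e = C/mean`, `V_E = 2·mean`,
  `beta = a·ln(mean)`, `alpha_u = ln(1/var)`, `E(0) = max`. Defaults
  `C = 0.02·max(I)`, `a = 0.2` (the constants have no canonical values;
  this `C` resolves a 2:1 intensity ratio into >= 5 firing-time bins even
  on background-dominated slices, where a larger `C` merges adjacent
  tissue classes, and `a` keeps `beta` of order one on 8-bit slices).
  Two stabilisations matter:
  * the memory factor `f = exp(-alpha_u)` is clipped into [0, 0.25] —
    on any slice with variance > 1 the formula gives a negative decay
    constant (divergent recurrence), and a large memory factor makes U
    ramp linearly so all intensity classes fire within an iteration of
    each other, destroying the log-intensity -> firing-time quantisation
    the segmentation relies on;
  * the 3x3 inverse-distance coupling kernel `W` is normalised to unit
    sum, so the synchronisation boost is bounded by `beta` and a firing
    wave cannot jump an intensity-class boundary.
  Pixels that first fire at the same iteration share a label; never-fired
  pixels are background. The volume pipeline rescales slices to an 8-bit
  range, classifies per-slice region mean intensities into three tiers by
  multi-Otsu over the volume, fuses bright regions across slices by 3D
  connected components into up to two tooth structures (a target molar
  plus its neighbour), and takes each fully-enclosed cavity inside a
  tooth as its pulp (the anatomical definition: a low-intensity chamber
  surrounded by dentin). A mid-intensity bulk outside the teeth is
  labelled alveolar when present.
* **Surface extraction**: marching cubes at 0.5 on the binary mask,
  vertices scaled into mm, umbrella-operator Laplacian smoothing
  (lambda = 0.5, default 10 passes), outward vertex normals averaged
  from triangle normals.

## Equivalent-crown carving

The scan crown's oriented bounding box (centroid centre per the OBB
definition; PCA axes, canonicalised: descending variance, first two
signs positive against the global axes, third axis right-handed) is
aligned to the CBCT tooth's box: rotation maps box axes onto box axes
(prongs parallel; near-180° ambiguity resolved toward the minimal
rotation), and the centre moves to (x_ct, y_ct, z_op) — x and y from the
CBCT box, z kept from the scan box, exactly as the procedure prescribes.
The CBCT tooth is then cut at the aligned box's bottom face A'B'C'D'
with the normal pointing occlusally; points with non-negative signed
distance are kept. Whether the box should be PCA-derived or scanner-axis
aligned is not specified anywhere; PCA is used and canonicalised for
determinism.

## Synthetic phantoms — what they emulate and what they don't

`make_tooth_phantom` builds a molar-like crown: an anisotropic ellipsoid
(semi-axes 0.50d / 0.42d / 0.35d — molars are wider mesiodistally than
buccolingually) with `n_cusps` Gaussian cusps of unequal seeded heights
on a ring, and two occlusal fissure grooves along the inter-cusp
bisectors. The asymmetries are load-bearing: a symmetric smooth phantom
has an azimuthally near-unidentifiable pose, so any registration method
"errs" by 1-2° on it — a property of the object, not of the methods.
Occlusal displacements taper smoothly to zero toward the equator; a hard
`z > 0` cutoff folds triangles on the near-vertical walls. The pulp is a
0.45-scaled inner ellipsoid with one sharp horn (sigma 0.06d) under each
cusp; generation fails if any pulp vertex comes within 1% of the crown
diameter of the crown surface.

The *scan* cloud samples the crown surface above the gingival margin at
a default 25/mm² (tests use 60/mm²; intraoral scanners deliver ~100/mm²)
with Gaussian noise of sigma 0.02 mm along the normal — the 20 µm
scanner accuracy class. The *CBCT* clouds follow the clinical
reconstruction chain: voxel occupancy at 0.25 mm pitch (voxel centre
inside the closed surface, decided by the nearest dense-sample normal,
which keeps the interface unbiased), marching cubes, and smoothing. The
smoothing is a shrink-free Taubin variant (alternating +0.5 / -0.53
Laplacian steps): plain Laplacian smoothing shrinks cusp tips by
~0.2 mm, which is a generator artefact, not an imaging property. On top
come Gaussian surface noise (default sigma 0.05 mm — no published value;
quantisation alone contributes ~0.05 mm rms), optional gross outliers
(an exact floor(frac·n) count displaced 1-5 mm along the outward normal
and pushed further if the direction grazes the surface), and contiguous
occlusal dropout blotches. Crown and pulp clouds share one frame, so a
crown-estimated transform transfers to the pulp with zero extra error.

Pose perturbations draw a random axis/angle (applied about the cloud
centroid) and a random translation, with presets small (<= 5°, <= 1 mm)
and large (<= 25°, <= 5 mm) — the two initial-deviation regimes the
parameter presets are tied to; the exact generating transform is
returned for recovery tests.

What passing phantom tests does *not* show: robustness to metal
artefacts, to partially erupted or damaged crowns, to calcified or
anatomically variant pulp chambers (where horn directions stop being
informative), to soft-tissue clutter in the scan, or to segmentation
errors that displace the pulp relative to the crown. The phantom pulp is
always cleanly segmented and rigidly consistent with its crown by
construction.

The segmentation phantom is a flat-capped cylinder "tooth" (radius 28%
of the lateral field, height 75% of the axial field) with an ellipsoidal
interior pulp cavity, rendered at class intensities
background 50 / pulp 100 / tooth 150 (a 50-intensity contrast) plus
Gaussian noise; analytic solid volumes make voxel-count checks exact to
a couple of percent at 0.25 mm spacing.

## Numerical choices and degenerate inputs

* kNN ties break toward the lower index (platform determinism).
* PCA axes are sign-canonicalised (non-negative dot with the matching
  global axis for the first two, right-handed third); rank-deficient
  covariances raise rather than guess.
* Normals orient away from the cloud centroid (crowns are locally convex
  occlusally), with a `flip` escape hatch; coincident-point
  neighbourhoods raise listing the offending indices.
* The l_p proximal solve compares the interior Newton stationary point
  against z = 0 and keeps the better, so the hard-threshold behaviour of
  p < 1 shrinkage is exact up to the Newton tolerance.
* Registration translation errors are measured as the residual motion's
  displacement at the source centroid, avoiding lever-arm ambiguity.
* Problem sizes in tests and the acceptance script (10-20 phantom seeds,
  scan densities 50-60/mm², CPD subsampled to 1200-1500 points) are
  chosen so the full suite reruns in minutes on one CPU while keeping
  every statistic well away from its decision boundary.

## Known limitations

* The SCM pipeline assumes intensity-separable classes per slice; it has
  no shape prior and will merge touching same-intensity structures
  beyond what 3D connected components can split.
* Automatic horn detection needs a reasonably oriented, well-segmented
  pulp; clinical use would rely on the manual override path.
* The equivalent-crown cut is a single plane; a scalloped gingival
  margin is out of scope (that extraction is manual in practice).
* Parameters are fixed, not auto-tuned; the density-adaptive radius
  floor is the only data-driven adjustment.
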