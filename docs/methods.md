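# Methods

## Shape representation

Every bone surface is treated as star-shaped about its vertex centroid: each
ray from the centroid crosses the surface once, so the surface is the graph
of a radius function r(θ, φ) on the unit sphere. That function is expanded in
real orthonormal spherical harmonics without the Condon–Shortley phase,
flat-indexed k = l² + l + m with sine harmonics at m < 0, the zonal harmonic
at m = 0 and cosine harmonics at m > 0. Orthonormality is under the
solid-angle inner product, so the unit sphere has the single coefficient
c₀ = 2√π and c₀/(2√π) is always the mean radius.

This single-channel radial flavor was chosen over the three-channel (x, y, z)
parameterization of general genus-0 SPHARM: it is exact for star-shaped
bones, needs no correspondence optimization, and yields one real coefficient
per index — the form required by per-coefficient box plots, ANOVA over
coefficient indices, and a flat classifier feature vector. The price is that
genuinely non-star-shaped anatomy is out of scope; the parameterization
refuses (rather than silently folds) surfaces where two vertices share a
direction within 0.1° with radii differing by more than 1%.

Degree-1 harmonics of a radial expansion encode translation of the expansion
origin, not shape. Since every surface is re-centred at its vertex centroid
before fitting, the synthetic generator sets the three l = 1 mean
coefficients and their SDs to zero; leaving them free would alias origin
shift into shape and make exact coefficient recovery impossible.

## Fitting and model order

Coefficients are the least-squares minimizer of Σᵢ (rᵢ − Σₖ cₖYₖ(θᵢ, φᵢ))²,
solved by SVD (`lstsq`), hence independent of sample ordering to ~1e-10 and
diagnosable: a rank-deficient design (e.g. samples on a single ring) raises a
conditioning error with the condition estimate. At least 2(L+1)² samples are
required; the 642-vertex icosphere comfortably supports the default L = 6
(49 coefficients). No quadrature weights are applied by default because
subdivided-icosahedron vertices are near-uniform; tests check the unweighted
Gram matrix on a 10⁴-point uniform sampling stays within 2e-2 of identity
(and within 1e-10 under exact Gauss–Legendre quadrature).

Model order is selected by the regression form of minimum description
length, MDL(L) = (N/2)·ln(RSS_L/N) + ((L+1)²/2)·ln N, minimized over
L = 0..L_max with ties to the smaller order. A numerically exact fit
(RSS below N·(1e-8·mean r)²) short-circuits to the smallest exactly fitting
order — without this guard, log(RSS) of a noiseless band-limited shape is
meaningless float noise.

## Pose normalization

Three rigid steps driven by the landmark triple (a, b, c): (1) rotate the
landmark plane onto z = 0, (2) translate c to the origin, (3) fix the
remaining in-plane freedom via landmark a. Two details matter:

* Step 1 rotates the *winding* normal (b−a)×(c−a) onto +z. The winding is
  intrinsic to the anatomy, so the canonical pose is invariant to any rigid
  motion of the input (verified to 1e-9 over random motions). The reported
  angle α is the unoriented plane angle in [0, π/2]; the applied rotation
  angle θ₁ ∈ [0, π] can be its supplement and is recorded separately so the
  transform replays exactly.
* Step 3 has two modes. `in_plane` (default) rotates about ẑ so a lands on
  the +x half-axis: idempotent, rigid-invariant, and a well-defined canonical
  frame. `literal_x` follows the verbal construction of the source workflow
  verbatim — rotate about the x axis by β, the angle between x̂ and the
  a-vector. This tilts the landmark plane back out of z = 0 and cannot be
  rigid-invariant: after steps 1–2 two moved copies of the same bone still
  differ by a rotation about ẑ, and β itself differs between them. The mode
  exists for fidelity and is deliberately not the default; the corresponding
  invariance test documents the failure rather than hiding it.

No scaling is applied anywhere: bone size stays in the coefficients (c₀).

## Landmarks

The anatomical definitions ("highest point of the trochlea", "most posterior
point of the cuboid tuberosity") name structures no geometry-only algorithm
can recognise. The computational content — the extremal point of a known
region along an anatomical direction — is kept, and the recognition problem
is factored into labeled vertex patches supplied with the surface (painted by
the generator, or annotated by a user in real mode). "Highest/lowest" project
on z, "most posterior" on y, via the rule directions. Ties break
lexicographically by coordinates then index, so detection is reproducible and
invariant to vertex reordering. An override map (label → vertex index) plays
the role of expert correction; a collinear triple is rejected with an
instruction to override.

## Segmentation and surface building

Slice-wise processing along a configured sagittal axis. Contrast enhancement
is a percentile-clipped linear rescale (defaults 1/99) — deterministic,
monotone, parameter-light. Region growing uses a fixed intensity band
|v − v_seed| ≤ tolerance on the 4-connected component of the seed; the
criterion depends only on the seed value, so the mask is independent of
traversal order and exactly checkable against a brute-force flood fill. An
adaptive running-mean criterion was rejected precisely because it is
traversal-order dependent. Seeds are inputs (operator-supplied in real mode,
ground truth in synthetic mode). The outer boundary is traced by
Moore-neighbour walking with Jacob's stopping criterion, and contour pixels
map to mm through the voxel spacing and origin (0-based indices, voxel-centre
convention).

Surface reconstruction replaces the original workflow's external
screened-Poisson tool with radial remeshing: normals from k-NN plane fits
(k = 12) oriented away from the centroid, then an icosphere (level 3,
642 vertices — well above the 2·49 samples L = 6 needs) whose vertex
directions receive inverse-squared-angular-distance-weighted radii of the
k = 6 angularly nearest cloud points; exact directional hits copy the radius.
A >30° angular coverage gap raises an error naming the gap direction. The
substitution is exact for the star-shaped surfaces this package models and
keeps the chain free of GUI tools; true Poisson reconstruction of general
topology is a non-goal.

Voxelization (the synthetic CT) rasterizes by even–odd parity of surface
crossings along z-rays through each voxel column of a world-anchored lattice
(cell centres at (i+½)·spacing). World anchoring leaves grid-vs-surface
alignment to the object's placement: symmetric alignments (an
origin-centred sphere on an integer lattice) bias digital volume counts by
±7%, while generic placements land within ~1% of the analytic volume.
Intensity defaults are Hounsfield-like (bone 1200, soft tissue 40, noise SD
30); the source study reports no acquisition parameters, so these are
package choices, not reproductions.

## Synthetic population

The generator emulates the study design: four classes × 15 subjects × 2
sides = 120 surfaces. Class means are degree-4 vectors (25 coefficients) with
mean radii 35/17/16/27 mm (calcaneus/cuboid/navicular/talus, typical adult
male scale) and 5–8 shape coefficients per class pair separated by ≥ 3 SD —
emulating the near-perfect class separability observed on real bones.
Inter-subject variation is independent Gaussian per coefficient (SD 0.5 mm on
shape coefficients, 3.0 on c₀, zero on l = 1), redrawn up to 100 times if a
draw's radius function goes non-positive, then failing loudly. Left bones are
mirrored *independent* draws from the same class mean: the sides share mean
shape without assuming subject-level symmetry. Landmark patches are 10°
geodesic caps about three fixed directions ≥ 110° apart.

What a green test does and does not establish: the cohort has known
band-limited ground truth, exact landmark labels and no acquisition
artefacts, so recovery, invariance and calibration results validate the
*machinery*. They do not reproduce the clinical numbers (left/right r² of
0.88–0.99, 1.02% misclassification at 40 trees, per-class
sensitivity/specificity 0.96–1.0), which require the undeposited 30-subject
CT data; the corresponding checks here are property-level analogs
(misclassification ≤ 5%, per-class sensitivity/specificity ≥ 0.95, per-class
left/right r² ≥ 0.95 — all of which the synthetic runs exceed, typically at
0% misclassification and r² ≥ 0.98). One structural difference worth knowing:
after mirrored-frame normalization the sine-type coefficients of left bones
flip sign, so once the dominant size coefficient is removed the left/right
correlation of the synthetic cohort collapses (~0.0–0.2) rather than staying
moderate as on real bones, where genuine bilateral shape similarity persists.

## Statistics and classification

Quartiles use linear interpolation (the default convention, stated so the
box-plot statistics are reproducible); outliers are values beyond 1.5 IQR
from the quartiles. The two-way ANOVA is the classical balanced fixed-effects
decomposition over bones × coefficient indices with subjects (and sides) as
replicates; unbalanced layouts are rejected outright, which sidesteps the
Type-I/II/III ambiguity — the emulated design is balanced. Both a full and a
reduced test (dominant coefficient excluded, index recorded per run) are
produced, because the size term otherwise swamps the coefficient factor. The
left/right comparison is the squared Pearson correlation of mean coefficient
vectors per class, with the same reduced variant.

The classifier is a random forest (scikit-learn) over the 49-coefficient
vectors. The experiment harness is in-repo and oracle-tested: deterministic
stratified fold assignment (members shuffled per class, dealt round-robin —
with 30 samples per class, unstratified 10-folds risk empty training
classes), confusion pooled over held-out folds (matching a single printed
rate rather than a fold average), one-vs-rest sensitivity TP/(TP+FN) and
specificity TN/(TN+FP) with division-by-zero reported as undefined rather
than 0, and a tree-count sweep over {10, 20, 40, 80, 160} on a shared fold
split with ties to the smaller ensemble.

## Numerical choices and limitations

* Fitting tolerance chain: parameterization is exact; fit accuracy is set by
  the SVD least squares (~1e-12 relative); mesh-pipeline coefficient recovery
  is limited by remeshing interpolation (< 1e-2 mm observed ~1e-13 on
  matching directions, ~1e-3 after resampling).
* The segmentation pathway has a known half-voxel inward bias: contour
  pixels are inside voxels, so c₀ is underestimated by roughly
  spacing/2 · 2√π (~1.3–1.6 mm at 1 mm spacing). Shape coefficients are
  much less affected (≤ 0.8 mm observed). Subvoxel contour refinement is out
  of scope.
* Determinism: one global seed derives all stage seeds by fixed offsets;
  two runs of the pipeline with the same configuration produce hash-identical
  artifacts (asserted in tests).
* Real-data modes expect labeled meshes (PLY + label sidecar) or NIfTI
  volumes with per-slice seed points; DICOM handling, Hounsfield calibration
  and multi-bone segmentation are out of scope.
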