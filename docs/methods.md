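# Methods

This note documents the models, conventions, parameters and design
decisions behind `osteoplan`, and what the synthetic phantoms do and do not
establish about behaviour on real data.

## Coordinate and transform conventions

Label volumes are index-ordered `(x, y, z)` with isotropic spacing; voxel
`(i, j, k)` sits at `origin + (i, j, k)·spacing` in millimetres. Meshes are
always in physical millimetres. All rigid motions are proper (determinant
+1) 4×4 homogeneous matrices; mirroring is never stored in a transform but
applied directly to mesh vertices with reversed face winding.

Euler decomposition uses fixed-axis X-then-Y-then-Z (`R = Rz·Ry·Rx`), the
convention whose middle angle is confined to `[-π/2, π/2)`; the outer angles
live in `[-π, π)`. The convention is a single named constant
(`geometry.EULER_CONVENTION`). A decomposition at `|Φy| ≈ π/2` raises
`GimbalLockError` rather than returning one of the infinitely many valid
answers — silent degeneracy would corrupt every statistic built on the
angles. Totals are `T = √(Δx²+Δy²+Δz²)` and `R = √(Φx²+Φy²+Φz²)`; method
differences `ΔT`/`ΦR` are Euclidean distances between the component
vectors.

## Meshing and resampling

Label volumes are resampled per label as indicator functions (trilinear
interpolation, re-threshold at 0.5) on a grid that tiles the same physical
field of view (half-voxel origin shift), which preserves label volumes
through grid changes. Surfaces come from marching cubes on the padded
indicator at iso-level 0.5. For registration-facing meshes the indicator is
first smoothed with a 1-voxel Gaussian, removing the staircase pattern of
the voxel grid; tests that need the raw iso-surface use `smooth_sigma=0`.
A lone voxel yields the inscribed octahedron (volume `4/3·(s/2)³`), the
expected marching-cubes behaviour for sub-voxel structures.

Nearest-point-on-surface queries use a vertex KD-tree to collect candidate
triangles (the faces incident to the six nearest vertices) and decide by
exact point-triangle distances; an exact brute-force mode backs the test
oracles. Plane cuts use uncapped mesh-plane slicing; the open boundary
loops are fan-triangulated from their centroids (valid for the star-shaped
cross-sections of long bones) and the cap vertices are tagged so the
objective can address the cut faces. Cut volume is conserved to 0.1%.

## Registration

Initial alignment matches centroids and long (first principal) axes. The
long-axis sign is caller metadata — a proximal→distal hint — because the
end-for-end orientation of a bone is not inferable from geometry. The spin
about the long axis of a twisted shaft is not resolvable from principal
directions, so twelve spin candidates are scored by a trimmed (best-half)
nearest-neighbour residual, the best few are mini-ICP-refined, and the
winner is refined by whole-bone ICP. Whole-bone alignment of a deformed
bone is a compromise fit, so its refinement stops on a relative criterion
(improvement < 0.1% of the residual).

ICP is point-to-surface: every moving vertex (no subsampling — determinism)
is projected to its nearest point on the fixed surface, gross outliers
beyond 10× the current RMS are gated out, and two candidate updates are
evaluated each iteration — the closed-form least-squares (Kabsch)
point-to-point update, which has the large convergence basin, and, once the
coarse phase slows, a linearized point-to-plane update, which converges
fast near the optimum. Whichever lowers the residual more is kept, so the
RMS history is non-increasing by construction; iteration stops when the
improvement falls below the tolerance (default 1e-4 mm).

Joint-end fragments default to the terminal 20% of the axial extent
(configurable): enough to cover epiphysis and metaphysis on the phantoms
while staying clear of mid-shaft deformities. Because a shaft fragment is
nearly invariant to small spins and axial slides, fragment registration is
multi-start: a deterministic grid of 12 spins × 3 axial shifts is
mini-ICP'd (two-stage: a cheap 4-iteration pass on all starts, a deeper
pass on the best six) and an alternative basin replaces the pre-aligned one
only if decisively better (10% margin) — near the segmentation-noise floor
the scores of all spins are within a few percent and choosing among them
would be arbitrary. With both sides analytic (noise-free) the congruent
basin reaches machine-precision residuals and recovery is exact to
millidegrees.

## Plane search and objective

The cut plane has six nominal parameters (centre on the axial centerline,
three rotations about the bone-local axes), but rotation about the plane
normal is a no-op, so the search spans centerline stations × two transverse
tilts. Defaults: stations every 2 mm over the middle 60% of the bone
(excluding the registered ends), tilts ±45° in 15° steps (49 tilt pairs,
~1.8k nodes on a 120 mm bone). The centerline is the area centroid of the
cross-section at each station.

The objective is the symmetric mean nearest-neighbour distance between the
two cut-face vertex sets after applying `M_prox` and `M_dist` — during the
sweep this is evaluated on the plane∩mesh intersection contour (the vertex
set both cut faces share), avoiding a full cut-and-cap per node; the
returned optimum is then cut fully. An optional term subtracts
`overlap_weight ×` (fraction of the template volume covered by the
reconstructed fragments); the default weight is 0 (pure gap minimization),
and the weight is recorded in every report. Ties break deterministically:
smaller objective, then station closest to mid-shaft, then lexicographic
(station, tilt, tilt).

For a pure rotational correction the single-plane gap cannot reach zero (a
closing wedge requires removing material); its minimum sits near the hinge.
The fragments are flagged as a closing wedge when the reconstructed distal
fragment crosses the proximal cut plane by more than 0.05 mm; the secondary
plane is the primary plane carried through `M_dist⁻¹·M_prox`, which lands
exactly on the proximal cut face after reconstruction, and the red/green
flag reports whether the two cut polygons intersect inside the bone.

The osteotomy location `ΔZ` is reported on the reconstructed anatomy: the
plane centre is carried through `M_prox` and projected on the template's
long axis. Measuring along the deformed bone's own principal axis would
bias the location by up to ~2 mm at 30° bends, because the bent bone's
principal axis tilts toward its longer segment. The plane's native station
in the deformed frame is kept alongside. The plane tilt names are exposed
neutrally as `psi_a`/`psi_z` (rotations about the first and second
transverse axes); reports label the axes explicitly.

## Agreement metrics

DSC is voxel-based, `2|A∩B|/(|A|+|B|)`, with both-empty defined as 1 and
one-empty as 0. Surface distances support two paths — boundary-voxel
centres for masks, per-vertex nearest-triangle distances for meshes — and
reports record which was used. MASD is the symmetric mean over the union of
both directed multisets (average symmetric surface distance); HD is the
maximum; HD95 the linearly interpolated 95th percentile of the union
(percentile dialects differ, so this is pinned). All three are symmetric in
their arguments and rigid-invariant. RCV is cartilage volume over bone
volume from watertight meshes (an absent cartilage surface gives 0).

## Statistics

The ICC is the two-way random model for absolute agreement of single
measures, computed from the ANOVA mean squares
`(MS_R − MS_E)/(MS_R + (k−1)MS_E + (k/n)(MS_C − MS_E))`. Reliability
reports sometimes attach a different numeral to this model; the function is
named by what it computes, and it matches pingouin's `ICC(A,1)` to 1e-9 in
tests. The estimator is not bounded below by −1 on tables without subject
variance; with real between-subject structure it stays in `[-1, 1]`. A
zero-variance table is defined as perfect agreement (1.0, with a warning).
Normality uses Shapiro–Wilk; mean differences use two-tailed paired t-tests
on the difference vectors; correlations are Pearson (consistent with fitted
linear trendlines); no multiple-testing correction is applied and raw
p-values are reported. Which samples enter each normality test (pooled over
bones or per bone) is ambiguous in general, so the study report computes
both and labels them. The RCV–age trend is fitted as `rcv ≈ a·exp(b·age)`
by least squares on `log(rcv)`. Reference residual errors after real
surgery (rotation 5.6° ± 4.2°, translation 2.0 ± 1.4 mm, from the
literature) are carried as constants in the study report for the
clinical-relevance comparison.

## The synthetic phantom

`make_healthy_bone` lofts analytic cross-sections into a watertight tube
with flared ends and voxelizes the same analytic solid at 0.5 mm, so mesh
and voxel representations agree to voxel precision. The shape carries the
asymmetries that make rigid registration well-posed on real bones:

* a 4 mm lateral bow of the shaft (the radial bow), the dominant
  large-scale asymmetry — it pins the spin about the long axis well above
  segmentation-noise scale;
* distinct epiphyses (proximal head 0.7× the distal radius), removing
  end-for-end symmetry;
* elliptical (cos 2θ, 22%) and one-sided (cos θ, 18%, styloid-like) end
  modulation, keeping the spin observable on voxelized, noisy surfaces
  (the cos θ term is what breaks 180° flips);
* a twisting 15% cos θ + 7.5% cos 2θ cross-section modulation and a 5%
  longitudinal ripple (23 mm period), so neither spin nor axial slide is a
  near-symmetry of the shaft.

The wedge deformity rotates the distal portion by the wedge angle about a
transverse axis anchored at the cross-section centroid of the wedge
station, with a smoothstep blend whose half-band (default ±2 mm) widens
just enough at large angles to keep the warp injective (a ±2 mm band folds
at 30° on a 4 mm shaft). The deformed volume uses the exact inverse warp
(closed-form outside the blend, 1-D bisection inside it). Ground truth
carries the exact inverse correction and the bisecting plane. The
contralateral bone is the pre-deformation mesh mirrored sagittally, so the
mirrored contralateral is exactly congruent with the ideal correction and
the ideal objective is ≈ 0; optional contralateral asymmetry is not
modelled.

Cartilage caps are the set of background voxels within a commanded
thickness of the bone (Euclidean distance transform), restricted to the
terminal 10 mm of each end; cap thickness falls exponentially with the age
proxy (2.5 mm at age 7, e-folding 8.3 years), which produces the negative
RCV-versus-age slope of endochondral ossification. Segmentation noise adds
a smooth correlated Gaussian field (σ = 3 voxels) to the mask's signed
distance and re-thresholds, with the amplitude calibrated in up to three
measure-and-rescale passes to a commanded MASD (default 0.42 mm, the
CT-versus-MRI agreement scale); topology is preserved by keeping the
largest component. The three planning variants per case are: clean volume
(CT-like bone), perturbed (MRI-like bone), perturbed plus cartilage
(MRI bone + cartilage). The composite variant plans against a
cartilage-bearing contralateral representation — comparing a composite
surface to a bare bone template would bias the fit by the cap thickness.

### What the phantoms do and do not show

The phantoms exercise every algorithm with exact ground truth, but they are
geometric idealizations: no cortical/trabecular structure, no joint
congruence constraints between radius and ulna, no intra-observer
segmentation variability, and a slim 4 mm shaft. The commanded 0.42 mm
boundary noise is therefore relatively ~3× larger than on real adolescent
forearm bones, so noise-driven differences between segmentation variants
(ΔT, ΦR, ΔZ spreads) are amplified relative to the magnitudes reported on
patient data; those magnitudes are study outputs here, not reproduction
targets. Recovery results on clean phantoms (rotation to ~0.2°, station to
~0.3 mm) show algorithmic correctness, not clinical accuracy.

## Problem sizes and runtime choices

Defaults are sized for a single CPU: phantom meshes use 1.5 mm rings with
40 points per ring (~3.2k vertices); planning meshes are contoured at
1.25 mm after resampling; the default search grid is ~1.8k nodes. The test
suite's planted-wedge design is 3 angles × 3 stations on 120 mm bones; the
cohort emulation uses 10 cases × 3 variants; the acceptance script uses the
same designs with a 5-case cohort. These are the package's declared
evaluation sizes; all are configurable upward.

## Known limitations

* Single-plane wedge osteotomies only (opening/closing); oblique
  single/double-cut rotational techniques are out of scope.
* Radius and ulna are planned independently; joint-level coupling between
  the two bones is not a planning criterion.
* The gap objective localizes the cut to the hinge region but, for pure
  rotations, has a shallow minimum along the axis (±1–2 grid steps when
  tilts are coarse).
* Fragment registration assumes the joint ends themselves are not deformed;
  deformities inside the terminal fragments violate the congruence
  assumption.
* The voxel path of the agreement metrics compares boundary-voxel centres,
  which saturates below ~half-voxel differences.
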