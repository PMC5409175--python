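# Methods

This note documents the models behind `murt`, the defaults that matter,
and what the synthetic phantoms do and do not establish about real data.
Everything quantitative stated here is computed by the test suite or by
`scripts/acceptance.py`; nothing is quoted from elsewhere.

## Conventions

World coordinates are RAS-like millimetres; voxel indices are 0-based
and each volume carries a 4×4 index→world affine. All registration and
dose computation happens in world mm, so CT (0.16 mm) and MR
(0.25–0.27 mm) grids never need matching spacings. A `RigidTransform`
maps moving-world to fixed-world (`y = Rx + t`); a `DeformationField`
lives on a target grid as a pull-back map (a grid point `x` samples the
moving image at `x + u(x)`). Out-of-field voxels resample to 0
(air/background); LABEL volumes resample with nearest-neighbour
interpolation. Difference images are signed, and regional percent
change uses the first image as denominator.

For the supine mouse phantom: x = left/right, y = caudal/cranial,
z = dorsal/ventral, so a 0° beam travels ventral→dorsal along −z and the
conical-arc rotation axis is the vertical z through the isocentre.

## Phantoms

**Gel vial.** A water-equivalent gel column (CT value 1000 on an
air=0/water=1000 scale) inside a glass wall (2400) of 1.5 mm, inner
diameter 25 mm. The meniscus is a plane tilted 15° by default; any
nonzero tilt destroys rotational symmetry about the vial axis, which is
what makes marker-free surface registration well-posed (verified: the
gel surface registered against its own 90° rotation has RMS distance
well above two voxels, and below half a voxel at zero tilt, in which
case a warning is recorded in the truth metadata). CT noise is Gaussian
(σ = 20), MR noise Rician at SNR 20 relative to the gel signal; neither
level is prescribed by any physical reference, they are chosen so the
CT-invisible / MR-visible dichotomy of the study holds. Masks are
voxelized analytically and blurred by 0.6 voxel for partial volume.

**Mouse abdomen.** Analytic ellipsoids for body, pancreatic tumour
(upper-right abdomen), kidneys, adrenals (2.4 mm diameter, cranial to
the kidneys), liver, spleen, stomach, a bowel compartment and a bladder.
Organs must be pairwise disjoint and inside the body; violations raise
an error naming the colliding pair. Contrast tables are config-driven:
CT soft-tissue values span ≤ 30 units around water so tumour and adrenal
CNR against body tissue is < 1 at σ = 20 (invisible), while bSSFP gives
them CNR ≥ 5 and CPMG gives the highest tumour contrast. CNR is measured
on eroded ground-truth masks so partial-volume edges do not bias the
means; at SNR 20 the Rician bias on organ means is below 2 %.

**Motion.** Intrinsic motion composes a vertical droop (zero at the
lowest body point — the cradle contact — rising linearly to the
requested amplitude at the free surface), a radial bladder expansion
derived from a volume-growth fraction, and a seeded smooth random warp
windowed to the bowel (its amplitude is a free parameter; no physical
displacement value is asserted for peristalsis). Extrinsic motion is a
single rigid pose perturbation about the volume centre. MR geometric
distortion is a seeded degree-2 polynomial field over normalised FOV
coordinates with no constant term (bulk shifts belong to the pose);
its amplitude parameter is the peak displacement over the FOV. Every
motion operation returns the exact field or transform applied, and a
zero spec returns the input object unchanged.

**Virtual gel readout.** Absorbed dose darkens the gel:
Δsignal = S·(1 − e^(−kD)) with S = 600 signal units and k = 0.35 /Gy,
scaled by the local gel fraction so dose in air leaves the background
untouched. With readout noise σ = 50 this separates the 2 Gy beam paths
from the 4 Gy intersection by 3σ, which is all the workflow needs
(ordinal separability); no real gel's response curve is claimed. The
response is invertible, and dose maps are recovered from pre/post scan
pairs via the inverse. The canonical segmentation of a high-dose region
thresholds the recovered dose midway between the single-beam plateau and
the summed plateau (3 Gy for 2+2 Gy); an unsupervised three-class Otsu
split of the dose map lands close to but slightly below that midpoint
(its threshold balances class masses, not physics), which is why the
midpoint rule is the default.

## Registration

**Surface ICP.** Region growing (26-connected, inclusive intensity
window) segments the gel — windows are chosen at half-levels between the
plateau intensities (500 between air and gel, 1700 between gel and
glass) so the implied boundary sits at the physical interface on both
modalities. Surfaces are triangulated at those same intensity
iso-levels (not on the binary mask: binarized flat surfaces such as the
meniscus carry a coherent grid-phase offset of a fraction of a voxel
that measurably biases cross-grid registration) and pooled on a 0.5 mm
lattice for uniform density. ICP alternates k-d-tree closest-point
matching with a Kabsch update (optional trimming for outliers; tolerance
1e-4 mm RMS change, 200 iterations max), initialised by centroid +
principal axes with the four proper sign combinations disambiguated by
one-shot RMS. Because point-to-point matching between two independent
samplings of the same surface pays a tangential quantisation penalty
that leaves shallow minima along near-symmetry directions, the solution
is polished by a few point-to-plane Gauss–Newton steps against normals
estimated on the fixed cloud; this recovers the final fraction of a
degree and is on by default. If the final RMS is anomalously large a
registration-quality warning (not an error) is emitted, since
near-symmetric gels can lock onto a rotated minimum.

**Rigid intensity registration** wraps a standard multi-resolution
(3-level) Mattes mutual-information optimisation (32 bins, regular-step
gradient descent), the stock choice for cross-modality rigid alignment;
a MIND-SSD metric variant is available when histograms are too flat.

**MIND deformable.** The modality-independent neighbourhood descriptor
uses the six-neighbourhood stencil at 1-voxel offsets, Gaussian patch
σ = 0.8 voxels, variance normaliser = mean of the six patch distances
floored at 1e-6 of the squared dynamic range; components lie in (0, 1]
and are invariant to affine intensity maps. Inputs are consistently
presmoothed (σ = 1 voxel) so that the extra smoothing a warp's
interpolation introduces does not masquerade as descriptor mismatch.
Two field models are provided:

* `free` — demons-style multichannel SSD descent over a 3-level
  pyramid: residuals projected on precomputed fixed-image descriptor
  gradients, per-voxel step cap (0.5 voxel), fluid smoothing of the
  update (σ = 1) and diffusion smoothing of the field
  (σ = 1 + 10α, α = 0.1 default). A persistent objective increase
  (> 5 % to the end of a level) raises a convergence error. This model
  handles local organ motion (droop, peristalsis).
* `polynomial` — Gauss–Newton directly in the coefficients of a global
  low-order polynomial field (degree 2 default), with Cauchy IRLS
  reweighting and an optional ROI mask. This is the appropriate model
  for scanner geometric distortion, which is a smooth field-of-view-wide
  effect: pooling evidence globally averages the noise away and the
  field cannot drift where there is no contrast. The recommended ROI is
  a shell around the body outline (`boundary_shell`), the one structure
  reliably visible in every modality; without it, strong one-sided edges
  (organs visible in MR only, or the glass vial visible in CT only) bias
  the fit by a fraction of a voxel even under the robust loss.

A free-form field smoothed strongly enough to suppress noise also
attenuates a smooth global field each iteration, which is why the
free model cannot recover FOV-scale distortion to sub-voxel accuracy on
noisy cross-modality phantoms and the polynomial model exists. The
descriptor SSD is a meaningful objective only where descriptors carry
structure; on noise-dominated flat regions warping changes the
interpolated noise texture, so reductions are asserted on the
body-outline shell, not as an unmasked global mean.

**Transform transfer** composes the rigid (+ optional deformable) chain
found for one MR contrast and applies it to a sibling contrast acquired
in the same scanner frame (or with a declared fixed offset), resampling
onto the CT grid in a single interpolation; the output is flagged as
planning-importable. A declared frame mismatch without a relative
transform is refused.

## Dose engine

Primary photon attenuation + inverse square + Gaussian penumbra only; no
scatter, no spectrum. μ comes from a two-point calibration (air→0,
water-equivalent CT value 1000 → μ_w = 0.02 /mm effective). Rays are
integrated by cumulative sum on a beam-aligned grid (parallel-ray
approximation, which at SAD = 350 mm and mouse-scale objects agrees with
the divergent closed form to well under 1 %: the depth-dose test holds
to 0.01 %). SAD defaults to 350 mm and the penumbra σ to 0.3 mm, both
configurable; dose values are relative until a plan is normalised, so Gy
are model units tied to the prescription point. Arcs are discretised
superpositions of equally-spaced static beams (36 control points
default; doubling from 36 to 72 moves the isocentre dose by < 0.5 %).
The conical arc rotates the subject about the vertical axis through the
isocentre with the gantry fixed, matching the delivery geometry the
phantom study emulates. The cross-beam intersection mask keeps only the
connected component at the crossing, because attenuation plus
inverse-square gain can push a single beam past the 1.5×-plateau
threshold near its entrance surface.

Known limitation: without scatter the dose outside the geometric field
is essentially zero, so out-of-field organ doses are lower bounds, and
the low-dose-bath comparisons between plans reflect geometry only.

## Planning and evaluation

The isocentre is the (optionally intensity-weighted) centroid of the
target mask; a zero-mean Gaussian operator-jitter model (σ = 0.25 mm
default) emulates a human prescribing the centre by eye, replacing the
manual step with an explicit, documented error budget (the radial error
of that model is Maxwell-distributed with mean 2σ√(2/π) ≈ 0.40 mm at
the default σ). Collimator choice takes the smallest available circular
field covering the target's maximal beam's-eye-view extent (the largest
caliper diameter of the mask); an oversized target emits a coverage
warning suggesting multiple fields, which are supported as manual plan
composition only. DVHs are cumulative with 0.1 Gy bins. The plan set for
the abdominal comparison contains exactly the four geometries (45°
conical arc; vertical beam; 30°+60° conical arcs; two 120° gantry arcs
equivalent to −120°…+120° of source travel), all normalised at the
shared isocentre.

The end-to-end gel evaluation per run: generate a gel phantom (CT
0.16 mm / MR 0.27 mm), form the cross-beam target (two orthogonal 2 mm
beams, 2 Gy each, at an off-centre, off-axis point to avoid mirror
symmetry) on a 0.3 mm dose grid, image the gel in an MR frame perturbed
by a transfer-pose jitter (3°, 1 mm), register MR→CT through gel
surfaces + ICP, prescribe the isocentre as the MR-visible intersection
centroid (plus operator jitter) mapped through the registration, deliver
a 45° conical arc (5 mm collimator, 24 control points, 4 Gy at the
isocentre), read out the virtual gel again and report the centroid
offset. Problem sizes (0.3 mm dose grid, 24 control points, 0.6 mm
surface-point pitch) resolve every structure involved while keeping the
five-run study a desk-scale computation; they are package defaults and
can be tightened via keyword arguments.

## What the phantoms do and do not show

Passing tests establish that the *chain* is unbiased and that each
stage's error contribution is at the sub-voxel level under controlled
contrast, noise and motion — the phantom geometry is analytic, organ
interiors are homogeneous, respiration is absent, and MR distortion is
exactly the low-order model the corrector assumes. Real tissue has
texture (which generally helps MIND), real distortion has higher-order
components (which the polynomial model truncates), and real gel
response varies batch to batch (here only ordinal separability is
used). Numbers transfer to real systems only insofar as those
assumptions hold.

## Numerical choices

Tolerances: ICP 1e-4 mm RMS change; rigid MI 200 iterations, min step
1e-4; MIND free model 50 iterations/level, polynomial model ≤ 25
Gauss–Newton steps with a 1-voxel trust region measured where the
evidence lives (the fit extrapolates freely at FOV corners, and capping
there would throttle convergence). Degenerate inputs: constant images
get a variance floor in MIND; rank-deficient point clouds warn;
empty masks, non-overlapping volumes, zero-sweep arcs, non-orthogonal
or skew cross-beams, and zero dose at a normalisation point raise typed
errors. Ties in collimator choice resolve to the smaller diameter.
Seeds: every stochastic stage takes an explicit seed; identical seeds
give bit-identical phantoms.
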