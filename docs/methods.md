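# Methods

This note records the model assumptions, parameter choices, and known limits
of the `brainmatch` pipeline and of its synthetic phantom generator. It
documents what the code computes and why the defaults are what they are; all
empirical statements below are the ones computed by the test suite and the
acceptance script, nothing more.

## Rigid registration

The transform is the 6-parameter rigid body
`M = Trans(tx,ty,tz)·Rx(rx)·Ry(ry)·Rz(rz)` acting on homogeneous
world-coordinate (mm) column vectors; each factor is a proper right-handed
rotation, and rotations act about the world origin. Working in world
millimetres (rather than voxel indices) makes the anisotropic 1.25 mm slice
axis exact. `estimate_rigid` returns the image→template matrix; the
segmentation entry points take the template→image matrix (the direction in
which the priors are pulled back), and the pipeline inverts explicitly at
the boundary between the two.

The cost is the sum of squared intensity differences between the image and
the template sampled at the mapped positions, after both volumes are
smoothed with a Gaussian kernel (default **5 mm FWHM** — the single
anti-local-minimum measure used here; there is no multi-resolution pyramid).
Minimization is Gauss–Newton on the first-order (Taylor) linearization with
the analytic template-gradient Jacobian, step-halving (up to 8 times) when a
trial step would increase the SSD, stopping at a relative SSD decrease below
`tol = 1e-6` or `max_iter = 32`. Two practical choices matter:

* **Out-of-field policy.** Template samples falling outside the template
  grid are filled with the template's background (corner) value rather than
  dropped. If they were dropped, translating the head out of the field of
  view would shrink the sum and the optimizer could "escape" to the
  boundary; with background filling every head voxel that leaves the field
  pays a full residual.
* **Global intensity scale.** A closed-form scalar gain on the template is
  re-fit every iteration (`estimate_scale = True`). Scan-to-scan global
  intensity scaling is part of the acquisition model (the phantom draws a
  0.9–1.1 gain per visit); without the scale term the gain would bias the
  geometric parameters. The transform interface stays 6-parameter.

The SSD is evaluated on every second voxel per axis by default
(`sample_step = 2`); sub-voxel accuracy comes from trilinear interpolation,
not sampling density, and measured recovery errors are identical at stride 1.
An optional mask restricts the SSD support (off by default — whole grid).

Registration accuracy is reported as head-centre displacement (mm) plus
residual rotation (deg) — a target-registration-error style metric. Raw
parameter differences are not comparable across conventions: with rotations
about the corner origin, a small rotation error shows up as a large
compensating translation difference.

## Tissue segmentation

Four clusters — GM, WM, CSF, "other" (background, scalp, eyes) — each with
normally distributed intensities described by a mean, a variance and an
effective voxel count. Template priors, mapped through the registration with
trilinear interpolation (voxels outside the prior field become pure
"other"), seed the per-voxel probabilities. Each iteration recomputes, in
order: cluster masses → weighted means → variances → class-conditional
normal densities → multiplicative probability update → per-voxel
renormalization. Iteration stops when the mean absolute probability change
drops below `tol = 1e-4` (default) or after `max_iter = 30`.

Numerical guards, all configurable:

* `sigma_floor = 1e-4·(intensity range)²` keeps collapsed clusters from
  producing singular densities; σ is a *variance* throughout.
* `mass_floor = 10` voxels: clusters below it keep their previous statistics
  and are flagged rather than updated from almost no support.
* `prior_floor = 1e-3`: the multiplicative update can never repopulate a
  class whose prior is exactly zero, so initial probabilities are floored
  and renormalized. Where subject anatomy departs from the template prior
  support this keeps the correct class reachable. Set it to 0 when the
  priors are exact by construction.
* Voxels whose four densities all underflow keep their previous
  probabilities; a constant-intensity image returns a flagged non-converged
  result instead of crashing.

The update multiplies densities into the *current* probabilities
(`prior_mode = "current"`); `"initial"` multiplies into the fixed mapped
priors instead. The current-probability form is a sharpening iteration: a
voxel's class probabilities tend to 0/1, with the limit assignment decided
by the densities. A consequence worth knowing: a broad low-prior cluster
will eventually capture far (≳2.5σ) intensity tails of a neighbouring tight
cluster if iterated long enough; spatially informative priors (near-zero
prior for absent classes at each location) are what keep this in check, and
the default tolerance stops iteration well before pathological sharpening.
With spatially flat priors the update reduces to unsupervised Gaussian
mixture fitting (checked against an independent EM implementation in the
tests); exactly flat probabilities are a symmetric fixed point, so that
comparison requires a symmetry-breaking jitter.

## Gray-matter binarization

The GM probability map is thresholded by Otsu's method over a histogram of
**256 uniform bins on [0, 1]**. The cut is placed at the upper edge of the
last lower-class bin (so values at the lower mode fall strictly below it),
with ties broken toward the lower threshold; the mask is `P_GM > threshold`.
Binarization is what makes matching invariant to the inter-visit intensity
scaling: the binary structure is unchanged when all intensities are
rescaled, while any intensity-based similarity degrades.

## Matching and scores

Masks are aligned through the template bridge: with per-image registrations
available, the inter-image transform is the matrix product of one
registration with the inverse of the other, and no direct mask-to-mask
estimation is needed. Binary masks are resampled nearest-neighbour (strictly
binary output); probability maps trilinearly.

The chamfer distance is the **directed, unnormalized** sum over the moved
mask's foreground of the Euclidean distance (in mm, anisotropic spacing
respected) to the nearest reference foreground voxel. It is evaluated with
an exact Euclidean distance transform of the reference complement, which the
tests verify equals the brute-force O(n²) double loop to 1e-9. Two
off-by-default options: `symmetric` averages the two directed sums, and
`per_voxel` divides by the moved foreground count; the directed sum is the
primary statistic, and its asymmetry is covered by a regression test.

Scores: `s = (1 − (d − dmin)/(dmax − dmin))·100`, clamped to [0, 100] for
distances outside the trained range (without clamping, out-of-range
distances would leave the stated score interval). The normalizer trains on
the pooled all-pairs distances of a cohort by default (`genuine`-only
training is available); `dmin`/`dmax` are the training extremes.

## Verification evaluation

Standard biometric definitions: FRR(t) = fraction of genuine scores < t,
FAR(t) = fraction of imposter scores ≥ t (accept on tie), TAR = 1 − FAR.
The EER is interpolated linearly between the two thresholds that straddle
the FAR/FRR crossing; it is invariant under strictly increasing score
transforms. Imposter pairs use the first visit of each subject by default so
genuine and imposter counts stay comparable; an all-visits mode exists.

The intensity baseline scores a pair by the mean squared intensity
difference after the same alignment, mapped through the same linear
normalization (trained on the MSE pool). It shares every preparation step
with the chamfer matcher, so the comparison between structure matching and
pixel matching isolates exactly the similarity statistic.

`CohortScorer` prepares each volume once (registration, segmentation, mask,
distance transform) and scores all pairs from the cache; this is
mathematically identical to calling the pairwise `match_pair` repeatedly.

## The phantom generator

The generator stands in for a real multi-visit T1 cohort. Anatomy is a
nested set of perturbed ellipsoids — WM core, GM shell, CSF shell, "other"
outside — with each shell boundary a *continuous* angular function: a fixed
base shape shared by every subject (distinct semi-axes 0.66/0.84/0.76 of the
half field per axis, an egg-shaped low-order term, and fixed mid-frequency
bumps) plus a subject-specific band-limited harmonic field per boundary
(4 harmonics of angular order ≤ 3, unit peak, scaled by the deformation
amplitude). Shell radii sit at 0.61/0.70/0.90 of the semi-axes.

Design rationale, in brief: the base shape must have no rotational symmetry
and must contain angular frequencies *above* the subject-field band,
otherwise a rigid rotation is either unidentifiable or confusable with a
subject deformation and intensity-SSD registration has no unique optimum.
Per-boundary independent subject fields make the GM shell vary on both
faces, which is what separates subjects (distinct subjects' GM masks overlap
with Dice < 0.85 at the default amplitude). Visit volumes are rendered by
evaluating the boundary functions *exactly* at each voxel's anatomy
coordinate under the drawn motion — never by resampling a label grid — so
rendering introduces no pose-dependent aliasing; grid-resampled rendering
measurably biased inter-visit transform composition by over a degree.

Default study conditions: 64×64×48 grid at (1, 1, 1.25) mm (a desk-scale
stand-in for 256×256×128 acquisition geometry; generation at other sizes is
a config field), class intensities other/CSF/GM/WM = 5/25/55/85 on a 0–100
scale, additive Gaussian noise with sd = 2% of that scale (the bottom of the
1.5 T SNR band), per-visit global gain uniform in 0.9–1.1, and per-visit
rigid motion drawn as a rotation about the field-of-view centre (≤ 5° per
axis) composed with a translation (≤ 5 mm per axis), reported in the
corner-origin parameter convention. Every output is a pure function of
(config, seed); the hard-cohort option lets two subjects share half their
deformation fields, giving a correlated imposter pair.

**What the phantom does not emulate** — and hence what passing tests do not
show about real data: no gyral/cortical folding (no algorithm here depends
on cortical topology, but real GM shape is far richer), no partial-volume
mixing at tissue boundaries (boundaries are crisp; real boundary voxels mix
classes and blur the intensity histogram), no bias fields or spatially
correlated noise, no atrophy/aging/pathology, and subject variability is
low-order smooth deformation rather than true anatomical variation. Results
on phantoms bound the pipeline's correctness, not its clinical performance.

## Problem sizes in the tests

Unit tests run on 32³ phantoms; the end-to-end studies use the default
10-subject × 2-visit cohort at 64×64×48, a 20-trial motion-recovery study,
and a 20-replicate comparison of chamfer vs intensity EER. These sizes keep
the full suite in the minutes range on one CPU while leaving every
statistic comfortably away from its acceptance bound.
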