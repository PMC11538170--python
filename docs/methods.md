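# Methods

## Problem

Ioflupane (¹²³I-FP-CIT) SPECT images the striatal dopamine transporter:
uptake is strong in the caudate and putamen and low everywhere else.
Quantification by fixed atlas VOIs requires warping every subject into a
common template space, but when striatal uptake is severely reduced the
image carries little anatomy for a registration to grip, and warping a
low-uptake subject onto a normal-uptake template systematically distorts
the striatum. `atrspect` implements the adaptive template registration
(ATR) answer: represent each subject as a weighted mixture of a
normal-pattern template and a disease-pattern ("egg-shape", posterior
putamen lost) template, pick the mixture weight that maximizes
zero-mean normalized cross-correlation (ZNCC) with the subject, and use
that subject-specific mixture as the normalization target.  The split
variant optimizes the weight per hemisphere and composes an asymmetric
target, addressing the left/right asymmetry typical of Parkinson
disease.

## Pipeline

For one subject the pipeline is

1. **Linear pre-alignment.** A 12-parameter affine (translation,
   rotation, log-scale, shear) maximizing ZNCC under a template brain
   mask, found by derivative-free Powell search over a 3-level
   multiresolution schedule. Initialization is the center-of-mass
   offset.  Deterministic: no stochastic sampling.
2. **Weight selection.** ZNCC between the aligned subject and every
   mixture `w·normal + (1−w)·egg` for `w ∈ {0.001, …, 0.999}` in steps
   of 0.001 — an exhaustive scan.  Because the mixture is affine in
   `w`, all 999 correlations reduce exactly to five masked inner
   products; the implementation evaluates the closed-form profile,
   and the tests verify it equals explicit per-`w` scoring.  Ties break
   toward larger `w` (the more-normal template).  Split mode runs the
   same scan per hemisphere on `mask ∩ hemisphere`.
3. **Nonlinear normalization.** A demons-style small-deformation
   registration to the selected template: per-iteration SSD forces
   (after fitting a gain/offset of the warped image to the template
   under the mask, so the force direction also increases correlation),
   fluid-style Gaussian smoothing of the update, compositive
   accumulation `u ← u∘du + du`, light diffusion smoothing of the
   field, and an accept-only-if-improved rule on the masked ZNCC with a
   positivity guard on the forward-difference Jacobian.  The returned
   field therefore never scores below its starting point and never
   folds.
4. **Outer refinement.** Weight selection is repeated on the warped
   subject and the normalization refined against the re-selected
   template (default 2 outer passes, stopping early when the selected
   weight moves < 0.005).  Iterative refinement was chosen over
   one-shot selection because the first selection happens on an image
   that is only linearly aligned.
5. **Quantification.**  The subject is resampled once through the
   composed map (affine ∘ deformation) onto the template grid.  Atlas
   VOIs (below) give per-region occipital uptake ratios, high/low-side
   values, the asymmetry index `AI = |L−R|/(L+R)×200 %`, and binding
   ratios (`ratio − 1`, the specific-binding scale used for
   comparability with the Southampton method).

## Templates

Parent templates are averages of eight standardized subjects per
pattern class, each divided by its own occipital-VOI mean before
averaging, so both parents (and hence every mixture) have occipital
mean exactly 1 and live on one intensity scale.  The split composite
feathers the two hemisphere mixtures across the mid-sagittal plane
(world x = 0) with a 4 mm FWHM blend band; a hard seam would inject a
spurious gradient into the nonlinear registration.  Width 0 restores a
hard split, and equal weights make the composite identical to the
global mixture regardless of the band.

## VOIs

Binary VOIs are built from an AAL-style integer atlas by the
resolution-matching rule: set the region indicator to 100, smooth with
an 8 mm FWHM 3D Gaussian, keep voxels strictly above 50.  Large
regions keep their half-maximum boundary on the raw edge; structures
thinner than the resolution supports vanish, which is reported as an
error rather than an empty mask.  Composite regions (striatum =
caudate ∪ putamen; occipital = the six AAL occipital components) are
built from the union indicator *before* smoothing so feathered edges
are not double-counted.  Laterality is cut at world x = 0 before
smoothing.  The occipital lobe is the nonspecific reference
throughout; the FWHM→σ constant is 2.3548 (= 2√(2 ln 2)).

## Evaluation statistics

Method agreement is summarized per region × {High, Low, AI} by
ordinary least squares (slope, intercept, Pearson r, two-sided p from
the t transform with n−2 df) and by the one-way random-effects
intraclass correlation ICC(1,1) with k = 2 ratings per target
(reference and candidate method): `ICC = (BMS − WMS)/(BMS + WMS)`,
exact-F 95 % confidence bounds, and the F-test p-value for BMS/WMS.
ICC(1,1) penalizes offset and scale differences that Pearson r
forgives, which is why both are reported.

## The synthetic phantom

The generator is parametric-analytic: a brain-shaped ellipsoid with a
cortical ribbon at the reference level, a deep white-matter compartment
at 0.75 of it (nonspecific uptake is not uniform in real scans, and
the interior contrast gives registration something to see), occipital
regions pinned to the reference level, and per-side caudate and
putamen ellipsoids with configurable uptake ratios and posterior
putamen truncation (the egg-shape pattern).  Images are produced as
uptake map → smooth random geometric deformation (per-subject anatomy)
→ 8.5 mm FWHM Gaussian blur (collimator resolution) → Gaussian or
Poisson noise.  The default grid is 128×128×90 at 1.72 mm; the test
suite and acceptance script run the same anatomy on a 64³ grid at
3.44 mm (same 220 mm field of view) to keep runtimes at desk scale.
Structure anti-aliasing uses a ~1-voxel soft edge.

Cohorts draw from five documented accumulation-type parameter ranges
(normal, eagle-wing, egg-shape, mixed, burst striatum) with a default
mix of 136 : 42 : 86 : 23 : 13 per 300 — e.g. egg-shape: both putamina
truncated to 0.3–0.6 of their length with ratios 1.3–2.0.  These
ranges are the generator's own conventions.

**Two truth levels.** `PhantomTruth.ratios` holds the generating
(pre-blur) label-mean ratios; `ratios_at_resolution` holds the ideal
measurement — the standard VOI quantification of the undeformed,
noise-free phantom at scanner blur.  At 8.5 mm blur any realistically
sized striatum loses 10–13 % of its VOI-mean contrast to the
partial-volume ramp, so pipeline accuracy is judged against the
resolution-matched truth: a reference normalization (the MRI-driven
standard in clinical practice) also measures the blurred image, and
the quantity under study is registration/template error, not
partial-volume error, which no normalization method corrects.

What the phantom does **not** emulate: projection-domain physics
(attenuation, scatter, collimator septal penetration, reconstruction
filters), anatomical variability beyond smooth deformations
(ventriculomegaly, atrophy), and extra-striatal binding.  Passing
tests therefore demonstrate the correctness and internal consistency
of the algorithms under controlled geometry, not clinical performance.

## Numerical choices

* Similarity mask: template voxels above 10 % of the normal-template
  maximum — whole-volume ZNCC would be dominated by the empty
  background and flatten the weight objective.
* Grid compatibility tolerance 1e-6 on spacing/affine entries
  (round-tripped files are not bit-identical); out-of-field resampling
  fills 0, matching the dark SPECT background.
* The pipeline's nonlinear pass is deliberately much smoother than the
  registration-module default (update smoothing 26 mm FWHM, total
  displacement ≤ 4 mm — comparable to the low-dimensional basis warps
  of classical SPM-style normalization): an aggressive local warp
  "fills in" reduced uptake toward the template's expectation, which
  inflates ratios at intermediate disease severity and erases
  left/right asymmetry.  The registration-module default (6 mm, ≤
  15 mm) is tuned for recovering known deformations.
* Weight-scan tie-break toward larger `w`; flat-metric affine steps
  keep current parameters.
* `>50` is implemented strictly, following the rule's wording.
* All phantom and Monte-Carlo randomness flows through seeded
  `numpy.random.Generator` instances; registration is seed-free.

## Known limitations

* The demons stage recovers what the image constrains: displacement
  tangential to isointensity surfaces is unidentifiable (aperture
  problem), so transform-space accuracy at flat-contrast landmarks is
  bounded even when the warped image matches the template almost
  perfectly.  Landmark validation is therefore image-space (structure
  centroids).
* Global ATR underestimates strong left/right asymmetry — the
  symmetric mixture template pulls both hemispheres toward a common
  pattern.  This is the documented motivation for the split variant,
  which removes most of that bias in the asymmetric-cohort tests.
* Hemisphere splitting assumes the mid-sagittal plane at world x = 0 of
  the template grid; templates built in a non-symmetric space would
  need a redefined plane.
* Deformation fields require axis-aligned template grids (diagonal
  affine); all grids this package builds satisfy that.
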