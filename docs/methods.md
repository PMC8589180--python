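# Methods

`izmap` quantifies the spatial relationship between deep-capillary-plexus
(DCP) telangiectasia and graded photoreceptor disruption on en-face
OCT/OCTA in macular telangiectasia type 2 (MacTel), and the longitudinal
predictive value of interdigitation-zone (IZ) loss for subsequent
ellipsoid-zone (EZ) loss. This note documents the models, the synthetic
data the package is validated on, the numerical choices, and the known
limitations.

## Imaging model and geometry

All images are square en-face projections of a 3 mm × 3 mm macular field
sampled at 304 × 304 pixels, so one pixel covers (3/304)² ≈ 9.74 × 10⁻⁵
mm². Areas are pixel counts times the squared pitch; no sub-pixel
modelling is attempted. Three channels describe one eye:

* **SCP angiogram** — superficial capillary plexus; its thick vessels
  project into deeper slabs as artifacts.
* **DCP angiogram** — deep capillary plexus, the layer carrying the
  telangiectasias (dilated, non-tapering vessels in a circumscribed zone).
* **Photoreceptor slab** — reflectance between the inner/outer-segment
  junction and the RPE, where IZ/EZ disruption appears hypo-reflective.

Photoreceptor disruption is graded into three nested combined regions:
A = IZ attenuation + IZ loss + EZ loss, B = IZ loss + EZ loss, C = EZ
loss, with C ⊆ B ⊆ A (every EZ-loss pixel also lacks the IZ). Exclusive
classes come from subtraction (attenuation-only = A \ B, IZ-loss-only =
B \ C), which partitions A exactly — an invariant asserted in the tests.

## Segmentation operators

**Phansalkar local threshold.** A pixel is vessel iff its normalized
intensity exceeds T(x) = μ(x)·(1 + p·e^(−q·μ(x)) + k·(σ(x)/r − 1)), with
μ, σ computed over a circular window clipped at the image border.
Defaults k = 0.25, r = 0.5, p = 2, q = 10, radius 15 px — the widely used
constants for [0, 1]-normalized intensities; all exposed in
`PhansalkarParams`. Non-negative images are normalized by their maximum
(making the operator invariant to positive intensity rescaling); the
implementation is verified against a per-pixel brute-force loop, exactly.

**Kapur maximum-entropy threshold.** The global level maximizing the sum
of Shannon entropies of the renormalized histograms below and above the
split; 256 bins, empty bins skipped (0·log 0 := 0), ties broken toward
the lowest level. Verified against exhaustive search over all bins.

**Hole filling.** Background components not 4-connected to the border are
annexed (foreground treated 8-connected by duality); idempotent and
monotone.

**Telangiectasia circumscription.** Within an operator-marked ROI:
Phansalkar binarization → morphological opening at capillary calibre
(disk radius 2) so ordinary capillaries neither bridge nor enclose area →
hole filling → removal of components smaller than 10 px or containing no
dilated vessel (maximum inscribed vessel width < 4 px). The result is
always a subset of the ROI. The opening radius, size and calibre cut-offs
are configurable; the defaults reflect the calibre separation between
capillaries (1–2 px) and telangiectatic vessels (≥ 4 px) at this sampling.

**SCP large-vessel artifacts.** Max-entropy foreground → opening at
capillary calibre → components kept only with area ≥ 300 px and maximum
inscribed width ≥ 4 px. Artifact pixels are *subtracted* from the
telangiectasia mask (the conservative quantitative reading of
"distinguishing artifact from true vessel"); the removed count is logged
so the display-only alternative stays auditable.

## Longitudinal analysis

Follow-up visits are aligned to baseline by registering the SCP
angiograms: centered affine initialization (regular-step gradient
descent) followed by B-spline free-form refinement (L-BFGS-B), both under
a mean-squared-error metric with a two-level multiresolution schedule
(shrink 4/2), via SimpleITK. The composed transform is exported as a
dense per-pixel displacement field on the baseline grid; masks are pulled
through it with nearest-neighbour resampling. The named registration tool
of the original protocol is replaced by this standard scheme — the fixed
contract is that the deformation is estimated from the SCP and then
applied to the photoreceptor masks, not the optimizer. Self-registration
yields < 0.5 px displacement; known smooth 3 px warps are recovered with
≈ 0.1 px mean endpoint error in the tests.

New EZ loss is followup \ baseline and EZ recovery is baseline \
followup, both in the registered frame. Predictive values of baseline
IZ loss for new EZ loss are computed pixelwise within an analysis domain
Ω:

* PPV = |new ∩ IZ ∩ Ω| / |IZ ∩ Ω|, NPV = |Ω \ (IZ ∪ new)| / |Ω \ IZ|,
* prevalence = |new ∩ Ω| / |Ω|,
* rPPV = PPV / prevalence, rNPV = NPV / (1 − prevalence),

so 1 means chance level. **Domain choice:** Ω defaults to the scan minus
baseline EZ loss — new loss cannot occur where loss already exists — and
this choice reproduces the printed magnitude relation
0.089 / (0.052/≈9 mm²) ≈ 15 between PPV, new-loss area and rPPV; Ω = full
scan remains selectable (`exclude_baseline_ez=False`). Per-eye predictive
values are averaged arithmetically across eyes, never pooled over pixels.
Eyes with empty baseline IZ loss have undefined PPV and are excluded from
the PPV/rPPV means.

## Cohort statistics

Severity stage (ordinal 0–6) is never treated as a numeric distance:
associations with stage use Spearman rank correlation (midranks for
ties), with a two-tailed exact permutation p-value for n ≤ 10 (full n!
enumeration, vectorized) and the t-approximation above. Stages pool into
early (0–2), moderate (3–5) and advanced (6).

Group comparisons use a Gaussian identity-link GEE with exchangeable
working correlation (two eyes share a patient), robust sandwich
covariance, a Wald chi-square on 2 df for the 3-level group factor, and
three Bonferroni-adjusted pairwise contrasts (statsmodels under the
hood). The sandwich Wald test is anti-conservative at small cluster
counts (empirically ~0.10 at 30 clusters, ~0.05 from several hundred);
the calibration simulation therefore runs in the asymptotic regime. With
singleton clusters the fit coincides with independence-GEE estimates to
numerical precision.

Inter-grader agreement uses ICC(2,1) — two-way random effects, absolute
agreement, single measures — computed from the two-way ANOVA mean
squares, with an F-test p-value; pingouin's `ICC(A,1)` serves as an
independent cross-check in the tests. Missing overlap values (eyes
without telangiectasia have an undefined ratio) are NaN and excluded
pairwise, with logged counts, not imputed as zero.

## Synthetic data: what it emulates, and what it does not

The generator produces scenes whose *cohort-level statistics* match the
configured targets per pooled group: mean ± SD areas of telangiectasia
and of the three exclusive disruption classes, and mean ± SD percent
overlap of telangiectasia with each class. Geometrically, the nested
regions are super-level sets of a smooth random potential biased toward a
jittered field centre (blobby annuli, exact pixel counts, nesting by
construction). The telangiectatic zone is a wedge about the lesion
centre: each class contributes the pixels of its annulus angularly
nearest a common anchor angle (small shares arrive as compact blobs on
their class boundary), then the zone is compacted — enclosed holes and
narrow inlets are swapped for same-class fringe pixels — because a
circumscribed area delineated by loop-and-fill cannot represent them.

**Sampling.** Areas are drawn from truncated normals at 0 whose parent
location is solved so the *truncated* mean equals the target (plain
truncation would inflate the mean, badly for cells like EZ loss in early
disease, 0.016 ± 0.031 mm²). Where no truncated normal attains the
printed mean/SD pair (coefficient of variation > 1), the mean is matched
exactly and the dispersion is attained only approximately. Overlap
fractions are drawn by stick-breaking, innermost class first, each
relative share moment-matched and additionally capped by the class's own
pixel supply: marginal means are preserved exactly, the draw lives on the
simplex, and nested classes compete for area as they do in real eyes.
One integer seed drives everything; identical seeds give bit-identical
scenes.

**Rendering.** Capillaries are curvy random-walk polylines of 1–2 px;
telangiectasia is rendered as a 6 px-wide dilated loop following the zone
boundary with internal chords (small zones are solid vessel knots inset
by 1 px); SCP large vessels are 8–12 px thick curvilinear paths. The slab
is 0.7 of dynamic range with depressions 0.15/0.35/0.55 for the three
classes; all channels carry multiplicative gamma speckle of contrast 0.15
(unit mean). The depressions exceed the speckle SD by design.

**Longitudinal pairs** resample the baseline through a smooth random
displacement (default max 3 px; the numerical inverse is stored as the
registration ground truth), add new EZ-loss blobs of 0.052 ± 0.022 mm²
with a per-eye containment fraction drawn from 0.90–0.95 placed inside
the warped baseline IZ-loss class (remainder just outside it), and remove
an EZ recovery rim of 0.045 ± 0.023 mm² along the warped EZ border. The
baseline regime for the longitudinal study is an eye with an IZ-loss
annulus of 0.60 ± 0.15 mm² around established EZ loss of 0.40 ± 0.20 mm²
— the setting in which new EZ loss emerges at the reported rates.

**What passing tests do and do not show.** The generator reproduces the
measurement *structure* (nested classes, circumscribed vascular zones,
projection artifacts, speckle, smooth inter-visit deformation) and the
cohort statistics, not OCTA physics: no decorrelation noise model, no
B-scan volumes, no motion or shadow artifacts, no neovascular membranes.
Agreement of the pipeline with generator truth demonstrates internal
consistency of the operators and the statistics at realistic lesion
scales; it cannot certify accuracy on device images, where vessel
appearance and grader behaviour differ.

## Numerical choices and degenerate inputs

* Windowed mean/SD for the local threshold via three correlations with a
  clipped footprint — border behaviour is exactly the per-pixel loop's.
* A constant image: max-entropy raises (degenerate histogram; callers
  that need a mask catch this and return empty with a warning);
  Phansalkar returns all-background for non-positive constants.
* Nesting violations in supplied masks: default policy `clip` repairs
  (B := B ∩ A, C := C ∩ B) and logs the pixel count; `strict` raises.
* Empty telangiectasia → overlap percentages are NaN (missing), not 0.
* Registration that fails to improve on the identity logs a warning and
  returns the best field found; fields are bounded by a configurable
  maximum displacement sanity check.
* GEE mean parameters iterate to a 10⁻⁸ coefficient tolerance; a reached
  iteration limit on the dependence parameter is logged and the fit is
  rejected only if estimates are non-finite.
* Exact Spearman permutation p-values enumerate at most 10! pairings in
  vectorized chunks; above n = 10 the t-approximation is used.

## Problem sizes

The validation suite runs at the study's native scale: 304² images; 50
scenes per pooled group for cohort-target recovery; 50 longitudinal pairs
(each with a full affine + B-spline registration) for the predictive-value
regime; 10 pairs for registration fidelity; 1000 replicates at 600
clusters for the GEE calibration. These sizes keep every Monte-Carlo
standard error well below the tolerances they are compared against.

## Known limitations

* The printed group SDs are targets, not guarantees: stick-breaking and
  truncation reshape the dispersion of skewed cells (their means are
  exact; their SDs can be narrower than printed).
* The telangiectasia renderer and the circumscription operator were
  co-designed; the ±few-percent area agreement quantifies the operator's
  boundary behaviour, not performance on device angiograms.
* Real-eye severity staging is an input label here; the package does not
  grade OCT volumes.
* Predictive values are computed over 6-month intervals in the emulated
  regime; nothing is claimed about longer horizons, where EZ dynamics
  differ.
* The external-limiting-membrane status and subretinal neovascularization
  are out of scope.
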