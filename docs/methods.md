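# Methods

## Overview

`cephgrowth` quantifies where in a lateral skull image a CNN "looks" when
it estimates chronological age or classifies sex, and turns that into two
regional statistics: the Age-related Saliency Index (ASI) and the
Sex-related Saliency Index (SSI). Because the clinical radiographs such a
study would use are private, the package ships a phantom generator that
plants known growth and dimorphism structure into synthetic
cephalogram-like images, so the whole analysis chain — preprocessing,
proxy-task training, Grad-CAM attribution, population averaging,
percentile thresholding, ensemble ROI measurement — can be validated as a
recovery problem with a computable ground truth.

## Phantom model

A phantom is a `canvas_side`² grayscale image (default 128 px,
configurable up to 1000 px; all geometry is specified in canvas fractions)
containing six disjoint parametric regions in a fixed lateral-skull
arrangement: orbit (disk), zygoma and sphenoid and temporal (ellipses),
maxilla (quadrilateral), mandible (horseshoe polygon). Region *r* has a
logistic growth schedule

    g_r(age) = 1 / (1 + exp(-k_r (age - t0_r)))

and its linear size is `s_r(age) = s_r0 (1 + beta_r g_r(age))`. Male
subjects additionally receive a mandible size offset
`delta * d(age)` and a mandible density offset `0.10 * d(age)`, with the
dimorphism schedule `d(age) = ((age-4)/15)²` rising toward adulthood —
male mandibles are both larger and more radio-dense, and the difference
is negligible in childhood. Default schedule parameters:

| region   | beta | t0   | k   | notes                      |
|----------|------|------|-----|----------------------------|
| orbit    | 0.03 | 8.0  | 0.8 | nearly static              |
| zygoma   | 0.32 | 11.0 | 0.9 | late growth                |
| maxilla  | 0.32 | 10.5 | 0.9 | late growth                |
| sphenoid | 0.30 | 5.5  | 0.9 | early growth               |
| temporal | 0.32 | 5.0  | 0.9 | early growth               |
| mandible | 0.08 | 8.0  | 0.9 | delta=0.16, density 0.10   |

Early midpoints for temporal/sphenoid and late midpoints for
maxilla/zygoma make the regional age-information profile cross over
around age 8, which is the pattern the regional indices are asked to
recover. The ground truth for that recovery is
`planted_importance(spec, age)`: region scores proportional to
`|beta_r g_r'(age)|` (the rate of planted change), normalized to sum to 1.

Appearance inside a region is its base gray level plus band-limited
trabecular texture whose correlation length shrinks from 2.5 px to
1.0 px as the region matures (texture frequency rises with maturation).
Optional cues for sensitivity analyses — a remodeling-density boost, a
growth-front rim, and activity-scaled texture contrast, each proportional
to the normalized remodeling rate — are implemented but default to zero;
in calibration runs they made the proxy tasks harder without improving
index recovery.

Per-subject nuisances: global position jitter (sd 1.5 px at 128 px),
*per-region* fractional size jitter (sd 3%), multiplicative exposure gain
(0.9–1.1), additive Gaussian noise (sd 0.03 on a [0,1] scale), and a
random horizontal mirror (p=0.5) recorded as the subject's orientation.
The per-region size jitter matters conceptually: without it a region
whose schedule has saturated would still be a noiseless age readout, and
an estimator would have no reason to down-weight it.

What the phantom does **not** emulate: overlapping projected anatomy,
soft tissue and dentition, scanner artifacts, exposure gradients, and
anatomical covariance between regions. Passing recovery tests therefore
shows the analysis chain is sound and sensitive to planted structure —
not that the same indices computed on clinical images carry the same
meaning.

## Preprocessing

The deterministic chain is contrast-limited adaptive histogram
equalization (scikit-image CLAHE, clip limit 0.02, 8×8 tiles),
proportional rescaling so the longer side hits the target (short side
rounds half-up), and zero-padding to a square with the extra pixel on the
bottom/right; the geometry is captured in an invertible record so masks
and saliency maps stay co-registered. Training augmentation applies one
random affine (±5°, ±3% translation, scale 0.95–1.05) and a horizontal
flip (p=0.5) per sample per epoch. Orientation alignment uses the
recorded metadata, not a pixel heuristic.

For the phantom study the equalization step defaults to *off*: phantom
exposure is standardized by construction, and part of the planted signal
(the dimorphic density offset, region gray levels) is exactly the kind of
intensity contrast CLAHE is designed to flatten. On clinical data the
switch belongs on; it is one config flag.

## Networks and training

The desk-scale backbone (`small_cnn`) is four stride-2 3×3 conv blocks
(8, 16, 32, 64 channels), each conv followed by batch normalization and
ReLU, ending in the named feature stack (64 channels at input/16
resolution, i.e. 8×8 for 128-px inputs), global average pooling and a
linear head: one output for age regression, two (male, female logits) for
sex classification. Batch normalization is not cosmetic here — without it
the plain stack undertrains badly at these data sizes. Optional
squeeze-excitation gates and 1×1-conv projection stages exist for
experiments and default to off. A full-scale `efficientnet_b0`
configuration is recognized but not implemented in this build.

Losses are the batch-mean L1 for age and softmax cross-entropy for sex
(negative log-likelihood; the training layer codes male=1 while the
evaluation layer treats female as the positive class — the two
conventions live in separate modules). Training uses Adam with weight
decay 1e-4, learning rate 2e-3 decayed ×0.8 every 5 epochs, batch size 32
(16 for the small sex subsets), at most 100 epochs, early stopping after
3 consecutive epochs without ≥1e-4 validation-loss improvement, and the
best-validation parameters are returned. The patience rule engages only
after a 400-update burn-in: with a few hundred training images an epoch
is a handful of updates, and epoch-counted patience would otherwise stop
training on the initial plateau (a regime the rule's large-data origin
never encounters). Everything is float32 and fully seeded; two runs with
one seed are bit-identical.

## Grad-CAM and population averaging

For a target output (the predicted age, or one sex logit — by default the
true class) and feature stack `F^r`, the channel weight is the global
average gradient `alpha_r = (1/N_p) sum_ij dT/dF^r_ij`, the map is
`M = sum_r alpha_r F^r`, and the saliency map is `ReLU(M)`. Gradients are
taken through the head in inference mode (running BN statistics, no
updates), so the attribution is of the deterministic prediction function.
Maps are bilinearly upsampled (half-pixel convention) to the preprocessed
image frame, mirrored to the standard orientation when needed, and
averaged pixelwise within (age-bin, sex) groups of test subjects.
Saliency values stay raw everywhere; min–max normalization happens only
in the blue-to-red display overlays.

## Regional indices

For each (age-bin, sex) group, ROI templates are rendered at the bin
midpoint with zero jitter and perturbed into k=20 simulated annotator
replicas (small affine jitter: translation sd 1.5 px, rotation sd 2°,
scale sd 2%, plus ±1 px dilation/erosion; a replica that empties is
redrawn, then errors). The consensus mask is the pixelwise majority vote
(ties included). The threshold *t* is the 75th percentile
(linear interpolation between closest ranks) of all pixel values pooled
over the group's maps; a per-map scope is available by flag. The regional
index is the mean saliency over supra-threshold pixels (`S >= t` counts)
inside a mask, defined as 0 when no pixel clears the threshold; a
subject's value for a region is the mean over the 20 annotator masks, and
the group entry is the unweighted mean over the group's test subjects.
ASI and SSI are the same statistic computed from the age-task and
sex-task maps respectively and share one code path. An area-normalized
variant (divide by mask area instead of N_s) exists behind the
`region_mean_index`/`ensemble_index` building blocks for sensitivity
analyses via the returned counts.

## Study sizes and runtime

The standard study uses a 3000-subject cohort (uniform ages 4–19,
balanced sexes), sex × one-year-age-bin stratified 7:1.5:1.5 splits, one
age model per sex, and sex models on the age subsets. This size keeps a
full end-to-end run around six minutes on one CPU core while leaving the
age model's test MAE (~1.0–1.3 y) far below the ~3.75 y
predict-the-mean baseline. Replicate analyses use half-size cohorts; the
per-seed conclusions are unchanged at 1500.

## Known limitations

* **Raw regression saliency grows with predicted age on this model
  class.** With global average pooling and a (quasi-)linear head, the
  pre-ReLU Grad-CAM map decomposes the prediction: its pixel sum is tied
  to the predicted age minus an intercept, so rectified maps of older
  subjects are globally more intense. Consequently the ASI of an
  early-maturing region (temporal, sphenoid) does not *decline* in
  absolute value after its growth window here — it plateaus while the
  late-growing regions overtake it. The recoverable signatures at desk
  scale are relative: which regions dominate within an age bin, the
  adolescent dominance of maxilla/zygoma, and the mandible localization
  of the SSI. Calibration experiments with deeper nonlinear heads,
  squeeze-excitation gating, and rate-coded appearance cues did not
  change this at desk scale; breaking the amplitude coupling appears to
  need a feature-to-output map that is strongly nonlinear at the hook
  point, i.e. the deep-backbone regime.
* Within-bin ASI rankings correlate positively but imperfectly with the
  planted rate-based importance (mean Spearman ≈ 0.2–0.45 across
  calibration runs): activation magnitude tracks cumulative maturity,
  not purely the current rate, so regions that have finished growing
  keep mid-level saliency.
* The sex models are accurate only where the planted dimorphism is
  visible (near adulthood); at ages 6–15 their accuracy degrades toward
  chance by design, and their saliency maps are correspondingly noisy.
* Grad-CAM spatial resolution is input/16; regions span only a few
  feature cells at 128 px, so bilinear upsampling smears saliency across
  region boundaries and into the background pool that sets the
  threshold.
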