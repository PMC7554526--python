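# Methods

This note documents the models and procedures implemented in `wmlseg`, the
choices made where the design was genuinely open, and what the synthetic
data can and cannot show.

## Segmentation model

The segmenter is a 2D U-net: a contracting path of double 3×3
convolution + ReLU blocks with 2×2 max pooling, a bottleneck, and an
expanding path of nearest-neighbour 2× upsampling followed by a 3×3
convolution, with the encoder feature map of the matching resolution
concatenated before each decoder block. A final 1×1 convolution and
sigmoid produce a per-pixel lesion probability. All convolutions are
same-padded, so the output map has the input's spatial shape; the input
side must be divisible by 2^depth.

The network, its backward passes and the optimiser are implemented in
NumPy (float32, single CPU, `wmlseg._nn`). Convolutions are evaluated as
matrix products on im2col-unrolled patches. Backpropagation is verified
against finite differences in the test suite.

Choices the underlying publication record leaves open, fixed here:

- **Output activation**: sigmoid on a single logit channel; the loss is
  mean pixel-wise binary cross entropy (numerically stable log-sum-exp
  form). No class weighting.
- **Padding**: same-padding throughout (the classic valid-padding U-net
  crop bookkeeping is avoided).
- **Initialisation**: He-normal, seeded; parameter count is a
  deterministic function of the configuration.
- **Input conditioning**: preprocessed volumes arrive on the [0, 255]
  intensity scale; the network multiplies inputs by 1/255 so that
  He-initialised weights and the 0.01 learning rate are well posed.
- **Optimiser**: SGD with initial learning rate 0.01 and batch size 4.
  Plain SGD carries no momentum term; classical momentum 0.9 is the
  package default (configurable, `TrainConfig.momentum`) — the standard
  practitioner's choice, and necessary for convergence inside desk-scale
  epoch budgets. No learning-rate decay, no early stopping: a fixed epoch
  budget keeps variant comparisons fair.
- **Scale**: depth 2 and 8 base filters by default so the whole pipeline
  trains on one CPU in minutes; publication-scale settings (depth 4,
  64 filters, 100 epochs, 256×256) are plain configuration values.

Training is reproducible run-to-run for a fixed seed on one device;
across BLAS implementations bit-identity is not guaranteed.

## Variants

F (FLAIR → WML), Cascade (FLAIR → WML net, DWI → AIL net, final mask =
WML minus AIL), FD (FLAIR⊕DWI two-channel → WML). The cascade subtraction
operates on the binarized (0.5-thresholded) masks *before* the size and
white-matter filters, so the post-processing chain is identical across
variants; whether the original design subtracted probabilities or masks is
unstated, and the binarized reading keeps the containment property
(cascade output ⊆ WML-net output) exact. The AIL network uses the same
0.5 threshold as the WML network. All variants in a comparison share the
subject-level split (stratified by severity and AIL status), seeds, epoch
budget and augmentation stream.

## Augmentation

Five transforms drawn per slice per epoch, uniform over: rotation
[−30°, 30°], shift [−0.1, 0.1] *of the image side* per axis (the unit is
not stated in the source protocol; side-fraction is the common
convention), isotropic scale [0.95, 1.05], shear [0, 0.1] (a single bound
is stated; it is read as the upper end of a [0, 0.1] interval along the
row axis), horizontal flip with probability 0.5 (the anatomically
symmetric axis). The five are composed into one affine about the slice
centre and applied in a single resampling pass — linear interpolation for
images, nearest-neighbour for masks — so masks remain exactly binary and
interpolation blur is not compounded. Augmentation never touches
validation or test slices.

## Post-processing and rating

Pixels with probability strictly greater than 0.5 are lesion candidates
("over 0.5" is read as a strict inequality so behaviour at the boundary
is deterministic). Connected components — per-slice 8-connectivity by
default, because the network is slice-wise and lesions are counted in
pixels; 3D 26-connectivity via config — are removed if they have fewer
than 5 pixels or if their white-matter membership is below 0.4. The
membership statistic is the component-mean WM probability (robust to
boundary voxels; median/max available). WMLV is the surviving voxel count
times the voxel volume, in ml — the only dimensionally coherent reading
of "product of lesion volumes and voxel volume".

The 0–9 severity score is obtained by substituting the measured WMLV into
an ordinary least-squares line fitted on training subjects
(score = a·WMLV + b), rounding, and clamping to [0, 9]. The regression is
linear in WMLV (a log-WMLV predictor would be a one-line change; linear is
what the substitution procedure implies). Continuous scores are used for
correlation statistics, integers for reporting.

## Evaluation

- **Pixel level**: DSC, precision, recall from exact voxel-set counts.
  Empty-mask cases leave the affected metric *missing* (NaN), never 0,
  and missing values are excluded from group means with the effective n
  reported.
- **Lesion level**: a ground-truth component is detected (TP) if at least
  one voxel overlaps the prediction (an overlap-fraction criterion is
  exposed via `min_overlap`); a predicted component with no ground-truth
  overlap is FP. A lesion-wise "true negative" has no canonical
  definition on voxel sets; here TN = pre-filter candidate components
  that neither overlap the ground truth nor survive post-processing
  (correctly rejected candidates). Because that convention is a modelling
  choice, the per-subject report also carries the unambiguous
  false-discovery proportion fp/(fp + matched predictions). When a
  trained network produces few rejected candidates, FPR under this
  convention saturates; the FDP column is the robust quantity.
- **Subject level**: Spearman rank correlation (tie-corrected) and
  ICC(2,1) — two-way random effects, absolute agreement, single rater —
  with its analytic 95% CI, computed via `pingouin`; the test suite
  verifies the value against a closed-form two-way ANOVA decomposition.
- **Strata**: mild (WMLV ≤ 5 ml), moderate (5 < WMLV ≤ 20 ml), severe
  (> 20 ml); boundary volumes fall in the lower stratum. Severity and
  AIL-status groupings are each a partition of the cohort.

## Synthetic cohorts

The generator emulates the *structure* of a multi-centre FLAIR/DWI stroke
cohort, not its anatomy:

- **Phantom**: an ellipse-based head in 18–22 transverse slices (5–7 mm
  thick), with a GM rim, two ventricle-like CSF bodies, and WM interior;
  tissue probability maps at 0.95/0.02. End slices contain no brain, so
  slice selection is exercised.
- **Geometry**: pixel spacing is sampled in 0.43–0.49 mm *referenced to a
  256 matrix* and scaled by 256/matrix_size, keeping the field of view
  constant across resolutions — a severe (> 20 ml) lesion load therefore
  fits a 64×64 desk-scale grid exactly as it fits 256×256.
- **WML**: smoothed-disk blobs seeded in the white matter with a
  periventricular preference (exponential weighting on distance to CSF);
  total volume is hit *exactly* by trimming the last blob, so every
  subject lands inside its requested severity stratum. A load beyond
  ~80% of the eroded WM raises an infeasibility error.
- **AIL**: compact blobs (0.5–3 ml by default) in ~47% of subjects,
  disjoint from WML, bright on DWI *and* on FLAIR with the same intensity
  distribution as WML — the property that makes the identification
  problem non-trivial for FLAIR-only input.
- **Intensities**: piecewise-constant tissue means plus i.i.d. Gaussian
  noise (default SD 10 on a 0–255-ish scale); lesion contrast is kept at
  ≥ 3 noise SDs so lesions are learnable. No bias field, no partial
  volume, no MR physics.
- **True scores**: a monotone step function of WMLV — deciles of a
  log-spaced grid over 0–40 ml — standing in for a visual rating scheme;
  any monotone 0–9 map preserves the rating-regression logic under test.

What passing tests therefore show: the pipeline's algorithmic contracts
(metrics, filters, cascade algebra, rating recovery) hold exactly, and a
small U-net can learn high-contrast blob lesions and reproduce the
qualitative severity trend (severe segmented better than mild) on held-out
subjects. What they do not show: performance on real brains, where lesion
texture, bias fields, registration error and anatomical variability
dominate; published cohort-level numbers are not reproducible from
synthetic data and are not claimed.

## Problem sizes

Default desk-scale runs use 30 subjects at 64×64 with 12 slices, a
depth-2/8-filter network and 20 epochs (~2 minutes on one CPU); the
end-to-end test repeats this for three seeds and requires the DSC and
severity-trend properties to hold for the majority.

## Known limitations

- The NumPy network is single-threaded-CPU oriented; publication-scale
  training (100 epochs, 256×256, depth 4) is configured but slow.
- The lesion-level FPR depends on the TN convention discussed above.
- The phantom's tissue maps are near-binary; the WM-membership filter is
  exercised at its extremes, not at graded boundaries.
- DWI is simulated at the same matrix as FLAIR (co-registered, resampled
  upstream); the pipeline requires pre-aligned inputs.
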