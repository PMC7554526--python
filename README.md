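# wmlseg

Identification and segmentation of **white matter lesions (WML)** on FLAIR
MRI in subjects who may also carry **acute ischemic lesions (AIL)** — with
slice-wise U-net segmentation, rule-based post-processing, a lesion-volume
based 0–9 severity rating, and a three-level evaluation framework.

## The problem

WML (white matter hyperintensities) are chronic small-vessel lesions that
appear bright on FLAIR. In patients with recent ischemic symptoms, acute
infarcts (AIL) are *also* bright on FLAIR, and are distinguished clinically
by their hyperintensity on diffusion-weighted imaging (DWI). Quantifying the
WML burden in such patients therefore requires separating two lesion classes
with nearly identical FLAIR appearance. `wmlseg` implements and compares
three input configurations of a 2D U-net for this task:

| variant | input | networks |
|---|---|---|
| **F** | FLAIR | one net trained on WML truth |
| **Cascade** | FLAIR + DWI | WML net on FLAIR, AIL net on DWI; final mask = WML \\ AIL |
| **FD** | FLAIR ⊕ DWI | one net on the stacked two-channel input |

The pipeline around the networks is:

1. **Preprocess** — centre-crop/zero-pad each slice to a uniform matrix
   (default 256×256), discard slices without WM/GM/CSF content (by tissue
   probability maps), linearly rescale each modality volume to [0, 255].
2. **Augment** (training only) — per slice, per epoch: rotation [−30°, 30°],
   shift ±0.1 of the side, scale [0.95, 1.05], shear [0, 0.1], horizontal
   flip, composed into one affine applied jointly to image and mask.
3. **Segment** — 2D U-net (configurable depth and width), SGD on pixel-wise
   cross entropy, initial learning rate 0.01, batch size 4.
4. **Post-process** — threshold probabilities at 0.5; remove components with
   < 5 pixels or mean WM probability < 0.4; compute the WML volume
   WMLV = voxels × voxel volume (ml).
5. **Rate** — score = a·WMLV + b fitted by OLS on training subjects, rounded
   and clamped to the 0–9 burden scale.
6. **Evaluate** — pixel level (DSC, precision, recall), lesion level
   (component-wise TPR/FPR), subject level (Spearman r, ICC(2,1)), stratified
   by severity (mild ≤ 5 ml < moderate ≤ 20 ml < severe) and by AIL status.

Because multi-centre stroke cohorts are rarely redistributable, the package
ships a **synthetic cohort generator**: an ellipse-based head phantom with
tissue maps, WML of exactly controlled volume placed periventricularly, and
AIL that are bright on DWI and mimic WML on FLAIR. Every stage of the
pipeline is testable end-to-end on generated data. The U-net itself,
including backpropagation and the SGD loop, is implemented in NumPy and
trains at desk scale on a single CPU in minutes.

## Worked example

```python
from wmlseg import CohortSpec, generate_cohort, prepare_subject, run_variant
from wmlseg import fit_rating_model, evaluate_cohort

spec = CohortSpec(n_subjects=30, ail_fraction=0.47, matrix_size=64,
                  slice_count_range=(12, 12), seed=1)
subjects, manifest = generate_cohort(spec)
prepared = [prepare_subject(s) for s in subjects]

result = run_variant("F", prepared, depth=2, base_filters=8, epochs=20, seed=1)
train = [s for s in prepared if s.subject_id in set(result.train_ids)]
test  = [s for s in prepared if s.subject_id in set(result.test_ids)]
rating = fit_rating_model([s.true_wmlv for s in train], [s.true_score for s in train])
report = evaluate_cohort(test, result.predictions, rating_model=rating)

print(report.group_summary[["group", "n", "dsc_mean"]])
print(report.agreement)
```

On the 10 held-out subjects this prints (seed 1, ~2 min on one CPU):

```
      group   n  dsc_mean
0       all  10  0.739
1      mild   3  0.659
2  moderate   3  0.746
3    severe   4  0.794
...
AgreementStats(spearman_r=0.957, ..., icc=0.697, ..., n=10)
```

Mean held-out DSC is 0.74 and rises monotonically from mild to severe —
small lesion loads are dominated by boundary error, large confluent ones are
easy — and the predicted 0–9 scores track the true burden scores closely
(Spearman r = 0.96). The same computation is exposed on the command line:

```bash
wmlseg simulate cohort.yaml --out cohort/
wmlseg run --variant Cascade --cohort cohort/ --out run/ --epochs 20
wmlseg evaluate --predictions run/ --cohort cohort/ --out eval/
wmlseg report --summary eval/summary.json
```

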