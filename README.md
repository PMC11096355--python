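# lesiontrack

Longitudinal lesion response prediction for irradiated brain metastases.

After stereotactic radiosurgery, an enhancing nodule on follow-up MRI may
swell transiently (treatment effect) or grow because the tumour is
progressing — two radiologically similar conditions with very different
outcomes.  `lesiontrack` implements a complete comparison study for
predicting the dichotomised response (progressive disease, PD, vs
non-PD) from a sequence of up to four scans (one pre-treatment, three
follow-ups):

* a **synthetic cohort generator** producing four-timepoint,
  rim-enhancing lesion volumes (NIfTI) whose PD/non-PD labels follow an
  analytic RANO-style regrowth rule (≥20% and ≥1 mm over the
  post-treatment nadir), so ground truth is exact;
* the **preprocessing chain**: isotropic resampling, grey-matter-anchored
  normalisation to [−1, 1], lesion-centred 64×96×96 patches, tri-planar
  (axial/coronal/sagittal) decomposition;
* three **prediction arms** — maximum axial diameter (Dmax) sequences and
  radiomics sequences (first-order, shape, GLCM, GLRLM, GLSZM) into
  gradient-boosted trees, and a residual CNN encoder with a GRU sequence
  head (2D tri-planar or 3D), trained end-to-end with focal loss;
* **Eigen-CAM** saliency for the trained encoders; and
* the **evaluation protocol**: ten random 8:2 splits, AUC with
  Youden-optimal cutoffs, paired t-tests with Bonferroni correction, and
  a 1→4-timepoint ablation.

Arms follow a statsmodels-like pattern: a model object built from a
preprocessed cohort, a `fit()` that returns a results object, and
`predict()`/`summary()` on the results.

## Worked example

```python
import numpy as np
import lesiontrack as lt
from lesiontrack.models import CohortData, ConvGRUModel, DmaxBoostModel
from lesiontrack.evaluate import SplitPlan, make_splits

spec = lt.CohortSpec(n_cases=200, seed=11)          # ~24% PD prevalence
data = CohortData.from_spec(spec, lt.desk_profile())

train_ids, test_ids = make_splits(data.ids, SplitPlan(n_splits=1, seed=7))[0]
train, test = data.subset(train_ids), data.subset(test_ids)

res = ConvGRUModel(train, dims="2d").fit(seed=0)
auc = lt.roc_auc(res.predict(test), test.labels)
print(f"2D Conv-GRU held-out AUC: {auc:.3f}")

dmax = DmaxBoostModel(train).fit(seed=0)
print(f"Dmax held-out AUC: {lt.roc_auc(dmax.predict(test), test.labels):.3f}")
print(res.summary())
```

Output:

```
2D Conv-GRU held-out AUC: 0.990
Dmax held-out AUC: 1.000
2d Conv-GRU arm (4 timepoints)
================================================
encoder               2d residual CNN, width 0.25
feature dim           64
head                  gru
epochs                20
focal gamma / alpha+  2.0 / 0.738
final train loss      0.0290
n train cases         160
```

Both arms recover the analytic labels: on this synthetic cohort the
regrowth rule that defines PD is visible in the diameter sequence itself
(hence the near-perfect Dmax AUC), while the Conv-GRU must rediscover it
from the images.  On a cohort whose class signal is confined to the late
follow-ups (`CohortSpec(signal_onset=3)`), the Conv-GRU's AUC rises
steeply as scans are added — the follow-up-length ablation
(`lesiontrack.evaluate.run_timepoint_ablation`).

A CLI covers the pipeline stages (`lesiontrack synth | features |
evaluate | ablate | explain`); see `lesiontrack --help`.

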