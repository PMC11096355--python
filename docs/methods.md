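# Methods

`lesiontrack` models the problem of predicting, from a short longitudinal
series of contrast-enhanced MR volumes, whether an irradiated brain
lesion will ultimately progress.  Clinically this is hard because an
enhancing nodule often swells transiently after stereotactic
radiosurgery: early size changes do not determine the long-term outcome,
and the reference standard (RANO-style longest-diameter assessment over
extended follow-up) only becomes available months later.  The package
implements the full comparison study — simple diameter trajectories,
handcrafted radiomics, and an end-to-end CNN + recurrent sequence model —
on synthetic cohorts whose ground truth is analytic, so every stage is
testable without clinical data.

## Synthetic cohorts

Each case is one lesion observed at four timepoints: a pre-treatment scan
at month 0 and three follow-ups at intervals drawn from N(2.6, 0.66),
N(2.8, 1.3) and N(2.9, 1.2) months (clamped at one month).  The
pre-treatment equivalent diameter is drawn from N(14.1, 9) mm truncated
to [5, 58] mm; about 24% of cases are progressive (PD).  Trajectories:

* **non-PD** — multiplicative shrinkage at every follow-up (factor
  0.35–0.85 at the first follow-up, 0.5–1.0 subsequently); lesions below
  4 mm are treated as resolved and their masks become empty, which all
  downstream stages must tolerate.
* **PD** — initial partial response followed by regrowth such that the
  final diameter exceeds the post-treatment nadir by at least 20% *and*
  1 mm — the longest-diameter regrowth rule used for brain metastases.
  The label is therefore a deterministic property of the generating
  schedule, not an annotation.

Lesions are rendered as rim-enhancing ellipsoids (bright rim outside 70%
of the radius, darker core inside) with fixed per-case axis ratios
ordered ax ≥ ay ≥ az, so the axial equatorial section is the largest and
its in-plane extent equals the scheduled diameter.  The background is
uniform tissue (intensity 80) with additive Gaussian noise (SD 4), and a
small uniform blob of grey-matter intensity (100) provides the
normalisation reference point; with zero noise that voxel's intensity is
exact.  Default grid: 56×64×64 voxels at 1 mm isotropic spacing.

With `signal_onset=3` the PD first-follow-up shrinkage is drawn from the
*same* distribution as non-PD, confining all class signal to timepoints
3–4; this cohort variant drives the follow-up-length ablation.

What the generator deliberately does **not** emulate: brain anatomy,
MRI physics and bias fields, inter-timepoint registration error,
multi-lesion patients, and radiologist label noise.  Passing label
recovery here shows the pipeline is correct and can exploit longitudinal
shape/texture signal; it does not certify clinical accuracy.

## Preprocessing

Per timepoint: (1) resample image and mask to isotropic spacing
(trilinear / nearest-neighbour, edge-clamped so constant fields stay
constant; 0.5 mm at full scale); (2) normalise intensities to [−1, 1] by
`clip((I − I_gm)/max(I_max − I_gm, I_gm − I_min), −1, 1)` over
non-background voxels, so the grey-matter reference maps exactly to 0 and
background (below an absolute threshold, default 0) maps to −1; (3) crop
a fixed 64×96×96-voxel patch (32×48×48 at desk scale) centred on the
voxel-rounded mask centroid, padding out-of-volume regions with −1/0; a
vanished lesion reuses the most recent non-empty centroid; (4) for the 2D
arm, take the axial/coronal/sagittal planes through the centroid and
centre the non-square planes on a square canvas padded with −1.
Normalisation happens after resampling and before cropping; the
grey-matter voxel is carried across resampling through its physical
coordinate.

## Prediction arms

**Dmax.** The maximum axial diameter is measured on the axial slice with
the largest lesion area (ties to the lowest slice index) as the maximum
pairwise boundary-pixel distance plus one pixel pitch (an isolated pixel
has diameter = pixel size; an empty mask has diameter 0).  The four
per-timepoint diameters are concatenated in time order and classified
with gradient-boosted trees (XGBoost: depth 3, 200 rounds, learning rate
0.1, logistic objective — frozen here since no reference values exist).

**Radiomics.** A frozen 32-feature vector per timepoint: 12 first-order
statistics (entropy over a fixed-bin-width histogram, width 0.1 in
normalised units, bin edges on multiples of the width), 5 voxel-based
shape features (exposed-face surface area — whose sphericity for a ball
converges to 2/3, a documented property of face-count surfaces — plus
volume, maximum 3D diameter, elongation), and 5 features each from GLCM
(13 symmetric unit offsets, averaged, normalised), GLRLM (run-length
matrix averaged over the 13 directions) and GLSZM (26-connected zones).
Vanished lesions contribute an all-zero vector with a validity flag so
sequence length stays fixed.  Sequences are concatenated time-major and
classified with the same boosted-tree configuration.

**CNN + GRU.** A residual encoder in the standard 34-layer layout
(7-wide stride-2 stem, stages of basic blocks 3/4/6/3, global average
pool, linear projection) emits one feature vector per timepoint — 512-d
at full width.  The 2D variant consumes the three orthogonal slices as
the three input channels of a single encoder pass; the 3D variant
consumes the volumetric patch.  One encoder is shared across timepoints.
Two heads: concatenation of all timepoint features into one fully
connected layer (2048 inputs for 4×512), and a single-layer GRU (hidden
size = feature dim) whose final state feeds a linear logit; the GRU
accepts 1–4 timepoints, which enables the ablation.  Training is
end-to-end: Adam, 20 epochs, batch size 8, learning rate 1e-4 stepping
to 1e-5 for epochs 10–15 and 1e-6 after; focal loss with γ = 2 by
default (a per-fold grid search over {0, 1, 2, 5} maximising validation
AUC is available; α is fixed at the complement of the training positive
fraction); augmentation on training only — rotation ±30° (in-plane;
about the axial axis in 3D), scaling 0.85–1.15×, horizontal flip p =
0.5, per-axis translation ±10 px (±5 px at desk scale).  The network
engine is a compact numpy implementation with explicit backprop
(im2col convolutions, batch norm, max pool, GRU backprop-through-time),
written for exactness and desk-scale speed; its gradients are verified
against finite differences in the test suite.

The *desk profile* (quarter width, 64-d features, one block per stage,
32×48×48 patches at 1 mm) is a first-class configuration, not a fork: it
exercises every code path of the full-scale model at laptop cost.

## Saliency

Eigen-CAM: flatten the last convolutional block to positions × channels,
centre the columns, project every position onto the first right singular
vector, take absolute values (the principal direction's sign is
arbitrary), min–max normalise and upsample linearly to the input canvas.
Constant activation blocks yield an all-zero, flagged map.

## Evaluation protocol

Ten independent random 8:2 train/test splits at the case level
(re-randomised per split; an opt-in stratified variant guards small desk
cohorts against single-class test sets).  Per split and arm: rank-based
AUC with half credit for ties, and sensitivity/specificity at the
Youden-optimal cutoff (candidate thresholds at score midpoints; ties
broken toward higher specificity, then higher cutoff; cutoffs are
test-set-derived).  Arms are compared with two-sided paired t-tests over
the split AUCs, against a Bonferroni threshold of α/k (0.0125 at α =
0.05, k = 4); zero-variance difference vectors raise an error rather
than returning a silent p-value.  The ablation harness retrains the
GRU model on the first k ∈ {1, 2, 3, 4} timepoints with identical
splits and settings.

## Problem sizes and numerical choices

The packaged experiments use desk-scale sizes chosen to keep the whole
suite reproducible on one CPU: label recovery on a 200-case cohort with
a single 8:2 split (held-out Conv-GRU AUC, Dmax AUC, and a
permuted-label null), and the ablation on a 120-case late-signal cohort
with two splits and 12 epochs.  Probabilities inside the focal loss are
clamped to 1e-7; batch-norm uses ε = 1e-5 and momentum 0.1; Adam uses
the standard (0.9, 0.999) moments.  All randomness flows from explicit
integer seeds through `numpy.random.Generator`; repeated runs are
bit-reproducible.

## Known limitations

Synthetic lesions are single ellipsoidal nodules with stationary
centres; there is no registration error, necrosis geometry, or scanner
heterogeneity, so absolute AUCs here are upper bounds driven by the
analytic label rule, not estimates of clinical performance.  The
radiomics list is intentionally small and fixed; wavelet/filtered
features, feature selection and harmonisation are out of scope.  The
"Conv-GRU" uses a vector GRU over encoder features; a convolutional-gate
GRU over spatial maps is a possible alternative reading of the
architecture and was not implemented.
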