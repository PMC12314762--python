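# Methods

## Problem and model

`mipanomaly` implements one-class (anomaly-detection) cancer screening on
unilateral breast maximum-intensity-projection (MIP) images. A dynamic
contrast-enhanced MRI exam is reduced to a 2D subtraction MIP (first
post-contrast minus pre-contrast, negatives clipped, maximum projected),
split at the midline into two single-breast images in a canonical
orientation (chest wall on the left), and scored by a fully convolutional
network.

The core detector is a fully convolutional data description (FCDD) model.
A bias-free convolutional backbone maps an H×W image to a d×u×v feature map
φ(X) on a grid with cumulative stride s and receptive field r (both in
closed form from the layer spec). Each grid location gets a pseudo-Huber
anomaly score

    A_uv = sqrt(||φ_·uv||² + 1) − 1 ≥ 0,

and the breast-level score is the mean of the map, s(X) = mean(A). Training
minimizes the semisupervised one-class objective, per sample with label
y ∈ {0, 1}:

    ℓ = (1 − y)·s(X) − y·log(1 − exp(−s(X))),

which pulls benign images toward the hypersphere center and pushes labeled
malignancies away. `exp(−s)` is clamped to `1 − 1e−6` so the malignant
branch is finite at s = 0; benign-only training (no y = 1 terms) is a valid
degenerate case. Three comparators share the backbone: **FCDD-Symmetric**
scores each location by the pseudo-Huber distance to the contralateral
breast's feature vector (the opposite side acts as the normal-class center;
gradients flow through both branches of the shared backbone); **HSC**
applies the same loss to the globally pooled embedding (image-level only);
**BCE** is a conventional classifier (global average pool + linear logit,
sigmoid cross-entropy).

Because no deep-learning framework is part of the runtime, the backbone and
its training loop are implemented directly on NumPy (`_nn.py`): im2col
convolutions, scale-only batch normalization (no additive shift, so the
one-class objectives cannot collapse by translating features), leaky-ReLU,
and SGD with momentum 0.9, weight decay 1e−4 and cosine learning-rate decay.
All gradients are hand-derived and verified against central finite
differences in the test suite. Inputs are standardized per image
(zero mean, unit SD) at the stem; with bias-free convolutions this removes
the global enhancement offset so the detector responds to structure, not to
overall brightness. The backbone computes in float32 by default; a float64
mode exists for numerical verification.

Default backbone: four 3×3 conv layers (16→32→64→128 channels), stride-2
downsampling twice → cumulative stride s = 4, receptive field r = 13 px.
Default training: 50 epochs, batch 32, lr 1e−2. These are library defaults;
the experiment drivers use lighter, explicitly stated settings (below).

## Explanations

* FCDD maps are lifted to image resolution by a transposed convolution with
  a fixed (non-learned) Gaussian kernel of size r, stride s, σ = r/4
  (configurable), kernel normalized to sum 1. The operation is linear and
  conserves total score mass for maps supported away from the borders; the
  natural output is center-cropped to the image size.
* BCE and HSC are not spatially explainable by construction, so Grad-CAM
  saliency is provided: channel weights are the spatial means of the
  gradient of the target scalar (logit for BCE, pooled pseudo-Huber score
  for HSC) at the last conv layer; the map is ReLU(Σ_k w_k·act_k),
  bilinearly upsampled.
* Maps are min-max normalized either per breast ("local", for model-to-model
  comparison) or over the evaluated set ("global", for case-to-case
  comparison). Constant maps normalize to zero.
* Localization quality is pixelwise AUC: the rank-based (Mann-Whitney,
  ties counted half) AUC of map values against binary truth-mask labels.
  It is invariant under strictly monotone transforms of the map, hence
  insensitive to the normalization mode. Benign images have a single-class
  mask; their pixelwise AUC is undefined (NaN) and excluded from summaries.

## Synthetic phantoms

The phantom generator supplies cohorts with the statistical structure the
evaluation protocol assumes, with pixel-level ground truth and no data
download:

* **Breast region**: half-ellipse mask, chest wall flush with one edge.
* **Parenchymal texture**: low-pass Gaussian random field (σ = 6 px at the
  128×128 reference scale) with amplitude set by the exam's BPE category.
  Default amplitudes (0.05, 0.10, 0.16, 0.24) for minimal/mild/moderate/
  marked — a free modeling choice (no quantitative BPE-to-contrast mapping
  exists to copy), fixed once; it makes marked-BPE texture comparable to
  NME lesion contrast, reproducing the BPE confound. BPE mix
  (0.49, 0.30, 0.14, 0.07) follows a screening population's distribution
  renormalized over known categories.
* **Bilateral correlation**: left/right fields share a common component
  with weight ρ (default 0.85) plus independent components with weight
  sqrt(1 − ρ²); realized pixel correlation between sides is ρ². The right
  image is stored mirrored (anatomy facing the midline).
* **Lesions**: "mass" = anisotropic Gaussian bump, half-max radius 3–8 px,
  contrast 0.35–0.70, truth mask = half-max region; "NME" = thresholded
  mid-frequency noise inside a local disk, area 80–600 px², contrast
  0.12–0.30, irregular and possibly multi-lobed. Mix 0.65/0.35 (mass/NME),
  mirroring the lesion-type ratio of annotated explanation sets. Lesion
  geometry is quoted at the 128×128 scale and scaled with image size.
* **Cohort structure**: patients have 1–3 exams; at most one breast per
  exam is malignant; breast-level prevalence defaults to 20%. Malignant
  exams are flagged "known cancer" with probability 0.94, chosen so that
  excluding known-cancer exams leaves ≈1.85% prevalence — the balanced vs
  imbalanced task pair the evaluation protocol targets. A stage proxy bins
  truth-mask area at fixed cut points (85/175/440 px² at reference scale,
  ≈40/70/90% of the realized area distribution), so smaller-lesion bins are
  more populated.

What the phantoms deliberately do not model: MR physics, motion/bias-field
artifacts, 3D anatomy, chest-wall/axillary structures, multi-lesion breasts
(beyond NME lobes), and the appearance diversity of real parenchyma. Passing
the end-to-end criteria on phantoms therefore demonstrates that the method
and protocol are implemented correctly and behave as designed on data with
the assumed structure — not that the clinical performance numbers transfer.

## Evaluation protocol

* **Tasks**: "balanced" uses every image; "imbalanced" drops known-cancer
  images from test folds only (they remain available to training, which
  measurably helps the low-prevalence task).
* **Splits**: patient-grouped k-fold (default 5), patients shuffled by seed
  and partitioned; train/test patient sets are disjoint by construction.
* **Metrics**: ROC AUC (Mann-Whitney with tie correction) and AUPR as
  average precision (step-wise; its random baseline equals prevalence,
  which the report attaches alongside AUC's 0.5). Operating points: Youden
  (J = sens + spec − 1, ties broken toward higher specificity, so constant
  scores yield the all-negative rule) and fixed-sensitivity points (largest
  threshold with empirical sensitivity ≥ 95% or 97%; the constraint is met,
  not approximated). Sensitivity/specificity/PPV recompute exactly from the
  reported confusion counts.
* **Paired comparison**: two-sided Wilcoxon signed-rank over matched
  (fold, seed) metric cells; zero differences dropped; exact distribution
  for ≤25 tie-free pairs, normal approximation with tie correction
  otherwise; all-tied inputs return p = 1 by convention.
* **Bootstrap CIs**: percentile 2.5/97.5 over seeded resamples at breast
  level (patient-level clustering available via groups); single-class
  resamples are redrawn, and the metric is declared unstable if more than
  half the draws fail.
* **Strata**: per-BPE / lesion-type / stage summaries with counts; small or
  single-class strata are flagged, never silently dropped.

## Experiment scales and numerical choices

The experiment drivers (`experiments.py`, also used by
`scripts/acceptance.py`) state their problem sizes explicitly, chosen for
single-CPU runtimes of minutes:

* Balanced task: 200 patients (~680 breasts) at 64×64, light backbone
  (8/16/32/32 channels, s = 4, r = 13), 30 epochs, lr 0.05, one grouped
  fold held out. Typical results at these scales: image-level AUC ≈ 0.95,
  mean pixelwise AUC ≈ 0.98 on malignant test images.
* Imbalanced comparison: disjoint train (100 patients, balanced
  composition including known cancers) and test (700 patients, known-cancer
  exams excluded → ≈1.5–2% prevalence) cohorts at 48×48; FCDD and BCE each
  trained with 8 seeds, 12 epochs, lr 0.01; specificity at 97% sensitivity
  compared pairwise by seed. Eight seeds gives the two-sided exact Wilcoxon
  enough resolution that one tied or weakly reversed pair still resolves
  below p = 0.05 (a uniformly consistent ordering gives p = 2/2⁸ ≈ 0.008);
  a six-seed design would sit exactly at its p = 0.03125 floor and fail on
  any single tie.

Other numerical conventions: the ε = 1e−6 clamp inside log(1 − exp(−s));
quantile clipping (0, 0.995) before min-max scaling in preprocessing
(constant images map to zeros); bilinear resampling aligns output corners to
input corners; the midline defaults to W/2 (phantoms are centered by
construction) and is overridable per image; MIPs project the full volume
(slab projection is a possible variant, not implemented); all randomness
derives from one global seed through named child seeds so paired tests stay
paired across reruns.

## Known limitations

* The NumPy training loop is single-threaded and memory-bound; it is sized
  for phantom-scale experiments, not clinical datasets.
* FCDD-Symmetric pairs features after the full backbone (one design among
  several; a frozen-contralateral variant would be a one-line change).
* PPV at operating points is raw empirical PPV, not prevalence-adjusted.
* Grad-CAM at the last conv layer inherits that layer's resolution; maps
  for very small lesions are correspondingly coarse.
* Pixelwise AUC is computed on raw maps; by monotone invariance this
  matches locally normalized maps exactly, and globally normalized maps
  per image as well.
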