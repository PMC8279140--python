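# Methods

## Problem and data model

A pneumothorax annotation is a binary mask over a 1024×1024 grayscale
radiograph, stored as one or more *relative* run-length strings: the first
token is an absolute flat pixel index, and each later run starts at
`previous_start + previous_length + gap`. The worked example
`247981 1 1022 2 1021 3` decodes to pixels {247981, 249004, 249005,
250027, 250028, 250029}. The format does not itself state the flattening
order or index base — the example's gaps (≈ width − 2) are consistent with
several dialects — so the codec defaults to **column-major, 0-based**
(matching the challenge's reference encoder) and exposes both choices as
flags. Multiple strings per image are merged by pixelwise OR at load time;
malformed strings raise an error naming the image rather than being
skipped, since silently dropped annotations would bias training. About 22%
of images are positive; an image with no finding is stored as `-1` and its
correct prediction counts as Dice 1 under the competition convention.

## Networks

Each segmentation network is a U-Net whose encoder is a classification
backbone truncated before global pooling and classifier. The decoder has
five blocks; blocks 1–4 upsample 2× by nearest neighbor, concatenate an
encoder tap, and apply two 3×3 conv(+BN)+ReLU; block 5 has no skip. The
head is a 3×3 conv to one channel plus a sigmoid clamped to
[1e−7, 1 − 1e−7] so float32 saturation never emits exact 0/1. Inputs must
be divisible by 32 (five downsampling stages).

Tap placement is a genuine design freedom ("the corresponding part of the
encoder" admits several readings); the package fixes it per backbone to
the convention that reproduces the reference models' parameter budgets:

| preset | taps (stride 2 → 16) | bottleneck | params |
|---|---|---|---|
| resnet50_unet | stem ReLU, stages 1–3 (64/256/512/1024) | stage 4 (2048) | 32.5 M |
| densenet169_unet | stem ReLU, transition 1×1-conv outputs pre-pool (64/128/256/640) | final BN-ReLU (1664) | 19.4 M |
| se_resnext50_unet | as ResNet-50, with grouped convs + SE (reduction 16) | 2048 | 34.5 M |
| efficientnetb4_unet | expansion activations of the stride-2 blocks (144/192/336/960) | 1×1 head conv (1792) | 25.6 M |

The alternatives (pre-compression DenseNet taps, EfficientNet block
outputs) land 9–10% away from the published budgets and were rejected on
that ground. SE-ResNeXt-101 and EfficientNet-B3 presets exist for
completeness; `tiny_unet` (five plain conv-BN-ReLU stages, ~0.27 M params
with its decoder) exists so training tests run in seconds on a CPU.

All of this runs on an in-package numpy autodiff engine (`pneumoseg.nn`):
tape-based reverse mode, shift-and-matmul convolution (exact transpose in
the backward pass, no im2col buffer, vectorized grouped/depthwise paths),
batch normalization composed from differentiable primitives, max/avg
pooling, nearest upsampling and SE gating. Gradients of every op are
checked against central finite differences in the test suite. ImageNet
pre-training is supported only as a load path for weight files already on
disk; tests use seeded He-normal initialization throughout.

## Training

Loss: mean BCE plus soft Dice, `BCE + 1 − (2Σpy + ε)/(Σp + Σy + ε)` with
ε = 1 (stabilizes empty masks) and probabilities clamped before logs. The
learning rate follows a single cosine cycle stepped per epoch — the
published schedules are stated as epoch-level start/end pairs, and nothing
suggests warm restarts, so the cyclic variant is deliberately not used.
Recipes ship as presets (optimizer, LR endpoints, batch size, epochs, SWA
window): SGD m = 0.9, 1e−3 → 1e−5, batch 10, 60 epochs, SWA 5 for
ResNet50-UNet; Adam 1e−4 → 1e−6, batch 6/6/4, 80 epochs, SWA 4/3/4 for
DenseNet169 / SE-ResNeXt50 / EfficientNetB4.

"SWA" is implemented as **terminal checkpoint averaging**: the element-wise
mean of the last k epoch weights. With a monotone single-cycle schedule
there are no cyclic snapshots, so this is the only consistent reading.
Because averaged weights shift every layer's activation statistics, BN
running moments are recomputed afterwards with one cumulative-average pass
over the training inputs (without this the averaged model is unusable).
Per-epoch logs report loss and IoU with predictions binarized at 0.5.

## Prediction and post-processing

Flip TTA averages the prediction with the unflipped prediction of the
mirrored input. Ensembling is a pixelwise weighted average with weights
normalized to sum 1 — the published best weights (40/40/20/20 for
EfficientNetB4/SE-ResNeXt50/DenseNet169/ResNet50) sum to 1.2 as printed,
and an unnormalized average would push probabilities above 1 and silently
re-scale every threshold. The alternative 10/10/40/40 weighting from the
published weight-trial table ships as a second named preset; the
discrepancy between the two is left unadjudicated.

Binarization uses the strict inequality (P > B-TH → 1; P = B-TH → 0).
Small-object removal keeps only components *strictly larger* than R-TH
pixels, 8-connected, applied by default at native 1024×1024 resolution
after bilinear upscaling of the probability map, so R-TH counts refer to
native pixels (thresholding at model resolution first is available behind
a flag; which order the reference pipeline used is unstated). A whole-mask
removal mode is also provided because "remove small objects" is ambiguous
between readings and both appear in competitor systems.

The search grid is B-TH ∈ {0.20 + 0.01·i : i < 70} — the stated count (70)
and range ("0.2 to 0.9, step 0.01") are jointly consistent only with an
exclusive upper bound, so 0.89 is the last value — crossed with R-TH ∈
{absent, 1024, 2048, 3072, 4096} (350 points). The objective is macro mean
per-image IoU with both-empty = 1 (the convention is published for Dice;
extending it to IoU keeps threshold tuning from penalizing correct
negatives). Ties break toward the least aggressive setting: lowest B-TH,
then R-TH absent, then smallest R-TH.

## Metrics

Per-image IoU and Dice are macro-averaged; both return 1 when prediction
and truth are both empty. Confusion-based rates (accuracy, precision,
recall, F-measure) are micro-averaged over pooled pixels, with 0 returned
on zero denominators. PSNR is computed on masks rescaled to {0, 255} with
peak 255; identical masks yield a documented +∞ sentinel (capped on
request), and the dataset value is the per-image mean. Whether the
reference validation IoU was micro- or macro-aggregated is unstated; macro
is used because the tuning objective is per-image.

## Synthetic phantoms

The fixture generator emulates the *geometry and statistics* of the task,
not radiographic appearance: elliptical lung fields on a body oval,
Gaussian pixel noise (σ = 8 gray levels), and 1–3 crescent-shaped lesions
(a disk minus an offset equal disk, centred on the lung-field boundary)
per positive image. Defaults mirror the corpus statistics: 22% positive
images, per-lesion area 0.5–8% of pixels. Surrogate probability maps are
clipped(blurred mask + Gaussian noise), which reproduces the qualitative
behaviour that matters for threshold search — graded boundaries, noise
floor, monotone IoU degradation with noise. What phantoms cannot show:
anatomical confounders (ribs, clavicles, tubes), realistic lesion texture,
inter-annotator variability, or the transfer-learning benefit of real
pre-trained encoders. Passing tests therefore certify the pipeline's
mechanics and conventions, not clinical performance; the published
leaderboard scores additionally require the external dataset, ImageNet
weights and GPU-scale training, and are out of scope.

## Numerical choices and problem sizes

Images and probability maps resize bilinearly; masks resize
nearest-neighbor and are re-thresholded, so binarity is preserved at every
stage. float32 throughout the networks; Dice ε = 1.0; BCE clamp 1e−7.
Augmentation probabilities (flip 0.5, shift-scale-rotate 0.5 with ±20°,
shift 0.0625, scale 0.1, one-of distortion 0.5, one-of intensity 0.5,
crop area ∈ [0.81, 1.0] for ResNet50-UNet only) are declared defaults —
the reference menu lists the transforms but not their rates. Test problem
sizes are chosen for seconds-scale CPU runs: 64–128 px phantoms, the
tiny preset for training (8 images, 30 epochs, ~5 s), full presets built
and run forward at 64/128 px for contract checks. The training smoke test
uses Adam 5e−3 → 5e−5, batch 4 — a rate at which the tiny model visibly
overfits within 30 epochs.

## Known limitations

* The numpy engine is single-threaded BLAS-bound; full-preset *training*
  at 512 px is out of reach (and out of scope) — the full presets are
  exercised for construction, parameter budgets and forward contracts.
* SE-ResNeXt101-UNet lands ~7% under its published parameter budget under
  every standard tap placement; the four reference presets match within 1%.
* DICOM support is single-frame 8-bit (the corpus format); multi-frame and
  12/16-bit windowing are not implemented.
* The cosine schedule is single-cycle by design; cyclic SWA snapshotting
  is not offered.
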