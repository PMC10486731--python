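# Methods

## Problem and model

Each eye is observed through up to two OCTA acquisitions — a 6×6 mm
high-resolution scan (`hr6`) and a 15×15 mm ultra-widefield scan
(`uwf15`) — each a rank-4 volume (X lateral, Y depth, Z lateral, 2
channels: structure = reflectance, flow = decorrelation). The label is an
ordinal severity grade g ∈ {0..5} on the ICDR scale, with panretinal
photocoagulation (PRP) ranked above PDR and grouped with it for the
severest binary task. The classifier outputs a 6-class probability vector
p; four cumulative task scores s_k = Σ_{j>k} p_j (k = 0..3) serve the
binary detection tasks "grade ≥ k+1". By construction s_0 ≥ s_1 ≥ s_2 ≥ s_3.

The proposed hybrid architecture is:

* per acquisition, **hierarchical fusion** of structure and flow: two
  single-channel backbone branches plus a fusion branch that, at each of
  four scales s, computes f_s = ReLU(stage_s(f_{s−1}) + proj_s([b1_s, b2_s]))
  where proj_s is a 1×1×1 convolution + batchnorm to the branch width and
  stage_s a stride-2 3×3×3 convolution + batchnorm (absent at the first
  scale); the decision head is a linear layer on
  [b1 pooled, b2 pooled, fusion pooled];
* across acquisitions, **decision fusion by averaging** of the two
  acquisition-level aggregated probability vectors (and task-score
  vectors). The max rule takes the elementwise maximum and renormalises
  the probability vector to sum 1 so the output stays on the simplex —
  the aggregation rule itself does not fix a normalisation, and
  renormalisation is the choice that keeps the output a probability.

Inference uses N-times random crop: N random sub-volumes are classified
and combined by the *severest prediction* rule. Severest is made
operational in two parts: per task, the aggregated score is the maximum of
the per-crop cumulative scores (a proper ranking score for ROC analysis,
monotone in N); the discrete grade is the severest per-crop argmax grade,
tie-broken toward the crop most confident in that grade. Crops are
aggregated within each acquisition first and acquisitions decision-fused
second, matching a fusion that operates on each branch's final output
probability. If one acquisition is missing at predict time, the hybrid
model falls back to the available branch and logs a warning.

## Preprocessing

Surface segmentation is unspecified in most clinical pipelines at this
level of detail; here it is per-A-scan maximum positive gradient of the
depth-smoothed (Gaussian σ = 1.5 voxels) structure channel for the ILM,
and the brightest voxel at least 5 % of the depth below it for the RPE
(the hyper-reflective RPE line), both followed by 5×5 lateral median
filtering. A volume whose maximum depth gradient is below 0.05 raises a
surface-not-found error. Flattening shifts each A-scan so the ILM sits at
depth 0 and resamples the [ILM, RPE] band to D_target samples by linear
interpolation (the band is "resized"; linear is the simplest interpolant
that preserves constants, and identity resampling is exact).

Cropping: the sub-volume grid tiles each axis at stride = patch size with
the last window clamped flush to the boundary, which makes the grid length
equal the ceil-count ∏ ⌈dim/patch⌉ — 9 patches for 500×224×500×2 and 16
for 834×224×834×2 with 224³×2 patches. Random crops draw origins uniformly
over all in-bounds positions. When an axis is shorter than the patch
(possible for depth at small scales) the volume is padded symmetrically
with zeros first. Axes are 0-based (X, Y depth, Z, channel), channels
ordered [structure, flow].

## Backbones and numerical choices

The three classifiers are 3D conversions of ResNet50, DenseNet121 and
EfficientNetB0: every 2D convolution/pool becomes its cubic counterpart,
stage layout unchanged, trained from scratch. `width_mult` scales all
channel counts (floor 8) so quarter-width models train on a CPU. Stage
downsampling uses stride-2 padded convolutions, so spatial sizes follow
ceil division (a 56³ input gives ResNet stage maps of 14³, 7³, 4³, 2³).

The networks run on a small reverse-mode autodiff engine (`octafuse.nn`)
written on numpy: convolutions are lowered to BLAS matrix products via
sliding windows, with depthwise convolution, batchnorm (running statistics,
momentum 0.1, ε = 1e-5), max/average/global-average pooling, SiLU/sigmoid
for the squeeze-excite blocks, softmax cross-entropy, Adam and exponential
learning-rate decay. Two standard trainability measures are built in:
inputs are centred at network entry ((x − 0.35)/0.35, matching the typical
intensity level of the synthetic volumes), and the last batchnorm scale of
every residual/skip-connected block is zero-initialised so blocks start as
identities; without them the 50-layer stack optimises far too slowly at
small batch sizes to be usable on a CPU.

## Training protocol

Patients are split at the patient level: the test set is drawn only from
patients with both acquisitions in every eye (so all fusion variants score
the same eyes); the rest are dealt into five folds stratified by worst-eye
grade, greedily filling the smallest fold within each grade group so fold
sizes and grade distributions stay balanced. Training uses one random crop
per example per epoch, unweighted 6-class cross-entropy, Adam with
exponential decay (γ = 0.99 per epoch), and mild augmentation: gamma in
[0.7, 1.5], Gaussian noise at 2 % of the dynamic range, and flips on the
two lateral axes only — the retina is oriented in depth, so depth flips are
forbidden. The checkpoint-selection metric is the validation mean of
AUC0–AUC3 (kappa as tie-break), evaluated with a deterministic center-crop
prediction every few epochs; the test set is never consulted during
training. Class imbalance is handled only through stratified splitting.

## Scale profiles

The nominal profile records the full-size protocol: 500×224×500×2 and
834×224×834×2 volumes, 224³×2 patches, N = 10/20 inference crops,
full-width backbones, learning rate 1e-4, batch 2, 500 epochs. The desk
profile divides the lateral/depth geometry by 14 — 36×16×36 and 60×16×60
volumes with 16³×2 patches, which preserves the 3×1×3 and 4×1×4 traversal
tilings — and scales the inference crops proportionally (N = 5/8). Because
total gradient steps shrink by orders of magnitude at this size, the desk
schedule uses batch 4, learning rate 1e-3 and 20 epochs: batch 2 leaves
batchnorm statistics too noisy, and 1e-4 moves a freshly initialised
network too little, for the step counts a desk run affords. Desk
experiments use 120 fully paired patients (240 eyes), a 25 % test
fraction, and quarter-width ResNet50 branches.

## Synthetic cohort generator

The generator emulates the structure the framework assumes, not OCT
physics. Per eye it draws a severity grade from a configurable
distribution (default: the class proportions of a paired clinical DR
cohort, roughly 19/10/47/14/3/6 % from grade 0 to 5), then renders each
requested acquisition from one shared physical lesion layout in
millimetre coordinates:

* **Geometry** — ILM depth is a shallow bowl plus a smooth random field;
  band thickness ≈ 30 % of the raw depth; a bright line marks the RPE; the
  vitreous is dark, giving the segmenter a well-posed gradient. Both
  acquisitions use the same axial sampling grid (1536 × scale samples), a
  simplification of device-specific axial resolutions; both are flattened
  to the same D_target afterwards, as in the nominal pipeline.
* **Channels** — structure is a layered intensity profile of relative
  depth; flow is a smoothed-noise filament texture confined to the inner
  band. Gaussian noise (σ = 0.04) is added to both.
* **Lesions** — Gaussian-profiled multiplicative flow voids with matched
  50 % structural dimming. Central voids (radius 0.55–0.95 mm, within
  2.2 mm of the fovea) appear from grade 1 and saturate at moderate
  disease (counts 0/2/4/5/5/5); they render at full amplitude (0.85) in
  the high-resolution scan but at 0.30 in the widefield scan, mimicking
  its coarser sampling. Peripheral non-perfusion patches (radius
  1.2–2.2 mm, Chebyshev radius > 3.4 mm, hence outside the 6×6 mm field
  of view) appear from grade 3 with growing burden (0/0/0/2/5/9). This
  saturating-central / growing-peripheral design is what makes early
  grades separable mainly on `hr6` and late grades mainly on `uwf15`, the
  property the hybrid fusion exploits; lesion sizes were chosen so the
  signal is learnable by quarter-width CNNs at desk scale.
* **Registration** — the two acquisitions of an eye share the lesion
  layout but receive independent lateral jitter (±0.25 mm), so paired
  volumes are deliberately unregistered.

What the generator does **not** model: speckle statistics, real vascular
topology, projection artifacts, segmentation failures on pathology, media
opacity, inter-device variation. Passing tests therefore demonstrate that
the pipeline's machinery behaves as specified and that fusion recovers a
designed complementarity; they say nothing quantitative about clinical
performance.

## Degenerate inputs and tie-breaks

AUC is the tie-aware Mann–Whitney statistic (half credit for ties —
max-aggregated scores collide often) and is undefined (error) when only
one class is present; per-task AUCs missing a class are reported as NaN
and excluded from mean AUC. Kappa is undefined for a single-cell confusion
matrix (chance agreement 1). `aggregate_severest` of a single crop is the
identity; decision fusion of an empty list is an error. Center crops use
origin ⌊(dim − patch)/2⌋ per axis.

## Known limitations

Desk-scale results are stochastic: orderings between single-acquisition
models are stable across seeds by design margin, but absolute AUC/kappa
values vary by several points between seeds and should only be read
relative to each other. Six-class kappa is low at desk scale — with ~20
epochs and 180 training eyes the models learn the lesion-burden signal
well enough for the cumulative tasks but not for precise grade boundaries.
Mixed-architecture hierarchical fusion (e.g. ResNet + EfficientNet
branches) is supported through the stage-count-aligned pyramid abstraction
but is not the default, and cross-acquisition feature fusion is provided
with both full and head-only fine-tuning but is not part of the proposed
hybrid configuration.
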