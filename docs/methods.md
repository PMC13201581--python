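# Methods

This note documents the models, algorithms, and numerical choices behind
`lobeprior`, and what the phantom-based validation does and does not show.

## Problem setting

The five pulmonary lobes (LLL, LUL, RLL, RML, RUL) are separated by thin
fissures that are frequently incomplete or invisible on CT, especially under
consolidations, nodules, or collapse. Pure image-driven segmentation then
leaves holes or mislabeled regions inside the lung. The pipeline combines a
learned segmenter with an explicit anatomical prior: a probabilistic atlas of
lobe occupancy built by label fusion over co-registered annotated scans,
used both as a soft input channel to the network and as the authority that
fills low-confidence gaps during post-processing.

Label codes are fixed throughout: 0 BG, 1 LLL, 2 LUL, 3 RLL, 4 RML, 5 RUL,
6 airway. Internally all grids use canonical (Z, H, W) axis order with
0-based voxel indices; NIfTI I/O transposes at the boundary.

## Preprocessing

CT volumes are resampled to isotropic 1 mm voxels (trilinear for
intensities; labels always travel through a separate nearest-neighbor
path), clipped to [-1024, 600] HU — the window that retains parenchyma and
fissure contrast — and mapped linearly onto [0, 1]. Resampled shape per axis
is round-half-away-from-zero of `shape * spacing / target`; sampling is
corner-aligned so an identity resample is exact.

## Probabilistic atlases

Given co-registered label maps Y_1..Y_N of one anatomical group g, the raw
prior for lobe k is the voxel-wise label fraction

    P~_k(v) = (1/N_g) Σ_i 1(Y_i(v) = k),

smoothed with an isotropic 3D Gaussian (σ = 1.0 voxel on the 1 mm grid,
i.e. 1 mm) and renormalized so Σ_k P_k(v) = 1 wherever the raw channels
have support; where no member places any lobe, all channels stay 0 rather
than being renormalized, so the prior is silent outside its support.

Groups are formed on mutually registered label maps: members whose
mean-over-five-lobes Dice reaches 0.80 are linked, and groups are the
connected components of that graph (single-linkage at the 0.80 cut). Each
group's reference volume is its medoid — the member with the highest mean
Dice to the rest. Group count is data-driven, not fixed.

For a new scan, the input is registered to every group reference and each
registration scored with

    score = w_MSE · 1/(1 + MSE) + w_NCC · (NCC + 1)/2 + w_MI · MI,

all weights 1. MSE is the mean squared intensity difference, NCC the global
Pearson correlation in [-1, 1], and MI the joint-histogram mutual
information (32 bins per axis over [0, 1], natural log, so MI(x, x) is the
marginal entropy in nats). The highest-scoring reference wins; ties break
to the lowest group id.

## Registration

Alignment is center-of-mass initialization (translation between
intensity-weighted centroids, in mm) followed by multi-resolution
symmetric-forces demons, a diffeomorphic-style solver suited to the
single-modality setting (both images are normalized CT). The pyramid runs
coarse to fine with shrink factors 2^(L-1)..1; the iteration schedule
[10000, 1000, 100] caps the per-level demons iterations at full scale
(an RMS-change criterion of 0.005 stops levels early), and desk-scale runs
pass reduced schedules such as [100, 50, 25]. Update and total fields are
Gaussian-smoothed (σ = 1 voxel) for regularity.

Transforms store dense displacement fields in voxel units: the forward
field, on the fixed grid, resamples a moving-space image into fixed space;
the inverse field is computed by fixed-point inversion of the forward field
and maps the other way. The rigid pre-alignment is folded into both fields.
Registration quality is monitored by the mutual information between the
fixed image and the warped moving image; if no pyramid level improves on
the rigid initialization, the best transform seen is returned with a
warning. Each level's field is scored at full resolution and the best
kept, so a diverging fine level cannot undo a good coarse solution.

Transforms are cached on disk (NIfTI displacement pair + JSON metadata)
keyed by a content hash of (fixed image, moving image, schedule, engine
version), which makes repeated predictions of the same scan skip
registration entirely.

On 64³ phantoms warped by a known smooth field, registering back recovers
per-lobe label overlap of Dice ≥ 0.9 and the forward∘inverse composition
has mean residual displacement well under one voxel; both are asserted in
the test suite.

## Network

Both stages use a 3D attention U-Net: encoder channels double per level
(depth 2 at desk scale; stage 1 uses base width 8, stage 2 base width 4 —
stage 2 receives the prior and coarse masks as inputs and trains well at
lower capacity), 3³ same-padding convolutions with ReLU, 2× max-pooling,
nearest-neighbor upsampling, and a spatial attention gate per skip
connection — a sigmoid heatmap computed from 1³ convolutions of the
gating (decoder) and skip features, multiplied onto the skip before
concatenation. A 1³ input projection mixes input channels before the first
3³ convolution.

- **Stage 1** takes the whole CT at low resolution (128³ at full scale,
  32³ at desk scale) and emits seven structure activations: the five lobes,
  the whole lung, and the airway. Because the whole lung is a superset of
  the lobes, these cannot share one softmax: the head is a 6-way softmax
  over background + lobes plus two sigmoid auxiliary channels (lung,
  airway).
- **Stage 2** refines on the working grid over sliding-window patches
  (128³ full scale, overlap 0.5, overlapping predictions averaged; desk
  scale uses 48³ patches that cover the whole phantom, so every structure
  is present in every training sample — sub-volume patches of the small
  phantoms leave near-empty structure targets whose Dice terms are
  unstable at batch size one). Its 13 input channels are the CT (1), the warped group prior
  (5), and the stage-1 activations upsampled trilinearly (7) — continuous,
  not binarized, so calibration information survives. One shared encoder
  feeds seven independent decoders, one per structure, each ending in a
  1-channel sigmoid head. The prior enters as a soft input channel, never
  as a hard constraint: stage 2 runs unchanged with the prior zeroed.

The network layer is a small tape-based reverse-mode autodiff on numpy
arrays written for this package (stride-1 im2col convolutions, float32).
Gradients of every op are verified against central finite differences in
the test suite.

Training minimizes 1 − mean per-structure soft Dice over the seven
foreground structures (smooth term ε = 1e-5); background is handled
implicitly by the stage-1 softmax. Restricting the Dice average to
foreground structures avoids the all-background collapse that a
background-inclusive Dice exhibits on class-imbalanced volumes, and
structures absent from a training sample are skipped in the mean so a
patch missing a structure exerts no collapse pressure on its decoder. The
optimizer is AdamW (weight decay 1e-5) with per-epoch exponential learning
rate decay 0.985 and the lowest-validation-loss checkpoint retained. The
full-scale protocol uses lr 1e-4 for ~50 epochs; the desk-scale
configuration uses lr 1e-2 for ≤20 epochs, which the small phantom networks
need to converge within a single-CPU budget. Stages train sequentially;
stage 1 is frozen when its predictions are generated for stage-2 inputs.

Train/validation splitting is by case ID (80/20), never by row, so the two
sets are disjoint at the phantom/patient level.

## Augmentation

Lesion insertion copies a pre-registered lesion (intensities + binary
footprint) into a target lung. The lesion's first two moments — computed
over its blend core, the region where the Gaussian-blurred footprint weight
exceeds 0.99, because the rim mixes lesion and parenchyma — are affinely
matched to the surrounding lung tissue (lung mask minus footprint, airway
excluded). The blend weight w = GaussianBlur(footprint ∩ lung, σ = 2 vox by
default) clipped to [0, 1] and zeroed outside the lung mixes
`w·lesion' + (1−w)·target`; voxels beyond the blur support stay
bit-identical and lesions never paint outside the lung. A lesion that
misses the lung entirely is skipped with a warning.

The full augmentation draw applies, in order: optional lesion insertion
(p = 0.5), scaling (0.9–1.1), rotation (±10° about a random axis pair),
per-axis mirroring, Gaussian noise (SD ≤ 0.02), Gaussian blur, brightness
(±0.1) and contrast (0.8–1.2) jitter, and a random crop (128³ full scale).
Geometric transforms hit the labels with nearest-neighbor interpolation;
intensities are clipped back to [0, 1]. Everything is driven by one seeded
generator.

## Post-processing

Each decoder's sigmoid is binarized at 0.5; only positive activations
indicate presence. Per structure decoder, only the largest 26-connected
component remains a candidate. The whole-lung decoder acts as a background
indicator — activations outside its region are discarded — with one
anatomical refinement: the two lungs are spatially disjoint, so the lung
region keeps up to two dominant components (second one admitted at ≥10% of
the largest) instead of a single largest component, which would amputate
one lung. Among candidates at a voxel the highest activation wins; exact
ties go to the lowest channel index. Lung voxels with no candidate are
gaps: they receive the argmax lobe of the warped prior where it has
support, else the lobe of the nearest labeled voxel. The airway is never
prior-filled (the prior has only lobe channels). After filling, each lobe
is reduced to one connected component and stray unlabeled lung voxels are
re-assigned by nearest label. Finally the working-space result is mapped
through the inverse displacement field (nearest-neighbor) and resampled
onto the native grid.

## Evaluation metrics

- Dice = 2|A∩B|/(|A|+|B|); empty-vs-empty defined as 1 (logged).
- Average Hausdorff distance: boundary voxels are mask voxels with ≥1
  6-neighbor outside; the metric is the symmetric mean of directed average
  boundary-to-boundary distances (exact Euclidean distance transform, mm).
- Absolute volume similarity = 1 − ||A|−|B||/|B| clipped to [0, 1]
  (1 = identical volumes; higher is better).

Reports are per structure plus the arithmetic mean over the five lobes,
with optional severity stratification on the known lesion fraction
(<5% mild, 5–25% moderate, >25% severe).

## Synthetic phantoms

The phantom generator emulates the *label topology* of chest CT, not its
appearance: two ellipsoidal lungs, the right split into three lobes and the
left into two by tilted gently-curved surfaces, thin bright fissure sheets,
a three-generation branching airway tube, and optional bright spherical
lesions strictly inside the lobes. Intensities are authored in HU
(parenchyma ≈ −850..−730 HU with distinct per-lobe bases, fissures −500 HU,
airway −1000 HU, lesions ≈ −120 HU, background 0 HU) and pass through the
real preprocessing. Cohorts share one base geometry deformed per member by
smooth Gaussian-filtered random displacement fields (default RMS 1 voxel,
chosen so whole-lung pairwise Dice stays above the 0.8 grouping threshold,
mirroring an anatomically homogeneous group).

Deliberate simplifications: per-lobe intensity offsets make lobe identity
partly readable from intensity alone (real lobes differ only at fissures);
there is no vasculature, no respiratory motion, no scanner artifact model.
Passing tests therefore demonstrates that the machinery — registration,
fusion, grouping, two-stage learning, prior filling, inverse mapping — is
correct and well-calibrated at desk scale, not that the shipped defaults
reach clinical accuracy on real CT; that requires full-scale training on
annotated scans.

## Problem sizes and numerical choices

Desk-scale experiments (the test suite and the acceptance script) use 48³
phantoms, stage-1 grid 32³, stage-2 whole-volume 48³ patches, demons
schedules of [100, 50, 25] or smaller, 8-case training cohorts, and ≤20
epochs (stage 1: 20 at width 8; stage 2: 12 at width 4). Full-scale defaults in `PipelineConfig` keep the published
protocol (128³, [10000, 1000, 100], 50 epochs, lr 1e-4).

Other fixed choices: trilinear interpolation for intensities everywhere,
nearest-neighbor for labels; 26-connectivity for components; argmax ties to
the lowest index; Dice smooth ε = 1e-5; MI histogram 32 bins; float32
network arithmetic; all RNG flows from one config seed through named
substreams (init / sampling / augmentation).

## Known limitations

- The demons engine assumes a shared voxel lattice for fixed and moving
  images after rigid pre-alignment (always true after isotropic
  preprocessing at matched FOV); cross-shape registration is not supported.
- Atlas construction registers all members to member 0 before grouping; a
  pathological first member would bias the common space. Group references
  (medoids) are chosen after grouping, but members are not re-registered
  to their medoid.
- The prior cannot fill airway gaps, and prior filling is restricted to the
  network's own lung region, so a failed lung segmentation is not rescued
  by the atlas.
- Stage-2 patch sampling uses a fixed seeded set of lung-centered patches
  per training epoch set, not fresh patches per epoch.
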