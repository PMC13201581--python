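# lobeprior

Prior-guided multi-stage segmentation of the five pulmonary lobes on chest
CT, built for scans where the lobar fissures are incomplete or hidden by
severe abnormalities (consolidations, nodules, collapse).

The lobes — left lower (LLL), left upper (LUL), right lower (RLL), right
middle (RML), right upper (RUL) — are separated by thin fissures that
standard segmenters lose under disease, leaving holes and mislabeled
regions inside the lung. `lobeprior` combines a learned segmenter with an
explicit probabilistic anatomical prior so that low-confidence regions are
resolved by expected lobe location rather than left unlabeled.

## Method

**Probabilistic atlases by label fusion.** Co-registered annotated scans
are grouped by structural similarity (pairwise mean-lobe Dice ≥ 0.80,
groups = connected components of that graph). Per group *g* and lobe *k*,

&nbsp;&nbsp;&nbsp;&nbsp;P̃⁽ᵍ⁾ₖ(v) = (1/N_g) Σᵢ 𝕀(Yᵢ(v) = k),

smoothed with a 3D Gaussian (σ = 1 mm) and renormalized so Σₖ Pₖ(v) = 1 on
the atlas support. A new scan is matched to its group by registering it to
every group reference (center-of-mass init + multi-resolution
diffeomorphic demons) and maximizing the composite score

&nbsp;&nbsp;&nbsp;&nbsp;w_MSE · 1/(1+MSE) + w_NCC · (NCC+1)/2 + w_MI · MI  (all w = 1).

**Two-stage attention U-Net.** Stage 1 segments the whole CT at low
resolution (lobes + whole lung + airway; 6-way softmax over BG + lobes
plus two sigmoid auxiliary heads). Stage 2 refines over sliding-window
patches from a 13-channel input — CT (1) + warped prior (5) + stage-1
activations (7) — through one shared encoder and seven independent
sigmoid decoders with spatial-attention-gated skips. Training minimizes
1 − mean per-structure soft Dice with AdamW (weight decay 1e-5,
exponential LR decay 0.985), keeping the lowest-validation-loss weights.

**Prior-guided post-processing.** Decoder activations above 0.5 compete by
magnitude (largest connected component per structure; the whole-lung
decoder gates everything as a background indicator). Lung voxels claimed
by no decoder are *gaps* and receive the argmax lobe of the warped prior;
the result is mapped back to native space through the inverse displacement
field.

Everything is exercisable end to end on synthetic 3D lung phantoms (five
lobes, fissures, a branching airway, optional lesions), so the pipeline is
fully testable without clinical data. Training-time augmentation includes
synthetic lesion insertion with intensity matching and Gaussian-edge
blending.

See `docs/methods.md` for assumptions, parameter meanings, and limits.

## Worked example: prior-based hole filling

Build an atlas from a six-phantom cohort, carve a hole out of the right
lower lobe of one member (emulating a consolidation the network cannot
label), and let the prior fill it:

```python
import numpy as np
from lobeprior.phantom import PhantomSpec, make_cohort
from lobeprior.prior_model import build_atlas, fill_from_atlas
from lobeprior.volume_io import LabelMap, normalize_hu

cohort = make_cohort(6, PhantomSpec(seed=3))
members = [(normalize_hu(ct), lab) for ct, lab in cohort]
atlas = build_atlas(members, sigma=1.0)
print(f"atlas channels sum to 1 on support: "
      f"{np.abs(atlas.probs.sum(0)[atlas.support] - 1).max():.2e}")

ct, lab = cohort[0]
carved = lab.labels.copy()
center = np.argwhere(carved == 3).mean(axis=0).astype(int)
sl = tuple(slice(c - 5, c + 5) for c in center)
hole = np.zeros(carved.shape, bool)
hole[sl] = carved[sl] == 3
carved[hole] = 0
print(f"carved a {int(hole.sum())}-voxel hole out of the right lower lobe")

lung = (lab.labels >= 1) & (lab.labels <= 5)
filled = fill_from_atlas(LabelMap(carved, lab.spacing, lab.affine), lung, atlas)
acc = (filled.labels[hole] == 3).mean()
print(f"prior fill relabeled {acc:.1%} of the hole as RLL; "
      f"{int((lung & (filled.labels == 0)).sum())} lung voxels left unlabeled")
```

Output:

```
atlas channels sum to 1 on support: 2.22e-16
carved a 973-voxel hole out of the right lower lobe
prior fill relabeled 100.0% of the hole as RLL; 0 lung voxels left unlabeled
```

The atlas assigns every carved voxel back to the correct lobe because the
cohort's fused label fractions peak at RLL there — exactly the mechanism
that repairs consolidation-induced gaps at full scale.

## Command line

```bash
lobeprior phantom --out phantom0 --shape 48 --seed 0 --lesions 2
lobeprior build-atlas --images cases/ --out atlases/ --dice-threshold 0.80
lobeprior train --manifest manifest.json --config config.yaml
lobeprior predict --input ct.nii.gz --out seg.nii.gz --config config.yaml
lobeprior evaluate --pred seg.nii.gz --ref truth.nii.gz --csv metrics.csv
```

Label codes in outputs: 0 BG, 1 LLL, 2 LUL, 3 RLL, 4 RML, 5 RUL,
6 airway (documented in a JSON sidecar next to each segmentation).

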