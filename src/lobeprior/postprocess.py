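"""Stage 3: fuse the seven decoder activations into one label map, clean it,
fill lung gaps from the probabilistic prior, and map back to native space.

Fusion rules: each decoder uses an independent sigmoid, so one voxel may be
claimed by several structures. Candidates are activations above 0.5 (only
positive sigmoid responses indicate presence), restricted to the largest
connected component of each structure decoder's binarized output; among
candidates the highest activation wins (ties break to the lowest channel
index). The whole lung decoder acts as a background indicator: activations
outside its mask are disregarded. Because the two lungs are disjoint, the
lung region keeps the two dominant components rather than a single one. Lung voxels claimed by no structure become gaps, later
filled with the lobe the warped prior considers most probable.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .network import AIRWAY_CH, LUNG_CH, N_STRUCTURES, StagePrediction
from .prior_model import ProbAtlas, fill_from_atlas
from .registration import Transform, apply_transform
from .volume_io import CTVolume, LabelMap, resample_labels_to

log = logging.getLogger(__name__)

_CONN26 = np.ones((3, 3, 3), dtype=bool)


def largest_component(mask: np.ndarray) -> np.ndarray:
    """Largest 26-connected component of a binary mask (empty -> empty)."""
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        return np.zeros_like(mask)
    lab, n = ndimage.label(mask, structure=_CONN26)
    if n == 1:
        return mask.copy()
    counts = np.bincount(lab.ravel())
    counts[0] = 0
    return lab == counts.argmax()


def lung_components(mask: np.ndarray, max_components: int = 2,
                    min_fraction: float = 0.1) -> np.ndarray:
    """Dominant components of the whole-lung mask.

    The two lungs are spatially disjoint, so a strict largest-component rule
    would amputate one of them; instead the union of up to two components,
    each at least ``min_fraction`` of the largest, forms the lung region.
    """
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        return np.zeros_like(mask)
    lab, n = ndimage.label(mask, structure=_CONN26)
    counts = np.bincount(lab.ravel())
    counts[0] = 0
    order = np.argsort(counts)[::-1]
    keep = [order[0]]
    for idx in order[1:max_components]:
        if counts[idx] >= min_fraction * counts[order[0]]:
            keep.append(idx)
    return np.isin(lab, keep)


@dataclass
class FusionResult:
    labels: LabelMap
    lung_mask: np.ndarray
    gap_mask: np.ndarray
    provenance: np.ndarray  # 0 bg, 1 network, 2 prior-fill, 3 fallback


def fuse_decoders(pred: StagePrediction, threshold: float = 0.5,
                  spacing=(1.0, 1.0, 1.0), affine=None) -> FusionResult:
    """Combine 7 sigmoid activation maps into a 7-class label map (pre-fill)."""
    act = np.asarray(pred.activations)
    if act.shape[0] != N_STRUCTURES:
        raise ValueError("expected 7 structure channels")
    if act.min() < 0 or act.max() > 1:
        raise FloatingPointError("activations must lie in [0, 1]")
    shape = act.shape[1:]
    lung_mask = lung_components(act[LUNG_CH] > threshold)

    # candidate masks: above-threshold, largest component per decoder
    cand = np.zeros_like(act, dtype=bool)
    for c in (0, 1, 2, 3, 4, AIRWAY_CH):
        cand[c] = largest_component(act[c] > threshold)

    # argmax over candidate activations only; outside lung -> background
    masked = np.where(cand, act, -1.0)
    masked[LUNG_CH] = -1.0  # lung channel is an indicator, not a label
    best = masked.argmax(axis=0)  # ties -> lowest channel index via argmax
    has_cand = masked.max(axis=0) > -1.0
    labels = np.zeros(shape, dtype=np.int16)
    assign = has_cand & lung_mask
    # channels 0..4 -> lobe codes 1..5; channel 6 -> airway code 6
    labels[assign] = np.where(best[assign] == AIRWAY_CH, 6,
                              best[assign] + 1).astype(np.int16)
    gap_mask = lung_mask & (labels == 0)
    provenance = np.zeros(shape, dtype=np.int8)
    provenance[labels > 0] = 1
    if affine is None:
        affine = np.eye(4)
        affine[0, 0], affine[1, 1], affine[2, 2] = spacing
    lm = LabelMap(labels, np.asarray(spacing, dtype=float), affine)
    return FusionResult(lm, lung_mask, gap_mask, provenance)


def finalize(fr: FusionResult, atlas: ProbAtlas | None, t: Transform | None,
             native: CTVolume) -> LabelMap:
    """Clean, prior-fill, and map the fused result back to native space.

    ``atlas`` must already be warped onto the working grid (or None to skip
    prior filling); ``t`` maps working (fixed) space back to native (moving)
    space via its inverse, or None if the working grid is the native grid.
    The airway is never prior-filled (the prior has only lobe channels).
    """
    seg = fr.labels
    cleaned = seg.labels.copy()
    for code in range(1, 7):
        m = cleaned == code
        keep = largest_component(m)
        cleaned[m & ~keep] = 0
    working = LabelMap(cleaned, seg.spacing.copy(), seg.affine.copy(),
                       seg.class_names)
    if atlas is not None:
        working = fill_from_atlas(working, fr.lung_mask, atlas)
    else:
        gaps = fr.lung_mask & (working.labels == 0)
        if gaps.any():
            filled = working.labels.copy()
            lobed = (filled >= 1) & (filled <= 5)
            if lobed.any():
                _, idx = ndimage.distance_transform_edt(~lobed, return_indices=True)
                filled[gaps] = filled[idx[0][gaps], idx[1][gaps], idx[2][gaps]]
            working = LabelMap(filled, working.spacing, working.affine,
                               working.class_names)

    # enforce one component per lobe after filling, re-assigning stragglers
    final = working.labels.copy()
    for code in range(1, 6):
        m = final == code
        keep = largest_component(m)
        final[m & ~keep] = 0
    holes = fr.lung_mask & (final == 0) & (working.labels != 6)
    if holes.any():
        lobed = (final >= 1) & (final <= 5)
        if lobed.any():
            _, idx = ndimage.distance_transform_edt(~lobed, return_indices=True)
            final[holes] = final[idx[0][holes], idx[1][holes], idx[2][holes]]
    working = LabelMap(final, working.spacing, working.affine,
                       working.class_names)

    if t is not None:
        working = apply_transform(t, working, "inverse")
    return resample_labels_to(native, working)
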