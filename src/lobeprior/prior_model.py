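"""Probabilistic lobe atlases: grouping by label similarity, label fusion,
atlas selection by a composite similarity score, and prior-based gap filling.

An atlas is built per anatomical group by voxel-wise label fusion: for each
lobe k, the fraction of co-registered members labeling each voxel k,

    P~_k(v) = (1/N_g) sum_i I(Y_i(v) = k),

smoothed with an isotropic 3D Gaussian (sigma = 1.0 voxel on the 1 mm grid)
and renormalized so the five channels sum to 1 wherever the pre-smoothing
fields have support (outside support, all channels stay 0).

Groups are the connected components of the graph linking pairs of registered
label maps whose mean-over-lobes Dice reaches a threshold (default 0.80).

A new scan is matched to a group by registering it to every group reference
and scoring each with

    score = w_mse/(1 + MSE) + w_ncc (NCC + 1)/2 + w_mi MI,

all weights 1 by default; the highest-scoring reference wins.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy import ndimage
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components

from . import registration as reg
from .metrics import LOBE_CODES, mean_lobe_dice
from .similarity import mse, mutual_information, ncc
from .volume_io import CTVolume, LabelMap, read_volume, write_volume

log = logging.getLogger(__name__)


@dataclass
class ProbAtlas:
    """Five-channel lobe-probability field plus its group reference volume."""

    probs: np.ndarray  # (5, Z, H, W), channel k-1 = lobe code k
    reference: CTVolume
    group_id: int
    n_members: int
    sigma: float = 1.0

    def __post_init__(self):
        if self.probs.shape[0] != len(LOBE_CODES):
            raise ValueError("atlas must have one channel per lobe")
        if self.n_members < 1:
            raise ValueError("atlas needs at least one member")

    @property
    def support(self) -> np.ndarray:
        return self.probs.sum(axis=0) > 0

    def argmax_labels(self) -> np.ndarray:
        """Most probable lobe code per voxel (0 outside support)."""
        out = np.where(self.support, np.argmax(self.probs, axis=0) + 1, 0)
        return out.astype(np.int16)


@dataclass
class GroupAssignment:
    groups: list  # list of lists of member indices
    threshold: float
    dice_matrix: np.ndarray

    def group_of(self, member: int) -> int:
        for gi, g in enumerate(self.groups):
            if member in g:
                return gi
        raise KeyError(member)


def pairwise_lobe_dice(labels: list[LabelMap]) -> np.ndarray:
    """Symmetric matrix of mean-over-lobes Dice between registered label maps."""
    shapes = {l.shape for l in labels}
    if len(shapes) > 1:
        raise ValueError("label maps must share one grid (register them first)")
    n = len(labels)
    d = np.eye(n)
    for i in range(n):
        for j in range(i + 1, n):
            d[i, j] = d[j, i] = mean_lobe_dice(labels[i].labels, labels[j].labels)
    return d


def group_by_dice(labels: list[LabelMap], threshold: float = 0.80) -> GroupAssignment:
    """Partition members into connected components of the Dice >= threshold graph.

    Deterministic given input order: groups are sorted by their smallest
    member index, members ascending within a group.
    """
    d = pairwise_lobe_dice(labels)
    return group_from_matrix(d, threshold)


def group_from_matrix(dice_matrix: np.ndarray, threshold: float = 0.80) -> GroupAssignment:
    """Grouping from a precomputed pairwise similarity matrix."""
    d = np.asarray(dice_matrix, dtype=float)
    adj = csr_matrix((d >= threshold).astype(np.int8))
    n_comp, comp = connected_components(adj, directed=False)
    groups = [sorted(np.flatnonzero(comp == c).tolist()) for c in range(n_comp)]
    groups.sort(key=lambda g: g[0])
    return GroupAssignment(groups=groups, threshold=threshold, dice_matrix=d)


def build_atlas(members: list, sigma: float = 1.0, group_id: int = 0,
                reference: CTVolume | None = None) -> ProbAtlas:
    """Label-fusion atlas from co-registered (CTVolume, LabelMap) members.

    The reference defaults to the medoid member: the one with highest mean
    lobe Dice to all other members.
    """
    if not members:
        raise ValueError("cannot build an atlas from an empty member list")
    label_maps = [m[1] for m in members]
    shapes = {l.shape for l in label_maps}
    if len(shapes) > 1:
        raise ValueError("members must be co-registered to one grid")
    n = len(members)
    raw = np.stack([
        np.mean([(l.labels == k) for l in label_maps], axis=0, dtype=np.float64)
        for k in LOBE_CODES
    ])
    support = raw.sum(axis=0) > 0
    probs = np.stack([ndimage.gaussian_filter(c, sigma) for c in raw])
    total = probs.sum(axis=0)
    norm = support & (total > 0)
    probs[:, norm] /= total[norm]
    probs[:, ~norm] = 0.0
    if reference is None:
        if n == 1:
            reference = members[0][0]
        else:
            d = pairwise_lobe_dice(label_maps)
            medoid = int(np.argmax((d.sum(axis=1) - 1.0) / (n - 1)))
            reference = members[medoid][0]
    return ProbAtlas(probs, reference, group_id=group_id, n_members=n, sigma=sigma)


def composite_similarity(fixed: CTVolume, warped_moving: CTVolume,
                         w_mse: float = 1.0, w_ncc: float = 1.0,
                         w_mi: float = 1.0) -> float:
    """Weighted MSE/NCC/MI score; higher means more similar."""
    if fixed.shape != warped_moving.shape:
        raise ValueError("composite similarity requires one common grid")
    a, b = fixed.intensities, warped_moving.intensities
    return (w_mse / (1.0 + mse(a, b))
            + w_ncc * (ncc(a, b) + 1.0) / 2.0
            + w_mi * mutual_information(a, b))


def select_atlas(input_ct: CTVolume, atlases: list[ProbAtlas],
                 levels=reg.DEFAULT_LEVELS, cache_dir=None):
    """Register the input to every atlas reference and keep the best score.

    Returns (atlas, transform) where the transform maps input (moving) to the
    winning reference (fixed). Ties break toward the lowest group_id.
    """
    if not atlases:
        raise ValueError("select_atlas needs at least one atlas")
    if len(atlases) == 1:
        a = atlases[0]
        t = reg.register_with_cache(a.reference, input_ct, levels, cache_dir)
        return a, t
    best = None
    for a in sorted(atlases, key=lambda a: a.group_id):
        t = reg.register_with_cache(a.reference, input_ct, levels, cache_dir)
        warped = reg.apply_transform(t, input_ct, "forward")
        score = composite_similarity(a.reference, warped)
        log.info("atlas group %d similarity %.4f", a.group_id, score)
        if best is None or score > best[0]:
            best = (score, a, t)
    return best[1], best[2]


def fill_from_atlas(seg: LabelMap, lung_mask: np.ndarray, atlas: ProbAtlas) -> LabelMap:
    """Assign unlabeled lung voxels the atlas argmax lobe (nearest-label fallback).

    Voxels outside ``lung_mask`` and airway voxels are untouched. Where the
    atlas has no support, the lobe label of the nearest labeled voxel is used.
    """
    lung_mask = np.asarray(lung_mask, dtype=bool)
    if seg.shape != lung_mask.shape or seg.shape != atlas.probs.shape[1:]:
        raise ValueError("seg, lung_mask, and atlas must share one grid")
    out = seg.labels.copy()
    gaps = lung_mask & (out == 0)
    if not gaps.any():
        return LabelMap(out, seg.spacing.copy(), seg.affine.copy(), seg.class_names)
    support = atlas.support
    atlas_arg = atlas.argmax_labels()
    use_atlas = gaps & support
    out[use_atlas] = atlas_arg[use_atlas]
    rest = gaps & ~support
    if rest.any():
        lobed = (out >= 1) & (out <= 5)
        if not lobed.any():
            raise ValueError("no labeled voxels available for fallback filling")
        _, (iz, ih, iw) = ndimage.distance_transform_edt(~lobed, return_indices=True)
        out[rest] = out[iz[rest], ih[rest], iw[rest]]
    return LabelMap(out, seg.spacing.copy(), seg.affine.copy(), seg.class_names)


# ---------------------------------------------------------------------------
# atlas construction from a cohort, and on-disk persistence


def build_group_atlases(cohort: list, threshold: float = 0.80, sigma: float = 1.0,
                        levels=reg.DEFAULT_LEVELS, cache_dir=None):
    """Full atlas-construction path from preprocessed (CTVolume, LabelMap) pairs.

    All members are registered to a common reference (member 0), grouped by
    pairwise mean-lobe Dice of the registered labels, and fused per group.
    Returns (list of ProbAtlas, GroupAssignment, registered label maps).
    """
    ref_ct = cohort[0][0]
    warped = []
    for i, (ct, lab) in enumerate(cohort):
        if i == 0:
            warped.append((ct, lab))
            continue
        t = reg.register_with_cache(ref_ct, ct, levels, cache_dir)
        warped.append((reg.apply_transform(t, ct, "forward"),
                       reg.apply_transform(t, lab, "forward")))
    assignment = group_by_dice([w[1] for w in warped], threshold)
    atlases = [
        build_atlas([warped[i] for i in g], sigma=sigma, group_id=gi)
        for gi, g in enumerate(assignment.groups)
    ]
    return atlases, assignment, warped


def save_atlas(atlas: ProbAtlas, out_dir) -> None:
    """Persist an atlas as one NIfTI per channel + reference + JSON metadata."""
    d = Path(out_dir)
    d.mkdir(parents=True, exist_ok=True)
    for ci in range(atlas.probs.shape[0]):
        ch = CTVolume(atlas.probs[ci], atlas.reference.spacing,
                      atlas.reference.affine, normalized=True)
        write_volume(ch, d / f"prob_lobe{ci + 1}.nii.gz")
    write_volume(atlas.reference, d / "reference.nii.gz")
    (d / "atlas.json").write_text(json.dumps({
        "group_id": atlas.group_id,
        "n_members": atlas.n_members,
        "sigma": atlas.sigma,
        "reference_normalized": bool(atlas.reference.normalized),
    }))


def load_atlas(atlas_dir) -> ProbAtlas:
    d = Path(atlas_dir)
    meta = json.loads((d / "atlas.json").read_text())
    probs = np.stack([
        read_volume(d / f"prob_lobe{k}.nii.gz").intensities
        for k in range(1, len(LOBE_CODES) + 1)
    ])
    ref = read_volume(d / "reference.nii.gz")
    ref.normalized = meta.get("reference_normalized", True)
    return ProbAtlas(probs, ref, group_id=meta["group_id"],
                     n_members=meta["n_members"], sigma=meta["sigma"])
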