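"""Segmentation quality metrics: Dice, average Hausdorff distance, volume
similarity, with per-structure reports and severity stratification.

- Dice = 2|A∩B| / (|A| + |B|); empty-vs-empty is 1.0 by convention.
- Average Hausdorff distance (AHD) is the symmetric mean of directed average
  boundary distances, in mm: (mean_{a∈∂A} d(a, ∂B) + mean_{b∈∂B} d(b, ∂A))/2.
  Boundary voxels are mask voxels with at least one 6-neighbor outside the
  mask; distances are Euclidean between voxel centers (exact EDT).
- Absolute volume similarity (AVS) = 1 − ||A| − |B|| / |B| clipped to [0, 1],
  so 1 means identical volumes and higher is better.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .volume_io import LabelMap

log = logging.getLogger(__name__)

LOBE_CODES = (1, 2, 3, 4, 5)

#: Default severity buckets on the lesion (involvement) fraction of lung volume.
SEVERITY_BUCKETS = (("mild", 0.05), ("moderate", 0.25), ("severe", np.inf))


def _check_grids(pred, ref):
    if pred.shape != ref.shape:
        raise ValueError(f"grid mismatch: {pred.shape} vs {ref.shape}")


def dice(pred: np.ndarray, ref: np.ndarray) -> float:
    """Dice overlap of two binary masks; both empty -> 1.0."""
    pred = np.asarray(pred, dtype=bool)
    ref = np.asarray(ref, dtype=bool)
    _check_grids(pred, ref)
    denom = int(pred.sum()) + int(ref.sum())
    if denom == 0:
        log.debug("dice of two empty masks, returning 1.0 by convention")
        return 1.0
    return 2.0 * int(np.logical_and(pred, ref).sum()) / denom


def boundary_voxels(mask: np.ndarray) -> np.ndarray:
    """Mask voxels with >= 1 face (6-)neighbor outside the mask."""
    mask = np.asarray(mask, dtype=bool)
    eroded = ndimage.binary_erosion(
        mask, structure=ndimage.generate_binary_structure(3, 1), border_value=0
    )
    return mask & ~eroded


def average_hausdorff(pred: np.ndarray, ref: np.ndarray, spacing=(1.0, 1.0, 1.0)) -> float:
    """Symmetric average boundary distance in mm."""
    pred = np.asarray(pred, dtype=bool)
    ref = np.asarray(ref, dtype=bool)
    _check_grids(pred, ref)
    if not pred.any() or not ref.any():
        raise ValueError("average Hausdorff distance is undefined for empty masks")
    spacing = np.asarray(spacing, dtype=float)
    bp, br = boundary_voxels(pred), boundary_voxels(ref)
    d_to_ref = ndimage.distance_transform_edt(~br, sampling=spacing)
    d_to_pred = ndimage.distance_transform_edt(~bp, sampling=spacing)
    return 0.5 * (float(d_to_ref[bp].mean()) + float(d_to_pred[br].mean()))


def abs_volume_similarity(pred: np.ndarray, ref: np.ndarray) -> float:
    """1 − | |A| − |B| | / |B|, clipped to [0, 1]."""
    pred = np.asarray(pred, dtype=bool)
    ref = np.asarray(ref, dtype=bool)
    _check_grids(pred, ref)
    nref = int(ref.sum())
    if nref == 0:
        raise ValueError("volume similarity is undefined for an empty reference")
    return float(max(0.0, 1.0 - abs(int(pred.sum()) - nref) / nref))


def mean_lobe_dice(a: np.ndarray, b: np.ndarray) -> float:
    """Dice averaged over the five lobe labels of two label grids."""
    return float(np.mean([dice(a == k, b == k) for k in LOBE_CODES]))


def severity_bucket(lesion_fraction: float, buckets=SEVERITY_BUCKETS) -> str:
    for name, hi in buckets:
        if lesion_fraction < hi:
            return name
    return buckets[-1][0]


@dataclass
class MetricsReport:
    per_structure: dict
    mean_over_lobes: dict
    severity: str | None = None

    def as_rows(self):
        """(structure, dice, ahd, avs) rows plus a mean-over-lobes row."""
        rows = [(s, *[v[m] for m in ("dice", "ahd", "avs")])
                for s, v in self.per_structure.items()]
        m = self.mean_over_lobes
        rows.append(("mean_lobes", m["dice"], m["ahd"], m["avs"]))
        return rows


def evaluate(pred: LabelMap, ref: LabelMap, lesion_fraction: float | None = None,
             structures: dict | None = None) -> MetricsReport:
    """Per-structure Dice/AHD/AVS plus the mean over the five lobes.

    Structures absent from the reference are reported with None metrics and
    excluded from the lobe mean, with a warning.
    """
    _check_grids(pred.labels, ref.labels)
    if structures is None:
        structures = {name: code for code, name in enumerate(pred.class_names)
                      if code in LOBE_CODES or name == "airway"}
    per = {}
    for name, code in structures.items():
        rmask = ref.labels == code
        pmask = pred.labels == code
        if not rmask.any():
            warnings.warn(f"structure {name} absent from reference; excluded")
            per[name] = {"dice": None, "ahd": None, "avs": None}
            continue
        per[name] = {
            "dice": dice(pmask, rmask),
            "ahd": (average_hausdorff(pmask, rmask, ref.spacing)
                    if pmask.any() else None),
            "avs": abs_volume_similarity(pmask, rmask),
        }
    lobe_names = [n for n, c in structures.items() if c in LOBE_CODES
                  and per[n]["dice"] is not None]
    mean = {
        m: float(np.mean([per[n][m] for n in lobe_names]))
        if lobe_names and all(per[n][m] is not None for n in lobe_names) else None
        for m in ("dice", "ahd", "avs")
    }
    sev = severity_bucket(lesion_fraction) if lesion_fraction is not None else None
    return MetricsReport(per_structure=per, mean_over_lobes=mean, severity=sev)
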