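"""Invertible spatial alignment: center-of-mass initialization followed by
multi-resolution symmetric-forces demons registration, with transform caching.

The deformable engine is SimpleITK's symmetric-forces demons run over a
Gaussian pyramid (coarse-to-fine, shrink factors 2^(L-1) ... 1) with a
per-level iteration cap. Demons suits the single-modality setting here
(both images normalized CT); registration quality is checked against the
mutual-information improvement over the rigid initialization, and if the
deformation does not improve MI, the best-scoring transform seen is
returned with a warning.

Conventions
-----------
All volumes live on the canonical (Z, H, W) lattice with identity world
orientation. A :class:`Transform` stores dense displacement fields in voxel
units: ``forward_field`` on the fixed grid maps fixed index -> moving index
(so "forward" application produces a fixed-space image from a moving-space
one), ``inverse_field`` the other way round. The rigid pre-alignment is
folded into both fields; ``pre_align`` (mm) is kept for inspection and for
rigid-only transforms.
"""

from __future__ import annotations

import hashlib
import json
import logging
import warnings
from dataclasses import dataclass

import nibabel as nib
import numpy as np
import SimpleITK as sitk
from scipy import ndimage

from .similarity import mutual_information
from .volume_io import CTVolume, LabelMap

log = logging.getLogger(__name__)

ENGINE_VERSION = "demons-1"

#: Per-level iteration caps, coarse to fine (full-scale default).
DEFAULT_LEVELS = (10000, 1000, 100)

#: Registration cache instrumentation (reset freely in tests).
CACHE_STATS = {"hits": 0, "misses": 0}


@dataclass
class GridMeta:
    shape: tuple
    spacing: tuple
    affine: np.ndarray

    @classmethod
    def of(cls, vol) -> "GridMeta":
        return cls(tuple(vol.shape), tuple(vol.spacing), np.asarray(vol.affine))


@dataclass
class Transform:
    """Rigid translation plus optional dense diffeomorphic fields."""

    pre_align: np.ndarray  # (3,) mm, canonical (z, h, w) axes
    forward_field: np.ndarray | None  # (3, Z, H, W) voxels, on fixed grid
    inverse_field: np.ndarray | None  # (3, Z, H, W) voxels, on moving grid
    fixed_meta: GridMeta
    moving_meta: GridMeta

    @property
    def is_rigid(self) -> bool:
        return self.forward_field is None


def _centroid_world(vol: CTVolume) -> np.ndarray:
    w = np.abs(np.asarray(vol.intensities, dtype=np.float64))
    total = w.sum()
    if total == 0:
        raise ValueError("cannot compute a center of mass of an all-zero volume")
    idx = [np.arange(n) for n in vol.shape]
    com = np.array([
        (w.sum(axis=tuple(a for a in range(3) if a != ax)) * idx[ax]).sum() / total
        for ax in range(3)
    ])
    return com * vol.spacing


def center_of_mass_init(fixed: CTVolume, moving: CTVolume) -> Transform:
    """Rigid translation matching intensity-weighted centroids (mm)."""
    t = _centroid_world(moving) - _centroid_world(fixed)
    return Transform(t, None, None, GridMeta.of(fixed), GridMeta.of(moving))


def _warp_array(arr, field_vox, order):
    coords = np.indices(arr.shape, dtype=np.float64) + field_vox
    return ndimage.map_coordinates(arr, coords, order=order, mode="nearest")


def _to_sitk(arr, spacing):
    img = sitk.GetImageFromArray(np.ascontiguousarray(arr, dtype=np.float64))
    img.SetSpacing(tuple(float(s) for s in spacing[::-1]))
    return img


def _field_to_vox(field_img, spacing):
    """SimpleITK displacement image (mm, xyz comps) -> (3,Z,H,W) voxel units."""
    arr = sitk.GetArrayFromImage(field_img)  # (Z,H,W,3) comps (x,y,z)=(w,h,z)
    out = np.empty((3,) + arr.shape[:3])
    for ax in range(3):  # canonical z,h,w <- comps 2,1,0
        out[ax] = arr[..., 2 - ax] / spacing[ax]
    return out


def _vox_to_field(vox, spacing):
    arr = np.empty(vox.shape[1:] + (3,))
    for ax in range(3):
        arr[..., 2 - ax] = vox[ax] * spacing[ax]
    img = sitk.GetImageFromArray(arr, isVector=True)
    img.SetSpacing(tuple(float(s) for s in spacing[::-1]))
    return img


def register_diffeomorphic(
    fixed: CTVolume,
    moving: CTVolume,
    levels=DEFAULT_LEVELS,
    smooth_sd: float = 1.0,
) -> Transform:
    """Multi-resolution demons registration of ``moving`` onto ``fixed``.

    Both inputs must be normalized to [0, 1] and share shape and spacing.
    ``levels`` caps the demons iterations per pyramid level, coarse to fine;
    desk-scale callers pass reduced schedules such as (100, 50, 25).
    """
    for name, v in (("fixed", fixed), ("moving", moving)):
        if not v.normalized:
            raise ValueError(f"{name} volume must be normalized to [0, 1]")
    if fixed.shape != moving.shape or not np.allclose(fixed.spacing, moving.spacing):
        raise ValueError("registration requires congruent fixed/moving grids")

    init = center_of_mass_init(fixed, moving)
    t_vox = init.pre_align / fixed.spacing
    mov0 = _warp_array(
        moving.intensities.astype(np.float64),
        t_vox[:, None, None, None] * np.ones((3,) + tuple(fixed.shape)),
        order=1,
    )
    fix = fixed.intensities.astype(np.float64)
    spacing = fixed.spacing

    mi_init = mutual_information(fix, mov0)
    best_field = np.zeros((3,) + tuple(fixed.shape))
    best_mi = mi_init

    n_levels = len(levels)
    fix_img = _to_sitk(fix, spacing)
    mov_img = _to_sitk(mov0, spacing)
    field = None
    for li, iters in enumerate(levels):
        shrink = 2 ** (n_levels - 1 - li)
        if shrink > 1:
            f_l = _shrink(fix_img, shrink)
            m_l = _shrink(mov_img, shrink)
        else:
            f_l, m_l = fix_img, mov_img
        demons = sitk.FastSymmetricForcesDemonsRegistrationFilter()
        demons.SetNumberOfIterations(int(iters))
        demons.SetMaximumRMSError(0.005)
        demons.SetSmoothDisplacementField(True)
        demons.SetStandardDeviations(float(smooth_sd))
        demons.SetSmoothUpdateField(True)
        demons.SetUpdateFieldStandardDeviations(1.0)
        if field is None:
            field = demons.Execute(f_l, m_l)
        else:
            field = demons.Execute(f_l, m_l, _resample_field(field, f_l))
        # score the level at full resolution
        full = _resample_field(field, fix_img)
        vox = _field_to_vox(full, spacing)
        mi = mutual_information(fix, _warp_array(mov0, vox, order=1))
        if mi > best_mi:
            best_mi, best_field = mi, vox
    if best_mi <= mi_init:
        warnings.warn("demons registration did not improve mutual information; "
                      "returning the best transform seen")

    fwd = best_field + t_vox[:, None, None, None]
    fwd_img = _vox_to_field(fwd, spacing)
    inv_img = sitk.InvertDisplacementField(
        fwd_img, maximumNumberOfIterations=50,
        maxErrorToleranceThreshold=0.01, meanErrorToleranceThreshold=0.0005,
        enforceBoundaryCondition=False,
    )
    inv = _field_to_vox(inv_img, spacing)
    return Transform(init.pre_align, fwd, inv, GridMeta.of(fixed), GridMeta.of(moving))


def _shrink(img, factor):
    smoothed = sitk.SmoothingRecursiveGaussian(img, [factor / 2.0 * s for s in img.GetSpacing()])
    return sitk.Shrink(smoothed, [factor] * 3)


def _resample_field(field, ref_img):
    return sitk.Resample(field, ref_img, sitk.Transform(),
                         sitk.sitkLinear, 0.0, field.GetPixelID())


def apply_transform(t: Transform, vol, direction: str = "forward"):
    """Warp a CTVolume (trilinear) or LabelMap (nearest) through a Transform.

    ``forward`` maps a moving-space input onto the fixed grid; ``inverse``
    maps a fixed-space input onto the moving grid.
    """
    if direction not in ("forward", "inverse"):
        raise ValueError("direction must be 'forward' or 'inverse'")
    is_labels = isinstance(vol, LabelMap)
    arr = vol.labels if is_labels else vol.intensities
    src_meta = t.moving_meta if direction == "forward" else t.fixed_meta
    dst_meta = t.fixed_meta if direction == "forward" else t.moving_meta
    if tuple(arr.shape) != tuple(src_meta.shape):
        raise ValueError(
            f"input grid {arr.shape} does not match the transform's "
            f"{'moving' if direction == 'forward' else 'fixed'} side {src_meta.shape}"
        )
    if t.is_rigid:
        sign = 1.0 if direction == "forward" else -1.0
        t_vox = sign * t.pre_align / np.asarray(dst_meta.spacing)
        field = t_vox[:, None, None, None] * np.ones((3,) + tuple(dst_meta.shape))
    else:
        field = t.forward_field if direction == "forward" else t.inverse_field
    order = 0 if is_labels else 1
    out = _warp_array(arr.astype(np.float64), field, order=order)
    if is_labels:
        return LabelMap(np.rint(out).astype(vol.labels.dtype),
                        np.asarray(dst_meta.spacing), dst_meta.affine.copy(),
                        vol.class_names)
    return CTVolume(out, np.asarray(dst_meta.spacing), dst_meta.affine.copy(),
                    vol.normalized)


# ---------------------------------------------------------------------------
# on-disk transform cache


def transform_cache_key(fixed: CTVolume, moving: CTVolume, levels) -> str:
    """Content hash of (fixed, moving, schedule, engine version)."""
    h = hashlib.sha256()
    for v in (fixed, moving):
        h.update(np.ascontiguousarray(v.intensities, dtype=np.float64).tobytes())
        h.update(np.asarray(v.spacing, dtype=np.float64).tobytes())
    h.update(json.dumps(list(levels)).encode())
    h.update(ENGINE_VERSION.encode())
    return h.hexdigest()[:32]


def _field_nifti(field, path):
    nib.save(nib.Nifti1Image(np.moveaxis(field, 0, -1), np.eye(4)), str(path))


def cache_transform(t: Transform, key: str, cache_dir) -> None:
    """Persist a transform as a NIfTI displacement pair + JSON metadata."""
    from pathlib import Path

    d = Path(cache_dir)
    d.mkdir(parents=True, exist_ok=True)
    meta = {
        "key": key,
        "engine": ENGINE_VERSION,
        "pre_align": list(map(float, t.pre_align)),
        "rigid": t.is_rigid,
        "fixed": {"shape": list(t.fixed_meta.shape),
                  "spacing": list(map(float, t.fixed_meta.spacing)),
                  "affine": np.asarray(t.fixed_meta.affine).tolist()},
        "moving": {"shape": list(t.moving_meta.shape),
                   "spacing": list(map(float, t.moving_meta.spacing)),
                   "affine": np.asarray(t.moving_meta.affine).tolist()},
    }
    if not t.is_rigid:
        _field_nifti(t.forward_field, d / f"{key}_fwd.nii.gz")
        _field_nifti(t.inverse_field, d / f"{key}_inv.nii.gz")
    (d / f"{key}.json").write_text(json.dumps(meta))


def load_cached(key: str, cache_dir) -> Transform | None:
    """Load a cached transform; corrupt entries are treated as absent."""
    from pathlib import Path

    d = Path(cache_dir)
    meta_path = d / f"{key}.json"
    if not meta_path.exists():
        CACHE_STATS["misses"] += 1
        return None
    try:
        meta = json.loads(meta_path.read_text())
        fm = GridMeta(tuple(meta["fixed"]["shape"]), tuple(meta["fixed"]["spacing"]),
                      np.asarray(meta["fixed"]["affine"]))
        mm = GridMeta(tuple(meta["moving"]["shape"]), tuple(meta["moving"]["spacing"]),
                      np.asarray(meta["moving"]["affine"]))
        if meta["rigid"]:
            fwd = inv = None
        else:
            fwd = np.moveaxis(np.asanyarray(nib.load(str(d / f"{key}_fwd.nii.gz")).dataobj), -1, 0)
            inv = np.moveaxis(np.asanyarray(nib.load(str(d / f"{key}_inv.nii.gz")).dataobj), -1, 0)
            if fwd.shape != (3,) + fm.shape or inv.shape != (3,) + mm.shape:
                raise ValueError("field shape mismatch")
        t = Transform(np.asarray(meta["pre_align"], dtype=float), fwd, inv, fm, mm)
    except Exception as exc:  # corrupt entry -> absent
        log.warning("corrupt transform cache entry %s: %s", key, exc)
        CACHE_STATS["misses"] += 1
        return None
    CACHE_STATS["hits"] += 1
    log.info("transform cache hit for %s", key)
    return t


def register_with_cache(fixed: CTVolume, moving: CTVolume, levels=DEFAULT_LEVELS,
                        cache_dir=None, smooth_sd: float = 1.0) -> Transform:
    """Registration with transparent on-disk caching (if cache_dir given)."""
    if cache_dir is None:
        return register_diffeomorphic(fixed, moving, levels, smooth_sd)
    key = transform_cache_key(fixed, moving, levels)
    t = load_cached(key, cache_dir)
    if t is None:
        t = register_diffeomorphic(fixed, moving, levels, smooth_sd)
        cache_transform(t, key, cache_dir)
    return t
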