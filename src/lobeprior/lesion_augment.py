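"""Training-time augmentation: synthetic lesion insertion with intensity
matching and Gaussian-edge blending, plus standard geometric and intensity
augmentations.

Lesion insertion copies a pre-registered lesion (intensities + mask) into
the lung of a target image. The lesion intensities are first rescaled to
match the first two moments of the surrounding lung tissue,

    x' = (x - mu_lesion) / sigma_lesion * sigma_lung + mu_lung,

where the lung statistics are computed over the target lung mask minus the
lesion footprint (airway voxels are excluded from "surrounding lung"). The
rescaled lesion is mixed in with a soft weight map w = GaussianBlur(mask)
clipped to [0, 1] and restricted to the lung, so lesions never paint outside
the lung and voxels beyond the blur support stay bit-identical.

Geometric/intensity augmentation applies, in order: optional lesion
insertion, scaling, rotation, axis mirroring, Gaussian noise, Gaussian blur,
brightness/contrast, and a random crop. Identical geometric transforms are
applied to the labels with nearest-neighbor interpolation, and intensities
are clipped back to [0, 1]. One seeded generator drives every draw.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy import ndimage

from .volume_io import CTVolume, LabelMap

log = logging.getLogger(__name__)


@dataclass
class LesionEntry:
    intensities: np.ndarray  # normalized [0,1] grid, defined on the atlas grid
    mask: np.ndarray  # binary footprint on the same grid
    atlas_space_id: int

    def __post_init__(self):
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.intensities.shape != self.mask.shape:
            raise ValueError("lesion intensities and mask must share a grid")


@dataclass
class LesionBank:
    entries: list = field(default_factory=list)

    def for_group(self, atlas_space_id: int) -> list:
        return [e for e in self.entries if e.atlas_space_id == atlas_space_id]

    def save(self, out_dir) -> None:
        import nibabel as nib

        d = Path(out_dir)
        d.mkdir(parents=True, exist_ok=True)
        index = []
        for i, e in enumerate(self.entries):
            nib.save(nib.Nifti1Image(e.intensities.transpose(2, 1, 0), np.eye(4)),
                     str(d / f"lesion{i}_int.nii.gz"))
            nib.save(nib.Nifti1Image(e.mask.astype(np.uint8).transpose(2, 1, 0),
                                     np.eye(4)), str(d / f"lesion{i}_mask.nii.gz"))
            index.append({"intensities": f"lesion{i}_int.nii.gz",
                          "mask": f"lesion{i}_mask.nii.gz",
                          "atlas_space_id": e.atlas_space_id})
        (d / "index.json").write_text(json.dumps(index))

    @classmethod
    def load(cls, bank_dir) -> "LesionBank":
        import nibabel as nib

        d = Path(bank_dir)
        index = json.loads((d / "index.json").read_text())
        entries = []
        for item in index:
            ints = np.asanyarray(
                nib.load(str(d / item["intensities"])).dataobj).transpose(2, 1, 0)
            mask = np.asanyarray(
                nib.load(str(d / item["mask"])).dataobj).transpose(2, 1, 0) > 0
            entries.append(LesionEntry(ints, mask, item["atlas_space_id"]))
        return cls(entries)


def insert_lesion(target: CTVolume, target_lung: np.ndarray, entry: LesionEntry,
                  blend_sigma: float = 2.0,
                  rng: np.random.Generator | None = None) -> CTVolume:
    """Blend one registered lesion into the target's lung.

    Returns the target unchanged (with a warning) if the lesion footprint
    misses the lung entirely.
    """
    target_lung = np.asarray(target_lung, dtype=bool)
    if target.shape != entry.mask.shape or target.shape != target_lung.shape:
        raise ValueError("target, lung mask, and lesion entry must share a grid")
    if not target_lung.any():
        raise ValueError("empty target lung mask")
    core = entry.mask & target_lung
    if not core.any():
        log.warning("lesion lies entirely outside the target lung; skipped")
        return target.copy()

    surround = target_lung & ~entry.mask
    if not surround.any():
        surround = target_lung
    mu_lung = float(target.intensities[surround].mean())
    sd_lung = float(target.intensities[surround].std())

    if blend_sigma > 0:
        w = np.clip(ndimage.gaussian_filter(core.astype(np.float64),
                                            blend_sigma), 0.0, 1.0)
    else:
        w = core.astype(np.float64)
    w[~target_lung] = 0.0  # never paint outside the lung

    # lesion moments over the blend core (w ~ 1): the footprint rim mixes
    # lesion and parenchyma and would bias the match
    core_mask = w > 0.99
    if not core_mask.any():
        core_mask = core
    lesion_vals = entry.intensities[core_mask]
    mu_l, sd_l = float(lesion_vals.mean()), float(lesion_vals.std())
    if sd_l == 0:
        rescaled = np.full_like(entry.intensities, mu_lung)
    else:
        rescaled = (entry.intensities - mu_l) / sd_l * sd_lung + mu_lung

    out = (1.0 - w) * target.intensities + w * rescaled
    out = np.clip(out, 0.0, 1.0)
    return CTVolume(out, target.spacing.copy(), target.affine.copy(),
                    target.normalized)


@dataclass
class AugmentConfig:
    """Probabilities and ranges for the augmentation draws.

    Ranges follow common practice for CT segmentation: mild zoom (0.9-1.1),
    small in-plane rotations (+-10 degrees), low-amplitude noise and blur,
    and modest brightness/contrast jitter.
    """

    p_lesion: float = 0.5
    blend_sigma: float = 2.0
    p_scale: float = 0.3
    scale_range: tuple = (0.9, 1.1)
    p_rotate: float = 0.3
    rotate_deg: float = 10.0
    p_mirror: float = 0.3
    p_noise: float = 0.3
    noise_sd_max: float = 0.02
    p_blur: float = 0.2
    blur_sigma_max: float = 1.0
    p_brightness: float = 0.3
    brightness_delta: float = 0.1
    p_contrast: float = 0.3
    contrast_range: tuple = (0.8, 1.2)
    crop: tuple | None = (128, 128, 128)


def _zoom_about_center(arr, factor, order):
    center = (np.asarray(arr.shape) - 1) / 2.0
    idx = np.indices(arr.shape, dtype=np.float64)
    coords = (idx - center[:, None, None, None]) / factor + center[:, None, None, None]
    return ndimage.map_coordinates(arr, coords, order=order, mode="nearest")


def augment(ct: CTVolume, labels: LabelMap, cfg: AugmentConfig,
            rng: np.random.Generator,
            lesion_bank: LesionBank | None = None,
            lung_mask: np.ndarray | None = None,
            atlas_space_id: int = 0):
    """One stochastic augmentation draw applied to an image/label pair."""
    if ct.shape != labels.shape:
        raise ValueError("image and labels must be congruent")
    img = ct.intensities.astype(np.float64)
    lab = labels.labels.copy()

    if lesion_bank is not None and lung_mask is not None:
        entries = lesion_bank.for_group(atlas_space_id) or lesion_bank.entries
        if entries and rng.random() < cfg.p_lesion:
            entry = entries[rng.integers(len(entries))]
            vol = insert_lesion(
                CTVolume(img, ct.spacing, ct.affine, ct.normalized),
                lung_mask, entry, cfg.blend_sigma, rng)
            img = vol.intensities

    if rng.random() < cfg.p_scale:
        f = rng.uniform(*cfg.scale_range)
        img = _zoom_about_center(img, f, order=1)
        lab = _zoom_about_center(lab, f, order=0).astype(lab.dtype)
    if rng.random() < cfg.p_rotate:
        angle = rng.uniform(-cfg.rotate_deg, cfg.rotate_deg)
        axes = [(1, 2), (0, 2), (0, 1)][rng.integers(3)]
        img = ndimage.rotate(img, angle, axes=axes, reshape=False,
                             order=1, mode="nearest")
        lab = ndimage.rotate(lab, angle, axes=axes, reshape=False,
                             order=0, mode="nearest").astype(lab.dtype)
    for ax in range(3):
        if rng.random() < cfg.p_mirror:
            img = np.flip(img, axis=ax)
            lab = np.flip(lab, axis=ax)
    if rng.random() < cfg.p_noise:
        img = img + rng.standard_normal(img.shape) * rng.uniform(0, cfg.noise_sd_max)
    if rng.random() < cfg.p_blur:
        img = ndimage.gaussian_filter(img, rng.uniform(0.2, cfg.blur_sigma_max))
    if rng.random() < cfg.p_brightness:
        img = img + rng.uniform(-cfg.brightness_delta, cfg.brightness_delta)
    if rng.random() < cfg.p_contrast:
        c = rng.uniform(*cfg.contrast_range)
        img = (img - img.mean()) * c + img.mean()

    if cfg.crop is not None:
        crop = tuple(int(c) for c in cfg.crop)
        if any(c > s for c, s in zip(crop, img.shape)):
            raise ValueError(f"crop {crop} larger than volume {img.shape}")
        start = [int(rng.integers(0, s - c + 1)) for s, c in zip(img.shape, crop)]
        sl = tuple(slice(s, s + c) for s, c in zip(start, crop))
        img, lab = img[sl], lab[sl]

    img = np.clip(img, 0.0, 1.0)
    out_ct = CTVolume(np.ascontiguousarray(img), ct.spacing.copy(),
                      ct.affine.copy(), ct.normalized)
    out_lab = LabelMap(np.ascontiguousarray(lab), labels.spacing.copy(),
                       labels.affine.copy(), labels.class_names)
    return out_ct, out_lab


def bank_from_phantoms(specs, atlas_space_id: int = 0) -> LesionBank:
    """Build a lesion bank from phantom lesions (normalized intensities)."""
    from .phantom import make_phantom
    from .volume_io import normalize_hu

    entries = []
    for spec in specs:
        vol, _, mask = make_phantom(spec)
        if not mask.any():
            raise ValueError("phantom spec produced no lesion voxels")
        entries.append(LesionEntry(normalize_hu(vol).intensities, mask,
                                   atlas_space_id))
    return LesionBank(entries)
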