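"""Synthetic 3D lung phantoms: five lobes, fissures, airways, optional lesions.

The phantom emulates the label topology of a chest CT rather than its
photo-realistic appearance: two ellipsoidal lungs (right split into three
lobes, left into two, by tilted curved surfaces), thin brighter fissure
sheets along the dividing surfaces, a three-generation branching airway tube
rooted between the lungs, and optional bright spherical lesions overwriting
parenchyma. Intensities are authored in Hounsfield units so the standard
preprocessing (clip to [-1024, 600], rescale to [0, 1]) is exercised
realistically; parenchyma sits near -800 HU, background near 0 HU.

A cohort generator applies smooth random per-member deformations so that
grouping, atlas construction, and registration have anatomically plausible
variation to work with.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict, replace

import numpy as np
from scipy import ndimage

from .volume_io import CTVolume, LabelMap, default_affine, normalize_hu, HU_LO, HU_HI

# Base parenchyma HU per lobe (distinct so stages can be learned desk-scale),
# plus fissure / airway / lesion / background values.
LOBE_HU = {1: -850.0, 2: -820.0, 3: -790.0, 4: -760.0, 5: -730.0}
FISSURE_HU = -500.0
AIRWAY_HU = -1000.0
LESION_HU = -120.0
BACKGROUND_HU = 0.0


@dataclass
class PhantomSpec:
    """Parameters of one synthetic lung phantom.

    ``lung_radius_frac`` is the width-axis semi-axis of each lung as a
    fraction of the grid width; ``fissure_tilt`` is the mean tilt (degrees)
    of the lobar dividing surfaces, with a small seeded jitter per surface;
    ``noise_sd`` is additive Gaussian noise in normalized intensity units;
    ``deform_amplitude`` is the RMS magnitude (voxels) of a smooth random
    warp applied to the whole phantom.
    """

    shape: tuple = (48, 48, 48)
    seed: int = 0
    lung_radius_frac: float = 0.16
    fissure_tilt: float = 10.0
    lesion_count: int = 0
    lesion_radius_range: tuple = (3.0, 5.0)
    noise_sd: float = 0.01
    deform_amplitude: float = 0.0

    def __post_init__(self):
        if self.lesion_count < 0:
            raise ValueError("lesion_count must be >= 0")
        if self.lesion_radius_range[0] <= 0:
            raise ValueError("lesion radii must be positive")

    def to_dict(self) -> dict:
        d = asdict(self)
        d["shape"] = list(self.shape)
        d["lesion_radius_range"] = list(self.lesion_radius_range)
        return d


def _smooth_field(rng, shape, sigma, amplitude):
    """Smooth random displacement field, (3, Z, H, W), RMS ~ amplitude voxels."""
    disp = np.empty((3,) + tuple(shape))
    for ax in range(3):
        f = ndimage.gaussian_filter(rng.standard_normal(shape), sigma)
        rms = np.sqrt(np.mean(f**2))
        disp[ax] = f * (amplitude / rms) if rms > 0 else 0.0
    return disp


def _warp(grid, disp, order):
    idx = np.indices(grid.shape, dtype=np.float64)
    coords = idx + disp
    return ndimage.map_coordinates(grid, coords, order=order, mode="nearest")


def _tube(shape, p0, p1, radius):
    """Binary mask of a cylinder (capsule) between two points."""
    zz, hh, ww = np.indices(shape, dtype=np.float64)
    p0 = np.asarray(p0, dtype=float)
    d = np.asarray(p1, dtype=float) - p0
    L2 = float(d @ d)
    v = np.stack([zz - p0[0], hh - p0[1], ww - p0[2]])
    t = np.clip(np.tensordot(d, v, axes=1) / max(L2, 1e-9), 0.0, 1.0)
    closest = p0[:, None, None, None] + t[None] * d[:, None, None, None]
    dist2 = ((np.stack([zz, hh, ww]) - closest) ** 2).sum(axis=0)
    return dist2 <= radius**2


def _airway_mask(shape, lung_centers, z_top):
    """Three-generation branching tube rooted between the lungs."""
    Z, H, W = shape
    carina = np.array([0.48 * Z, 0.5 * H, 0.5 * W])
    r = max(1.4, 0.028 * W)
    mask = _tube(shape, [z_top, 0.5 * H, 0.5 * W], carina, r)
    for center in lung_centers:  # main bronchi
        hilum = np.array([0.55 * Z, 0.5 * H, 0.5 * W + 0.55 * (center[2] - 0.5 * W)])
        mask |= _tube(shape, carina, hilum, 0.8 * r)
        for dz in (-0.16 * Z, 0.16 * Z):  # lobar generation
            tip = hilum + np.array([dz, 0.0, 0.35 * (center[2] - 0.5 * W)])
            mask |= _tube(shape, hilum, tip, 0.55 * r)
    return mask


def make_phantom(spec: PhantomSpec):
    """Generate (CTVolume in HU, LabelMap, lesion_mask) from a spec.

    Deterministic given the spec (including its seed).
    """
    shape = tuple(int(s) for s in spec.shape)
    if min(shape) < 32:
        raise ValueError("phantom shape must be >= 32 on every axis")
    Z, H, W = shape
    rng = np.random.default_rng(spec.seed)

    zz, hh, ww = np.indices(shape, dtype=np.float64)
    rw = spec.lung_radius_frac * W
    if spec.lesion_count and spec.lesion_radius_range[1] >= rw:
        raise ValueError("lesions must be smaller than the lung radius")
    semi = np.array([0.40 * Z, 0.33 * H, rw])
    centers = [
        np.array([0.52 * Z, 0.50 * H, 0.28 * W]),  # left lung
        np.array([0.50 * Z, 0.50 * H, 0.72 * W]),  # right lung
    ]
    lungs = []
    for c in centers:
        e = (((zz - c[0]) / semi[0]) ** 2 + ((hh - c[1]) / semi[1]) ** 2
             + ((ww - c[2]) / semi[2]) ** 2)
        lungs.append(e <= 1.0)

    labels = np.zeros(shape, dtype=np.int16)
    fissure = np.zeros(shape, dtype=bool)

    def divide(lung, center, fracs, lobe_codes):
        """Split one lung along z by tilted, gently curved surfaces."""
        zmin = zz[lung].min()
        zext = zz[lung].max() - zmin
        surfaces = []
        for f in fracs:
            tilt = np.radians(rng.normal(spec.fissure_tilt, 2.0))
            slope_h = np.tan(tilt)
            slope_w = np.tan(np.radians(rng.normal(0.0, 3.0)))
            curve = 0.04 * ((hh - center[1]) ** 2) / max(H, 1)
            surfaces.append(
                zmin + f * zext
                + slope_h * (hh - center[1]) + slope_w * (ww - center[2]) + curve
            )
        region = np.zeros(shape, dtype=np.int8)
        for s in surfaces:
            region += (zz > s).astype(np.int8)
            fissure[lung & (np.abs(zz - s) < 0.8)] = True
        for i, code in enumerate(lobe_codes):
            labels[lung & (region == i)] = code

    # upper lobes at low z (toward the head), lower lobes at high z
    divide(lungs[0], centers[0], [0.45], [2, 1])          # left: LUL, LLL
    divide(lungs[1], centers[1], [0.33, 0.60], [5, 4, 3])  # right: RUL, RML, RLL

    airway = _airway_mask(shape, centers, z_top=0.08 * Z)
    labels[airway] = 6

    hu = np.full(shape, BACKGROUND_HU)
    for code, val in LOBE_HU.items():
        hu[labels == code] = val
    hu[fissure & (labels > 0) & (labels < 6)] = FISSURE_HU
    hu[labels == 6] = AIRWAY_HU

    # lesions: bright blobs strictly inside lobes, pairwise separated so the
    # connected-component count equals lesion_count
    lesion_mask = np.zeros(shape, dtype=bool)
    lobe_region = (labels >= 1) & (labels <= 5)
    if spec.lesion_count:
        interior_dist = ndimage.distance_transform_edt(lobe_region)
        placed = []
        for _ in range(spec.lesion_count):
            r = rng.uniform(*spec.lesion_radius_range)
            cand = np.argwhere(interior_dist > r + 1)
            if len(cand) == 0:
                raise ValueError("no room to place a lesion of this size")
            for _attempt in range(200):
                c = cand[rng.integers(len(cand))]
                if all(np.linalg.norm(c - pc) > r + pr + 2 for pc, pr in placed):
                    break
            else:
                raise ValueError("could not place non-touching lesions")
            placed.append((c.astype(float), r))
            ball = ((zz - c[0]) ** 2 + (hh - c[1]) ** 2 + (ww - c[2]) ** 2) <= r**2
            lesion_mask |= ball & lobe_region
        texture = ndimage.gaussian_filter(rng.standard_normal(shape), 1.5) * 40.0
        hu[lesion_mask] = LESION_HU + texture[lesion_mask]

    hu = ndimage.gaussian_filter(hu, 0.6)  # soften hard edges

    if spec.deform_amplitude > 0:
        disp = _smooth_field(rng, shape, sigma=6.0, amplitude=spec.deform_amplitude)
        hu = _warp(hu, disp, order=1)
        labels = _warp(labels, disp, order=0).astype(np.int16)
        lesion_mask = _warp(lesion_mask.astype(np.int16), disp, order=0) > 0

    if spec.noise_sd > 0:
        hu = hu + rng.standard_normal(shape) * spec.noise_sd * (HU_HI - HU_LO)

    affine = default_affine((1.0, 1.0, 1.0))
    vol = CTVolume(hu, (1.0, 1.0, 1.0), affine)
    lab = LabelMap(labels, (1.0, 1.0, 1.0), affine.copy())
    return vol, lab, lesion_mask


def make_cohort(n: int, base: PhantomSpec, variability: float = 1.0):
    """Generate ``n`` phantoms sharing base geometry, each smoothly deformed.

    ``variability`` is the per-member RMS warp amplitude in voxels; member
    ``i`` uses seed ``base.seed + i``. Returns a list of (CTVolume, LabelMap)
    pairs (intensities still in HU).
    """
    if n < 1:
        raise ValueError("cohort size must be >= 1")
    if variability < 0:
        raise ValueError("variability must be >= 0")
    if variability == 0:
        vol, lab, _ = make_phantom(base)
        return [(vol.copy(), lab.copy()) for _ in range(n)]
    base_spec = replace(base, deform_amplitude=0.0, noise_sd=0.0)
    vol0, lab0, _ = make_phantom(base_spec)
    out = []
    for i in range(n):
        rng = np.random.default_rng((base.seed + 100003 * (i + 1)) % (2**31))
        disp = _smooth_field(rng, vol0.shape, sigma=6.0, amplitude=variability)
        hu = _warp(vol0.intensities, disp, order=1)
        lab = _warp(lab0.labels, disp, order=0).astype(np.int16)
        if base.noise_sd > 0:
            hu = hu + rng.standard_normal(vol0.shape) * base.noise_sd * (HU_HI - HU_LO)
        out.append((
            CTVolume(hu, vol0.spacing.copy(), vol0.affine.copy()),
            LabelMap(lab, lab0.spacing.copy(), lab0.affine.copy()),
        ))
    return out


def preprocess_phantom(vol: CTVolume) -> CTVolume:
    """Standard preprocessing for a phantom already on a 1 mm grid."""
    return normalize_hu(vol)
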