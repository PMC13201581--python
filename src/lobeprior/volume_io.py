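"""Volume and label-map containers, NIfTI I/O, and fixed CT preprocessing.

Internally every grid uses the canonical axis order ``(Z, H, W)`` — depth,
height, width — with 0-based voxel indices. NIfTI files store arrays in
``(i, j, k)`` fastest-first order, so arrays are transposed at the I/O
boundary and affines adjusted by the corresponding permutation.

Preprocessing follows the standard chest-CT recipe: resample to isotropic
1 mm voxels, clip Hounsfield units to ``[-1024, 600]`` (the window that
preserves parenchyma and fissure contrast), and rescale to ``[0, 1]``.
"""

from __future__ import annotations

from dataclasses import dataclass

import nibabel as nib
import numpy as np
from scipy import ndimage

#: Segmentation label scheme. Index = integer code in label maps.
CLASS_NAMES = ("BG", "LLL", "LUL", "RLL", "RML", "RUL", "airway")

#: Default Hounsfield clipping window.
HU_LO = -1024.0
HU_HI = 600.0

# 4x4 permutation swapping canonical (z, h, w) index order with NIfTI (i, j, k).
_AXIS_PERM = np.array(
    [[0, 0, 1, 0], [0, 1, 0, 0], [1, 0, 0, 0], [0, 0, 0, 1]], dtype=float
)


def _spacing_from_affine(affine: np.ndarray) -> np.ndarray:
    return np.linalg.norm(affine[:3, :3], axis=0)


@dataclass
class CTVolume:
    """A 3D intensity grid with spacing, affine, and normalization state.

    Intensities are Hounsfield units before :func:`normalize_hu` and
    dimensionless values in ``[0, 1]`` afterwards.
    """

    intensities: np.ndarray
    spacing: np.ndarray
    affine: np.ndarray
    normalized: bool = False

    def __post_init__(self):
        self.intensities = np.asarray(self.intensities)
        if self.intensities.ndim != 3:
            raise ValueError("CTVolume requires a 3D scalar grid")
        self.spacing = np.asarray(self.spacing, dtype=float)
        if np.any(self.spacing <= 0):
            raise ValueError("voxel spacing must be strictly positive")
        self.affine = np.asarray(self.affine, dtype=float)

    @property
    def shape(self) -> tuple:
        return self.intensities.shape

    def copy(self) -> "CTVolume":
        return CTVolume(
            self.intensities.copy(), self.spacing.copy(), self.affine.copy(),
            self.normalized,
        )


@dataclass
class LabelMap:
    """Integer voxel labels over the 7-class lobe/airway scheme."""

    labels: np.ndarray
    spacing: np.ndarray
    affine: np.ndarray
    class_names: tuple = CLASS_NAMES

    def __post_init__(self):
        self.labels = np.asarray(self.labels)
        if self.labels.ndim != 3:
            raise ValueError("LabelMap requires a 3D grid")
        if not np.issubdtype(self.labels.dtype, np.integer):
            raise ValueError("labels must be an integer grid")
        if self.labels.min() < 0 or self.labels.max() >= len(self.class_names):
            raise ValueError("voxel values must be valid class indices")
        self.spacing = np.asarray(self.spacing, dtype=float)
        self.affine = np.asarray(self.affine, dtype=float)

    @property
    def shape(self) -> tuple:
        return self.labels.shape

    def copy(self) -> "LabelMap":
        return LabelMap(
            self.labels.copy(), self.spacing.copy(), self.affine.copy(),
            self.class_names,
        )


def default_affine(spacing) -> np.ndarray:
    """Diagonal affine for a synthetic grid: voxel (z, h, w) -> world mm."""
    aff = np.eye(4)
    aff[0, 0], aff[1, 1], aff[2, 2] = np.asarray(spacing, dtype=float)
    return aff


def _load(path):
    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj)
    if data.ndim != 3:
        raise ValueError(f"expected a 3D scalar image, got shape {data.shape}")
    affine = np.asarray(img.affine, dtype=float) @ _AXIS_PERM
    return np.ascontiguousarray(data.transpose(2, 1, 0)), affine


def read_volume(path) -> CTVolume:
    """Read a NIfTI intensity volume. No resampling is performed."""
    data, affine = _load(path)
    return CTVolume(data, _spacing_from_affine(affine), affine)


def read_labels(path) -> LabelMap:
    """Read a NIfTI label map; values must be valid 7-class indices."""
    data, affine = _load(path)
    if not np.issubdtype(data.dtype, np.integer):
        rounded = np.rint(data)
        if not np.allclose(data, rounded):
            raise ValueError("label image contains non-integer values")
        data = rounded.astype(np.int16)
    return LabelMap(data.astype(np.int16), _spacing_from_affine(affine), affine)


def _save(path, data: np.ndarray, affine: np.ndarray) -> None:
    file_affine = affine @ _AXIS_PERM  # permutation is its own inverse
    img = nib.Nifti1Image(data.transpose(2, 1, 0), file_affine)
    nib.save(img, str(path))


def write_volume(vol: CTVolume, path) -> None:
    _save(path, vol.intensities, vol.affine)


def write_labels(labels: LabelMap, path) -> None:
    _save(path, labels.labels.astype(np.int16), labels.affine)


def _round_half_away(x: np.ndarray) -> np.ndarray:
    return np.floor(np.abs(x) + 0.5) * np.sign(x)


def resample_isotropic(vol: CTVolume, target_mm: float) -> CTVolume:
    """Resample intensities to isotropic ``target_mm`` voxels (trilinear).

    Output shape per axis = round-half-away-from-zero of
    ``shape * spacing / target_mm``; voxel 0 stays anchored (corner-aligned
    sampling). Labels go through :func:`resample_labels_to` instead.
    """
    if target_mm <= 0:
        raise ValueError("target_mm must be positive")
    if np.allclose(vol.spacing, target_mm):
        return vol.copy()
    factors = vol.spacing / float(target_mm)
    new_shape = _round_half_away(np.asarray(vol.shape) * factors).astype(int)
    new_shape = np.maximum(new_shape, 1)
    coords = np.meshgrid(
        *[np.arange(n) / f for n, f in zip(new_shape, factors)], indexing="ij"
    )
    out = ndimage.map_coordinates(
        vol.intensities.astype(np.float64), coords, order=1, mode="nearest"
    )
    scale = np.diag([1 / factors[0], 1 / factors[1], 1 / factors[2], 1.0])
    affine = vol.affine @ scale
    return CTVolume(out, _spacing_from_affine(affine), affine, vol.normalized)


def normalize_hu(vol: CTVolume, lo: float = HU_LO, hi: float = HU_HI) -> CTVolume:
    """Clip HU to ``[lo, hi]`` and rescale linearly onto ``[0, 1]``."""
    if lo >= hi:
        raise ValueError("lo must be strictly below hi")
    out = (np.clip(vol.intensities, lo, hi) - lo) / (hi - lo)
    return CTVolume(out, vol.spacing.copy(), vol.affine.copy(), normalized=True)


def resample_labels_to(ref: CTVolume, labels: LabelMap) -> LabelMap:
    """Nearest-neighbor resampling of a label map onto ``ref``'s grid.

    Works through world coordinates (ref affine, then the inverse label
    affine), so any pair of valid affines is supported. The output class set
    is always a subset of the input's.
    """
    if np.linalg.matrix_rank(labels.affine) < 4:
        raise ValueError("degenerate label affine")
    if labels.shape == ref.shape and np.allclose(labels.affine, ref.affine):
        return LabelMap(labels.labels.copy(), ref.spacing.copy(),
                        ref.affine.copy(), labels.class_names)
    mapping = np.linalg.inv(labels.affine) @ ref.affine
    idx = np.indices(ref.shape, dtype=np.float64).reshape(3, -1)
    src = mapping[:3, :3] @ idx + mapping[:3, 3:4]
    out = ndimage.map_coordinates(labels.labels, src, order=0, mode="constant")
    return LabelMap(out.reshape(ref.shape).astype(labels.labels.dtype),
                    ref.spacing.copy(), ref.affine.copy(), labels.class_names)


def denormalize_hu(vol: CTVolume, lo: float = HU_LO, hi: float = HU_HI) -> CTVolume:
    """Map normalized intensities back to the HU window (inverse of normalize_hu)."""
    out = vol.intensities * (hi - lo) + lo
    return CTVolume(out, vol.spacing.copy(), vol.affine.copy(), normalized=False)
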