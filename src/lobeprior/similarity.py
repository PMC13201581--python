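"""Intensity similarity measures used for atlas selection and registration QA.

Mutual information uses a joint histogram over the normalized [0, 1]
intensity range (32 bins per axis by default) with natural logarithms, so
MI(x, x) equals the Shannon entropy (nats) of the marginal histogram.
"""

from __future__ import annotations

import numpy as np

DEFAULT_BINS = 32


def mse(a: np.ndarray, b: np.ndarray) -> float:
    """Mean squared intensity difference."""
    _check(a, b)
    return float(np.mean((np.asarray(a, float) - np.asarray(b, float)) ** 2))


def ncc(a: np.ndarray, b: np.ndarray) -> float:
    """Global normalized cross-correlation (Pearson), in [-1, 1].

    A constant image has zero variance; NCC is defined as 0 in that case.
    """
    _check(a, b)
    a = np.asarray(a, float).ravel()
    b = np.asarray(b, float).ravel()
    ac, bc = a - a.mean(), b - b.mean()
    denom = np.sqrt((ac**2).sum() * (bc**2).sum())
    if denom == 0:
        return 0.0
    return float(np.clip((ac * bc).sum() / denom, -1.0, 1.0))


def joint_histogram(a: np.ndarray, b: np.ndarray, bins: int = DEFAULT_BINS) -> np.ndarray:
    """Joint intensity histogram over [0, 1] x [0, 1], values clipped."""
    _check(a, b)
    a = np.clip(np.asarray(a, float).ravel(), 0.0, 1.0)
    b = np.clip(np.asarray(b, float).ravel(), 0.0, 1.0)
    h, _, _ = np.histogram2d(a, b, bins=bins, range=[[0, 1], [0, 1]])
    return h


def mutual_information(a: np.ndarray, b: np.ndarray, bins: int = DEFAULT_BINS) -> float:
    """Histogram mutual information in nats; >= 0."""
    h = joint_histogram(a, b, bins)
    pxy = h / h.sum()
    px = pxy.sum(axis=1, keepdims=True)
    py = pxy.sum(axis=0, keepdims=True)
    nz = pxy > 0
    return float(np.sum(pxy[nz] * np.log(pxy[nz] / (px @ py)[nz])))


def _check(a, b):
    if np.shape(a) != np.shape(b):
        raise ValueError(f"grid mismatch: {np.shape(a)} vs {np.shape(b)}")
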