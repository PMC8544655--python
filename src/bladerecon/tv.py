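"""Discrete total-variation primitives: gradient, divergence, shrinkage."""

from __future__ import annotations

import numpy as np

__all__ = ["grad", "div", "shrink", "shrink_iso", "total_variation"]


def grad(img: np.ndarray) -> np.ndarray:
    """Forward finite-difference gradient with periodic boundary.

    Returns a field of shape ``(2, N, N)``: axis-0 difference then axis-1
    difference.
    """
    gx = np.roll(img, -1, axis=0) - img
    gy = np.roll(img, -1, axis=1) - img
    return np.stack([gx, gy])


def div(field: np.ndarray) -> np.ndarray:
    """Discrete divergence, the negative adjoint of :func:`grad`.

    Satisfies ``<grad u, p> = -<u, div p>`` exactly (periodic boundary).
    """
    p0, p1 = field
    return (p0 - np.roll(p0, 1, axis=0)) + (p1 - np.roll(p1, 1, axis=1))


def shrink(z: np.ndarray, t: float) -> np.ndarray:
    """Complex soft-thresholding ``z * max(|z| - t, 0) / |z|`` (0 at z=0)."""
    if t < 0:
        raise ValueError("threshold must be non-negative")
    mag = np.abs(z)
    scale = np.maximum(mag - t, 0.0) / np.maximum(mag, np.finfo(float).tiny)
    return z * scale


def shrink_iso(field: np.ndarray, t: float) -> np.ndarray:
    """Isotropic vector shrinkage on a gradient-like field ``(2, N, N)``.

    The two components of each pixel are shrunk jointly by their combined
    magnitude, the standard split-Bregman treatment of isotropic TV.
    """
    if t < 0:
        raise ValueError("threshold must be non-negative")
    mag = np.sqrt((np.abs(field) ** 2).sum(axis=0))
    scale = np.maximum(mag - t, 0.0) / np.maximum(mag, np.finfo(float).tiny)
    return field * scale[None]


def total_variation(img: np.ndarray) -> float:
    """Isotropic TV: sum over pixels of the gradient magnitude."""
    g = grad(img)
    return float(np.sqrt((np.abs(g) ** 2).sum(axis=0)).sum())
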