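"""Coil-sensitivity estimation from the shared central k-space.

Every blade of a PROPELLER acquisition crosses the low-frequency centre of
k-space, so smooth per-coil calibration images can be gridded from the
central disk alone.  Three estimators turn those calibration images into
unit-norm sensitivity maps:

``rss``
    Divide each coil image by the root-sum-of-squares across coils.  The
    map inherits the object phase, which can wrap and produce abrupt
    complex-component changes.

``power``
    Per-voxel dominant eigenvector of a local coil-covariance built from
    overlapping smoothed copies of the calibration images, extracted by
    power iteration and phase-referenced to coil 1.  Wherever coil 1 has a
    near-null, the reference phase is undefined and a phase singularity
    appears - the known failure mode of eigenvector maps.

``tensor``
    Alternating estimation of a virtual body image and the maps, with each
    map update projected back onto the central (low-frequency) k-space disk
    through the NUFFT + density compensation + mask + adjoint-NUFFT chain.
    The projection enforces smoothness by construction, so the maps come
    out free of phase singularities.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.ndimage import uniform_filter

from .containers import KSpaceData, SensitivityMaps
from .geometry import KTrajectory
from .nufft import DensityWeights, NufftPlan, density_compensation

__all__ = [
    "CenterMask",
    "make_center_mask",
    "central_coil_images",
    "rss_maps",
    "power_iteration_maps",
    "tensor_iteration_maps",
    "estimate_maps",
]

SUPPORT_FRACTION = 0.05  # of peak RSS intensity


@dataclass
class CenterMask:
    """Boolean mask selecting trajectory samples in the central k-space disk."""

    mask: np.ndarray
    radius: float

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask, dtype=bool)
        if not self.mask.any():
            raise ValueError("center mask selects no samples")


def make_center_mask(traj: KTrajectory, radius: float = np.pi / 8) -> CenterMask:
    """Mask of samples with ``|k| < radius``; every blade must contribute."""
    r = np.hypot(traj.coords[:, 0], traj.coords[:, 1])
    mask = r < radius
    if not mask.any():
        raise ValueError("no samples inside the requested central radius")
    for b in np.unique(traj.blade_index):
        if not mask[traj.blade_index == b].any():
            raise ValueError(f"blade {b} has no samples inside the central disk")
    return CenterMask(mask=mask, radius=float(radius))


def central_coil_images(
    data: KSpaceData,
    mask: CenterMask,
    weights: DensityWeights,
    plan: NufftPlan | None = None,
    matrix_size: int | None = None,
) -> np.ndarray:
    """Low-resolution per-coil images gridded from the central disk.

    Computes the density-compensated adjoint NUFFT of ``mask * w * f`` for
    each coil; the result is smooth because only low spatial frequencies
    contribute.  Returns an array of shape (n_coils, N, N).
    """
    if plan is None:
        if matrix_size is None:
            raise ValueError("matrix_size required when no plan is given")
        plan = NufftPlan(data.traj, matrix_size)
    if mask.mask.shape[0] != data.n_samples:
        raise ValueError("center mask is not aligned with the data")
    wm = weights.w * mask.mask
    scale = plan.gridding_scale(wm)
    return np.stack(
        [plan.adjoint(wm * data.samples[c]) for c in range(data.n_coils)]
    ) * scale


def _support_from_rss(rss: np.ndarray) -> np.ndarray:
    return rss > SUPPORT_FRACTION * rss.max()


def rss_maps(coil_imgs: np.ndarray, support: np.ndarray | None = None) -> SensitivityMaps:
    """Root-sum-of-squares normalised maps ``s_j = c_j / sqrt(sum |c_k|^2)``."""
    coil_imgs = np.atleast_3d(np.asarray(coil_imgs, dtype=np.complex128))
    if coil_imgs.ndim == 2:
        coil_imgs = coil_imgs[None]
    rss = np.sqrt((np.abs(coil_imgs) ** 2).sum(axis=0))
    if support is None:
        support = _support_from_rss(rss)
    maps = np.where(support[None], coil_imgs / np.maximum(rss, np.finfo(float).tiny), 0)
    return SensitivityMaps(maps=maps, support=support)


def _smoothed_stack(
    coil_imgs: np.ndarray, acs: int, kernel_squares: int
) -> np.ndarray:
    """Overlapping-window smoothed copies of the coil images.

    Each copy is a uniform average over an ``acs x acs`` window whose
    anchor is shifted within the window, giving ``kernel_squares``
    overlapping squares per voxel; together they sample the local signal
    subspace the way a calibration-kernel (SPIRiT-style) smoothing does.
    Returns shape (n_coils, K, N, N).
    """
    n_shift = int(round(np.sqrt(kernel_squares)))
    if n_shift * n_shift != kernel_squares:
        raise ValueError("kernel_squares must be a perfect square")
    step = max(acs // n_shift, 1)
    shifts = [(i * step - acs // 2 + step // 2) for i in range(n_shift)]
    out = []
    for c in coil_imgs:
        copies = []
        for dx in shifts:
            for dy in shifts:
                shifted = np.roll(np.roll(c, -dx, axis=0), -dy, axis=1)
                sm = uniform_filter(shifted.real, size=acs, mode="nearest") + 1j * (
                    uniform_filter(shifted.imag, size=acs, mode="nearest")
                )
                copies.append(sm)
        out.append(np.stack(copies))
    return np.stack(out)


def power_iteration_maps(
    coil_imgs: np.ndarray,
    acs: int = 16,
    kernel_squares: int = 16,
    n_iter: int = 30,
) -> SensitivityMaps:
    """Per-voxel dominant eigenvector maps by power iteration.

    Builds the local coil covariance ``C(x) = B(x) B(x)^H`` from
    ``kernel_squares`` overlapping ``acs``-wide smoothed copies of the
    calibration images and runs ``n_iter`` power iterations per voxel.
    The eigenvector phase is referenced to coil 1.
    """
    coil_imgs = np.asarray(coil_imgs, dtype=np.complex128)
    if coil_imgs.ndim == 2:
        coil_imgs = coil_imgs[None]
    nc = coil_imgs.shape[0]
    if acs > coil_imgs.shape[1]:
        raise ValueError("acs cannot exceed the matrix size")
    B = np.moveaxis(_smoothed_stack(coil_imgs, acs, kernel_squares), (0, 1), (2, 3))
    # B: (N, N, nc, K); C v = B (B^H v)
    v = np.ones(B.shape[:2] + (nc,), dtype=np.complex128) / np.sqrt(nc)
    for _ in range(int(n_iter)):
        t = np.einsum("xyck,xyc->xyk", np.conj(B), v)
        v = np.einsum("xyck,xyk->xyc", B, t)
        nrm = np.linalg.norm(v, axis=-1, keepdims=True)
        v = v / np.maximum(nrm, np.finfo(float).tiny)
    rss = np.sqrt((np.abs(coil_imgs) ** 2).sum(axis=0))
    support = _support_from_rss(rss)
    # phase reference: coil 1
    ref = v[..., 0]
    phase = np.exp(-1j * np.angle(ref))
    v = v * phase[..., None]
    maps = np.moveaxis(v, -1, 0)
    maps = np.where(support[None], maps, 0)
    return SensitivityMaps(maps=maps, support=support)


def tensor_iteration_maps(
    data: KSpaceData,
    mask: CenterMask,
    weights: DensityWeights,
    n_iter: int = 10,
    plan: NufftPlan | None = None,
    matrix_size: int | None = None,
    eps_rel: float = 1e-2,
    taper: bool = True,
) -> SensitivityMaps:
    """Smooth sensitivity maps by alternating low-frequency projection.

    Starting from RSS-normalised maps, each iteration (i) forms the virtual
    body image ``m = sum_j conj(s_j) c_j``, (ii) re-estimates each map as
    ``P[c_j conj(m) / (|m|^2 + eps)]`` where ``P`` grids the image onto the
    central masked trajectory (with density compensation) and back -- a
    low-frequency projection -- and (iii) renormalises every voxel to unit
    L2 norm across coils.  The Tikhonov guard ``eps = eps_rel * max|m|^2``
    keeps the voxelwise division finite where the body image vanishes.
    """
    if plan is None:
        if matrix_size is None:
            raise ValueError("matrix_size required when no plan is given")
        plan = NufftPlan(data.traj, matrix_size)
    if n_iter < 1:
        raise ValueError("n_iter must be >= 1")
    c = central_coil_images(data, mask, weights, plan=plan)
    nc = c.shape[0]
    rss = np.sqrt((np.abs(c) ** 2).sum(axis=0))
    support = _support_from_rss(rss)
    s = c / np.maximum(rss, np.finfo(float).tiny)

    if taper:
        r = np.hypot(plan.traj.coords[:, 0], plan.traj.coords[:, 1])
        window = np.where(r < mask.radius,
                          0.5 * (1.0 + np.cos(np.pi * r / mask.radius)), 0.0)
    else:
        window = mask.mask.astype(np.float64)
    wm = weights.w * window
    scale = plan.gridding_scale(wm)

    def project(img: np.ndarray) -> np.ndarray:
        return plan.adjoint(wm * plan.forward(img)) * scale

    for _ in range(int(n_iter)):
        m = (np.conj(s) * c).sum(axis=0)
        eps = eps_rel * float(np.abs(m).max()) ** 2
        ratio = np.conj(m) / (np.abs(m) ** 2 + eps)
        s_new = np.stack([project(c[j] * ratio) for j in range(nc)])
        if not np.isfinite(s_new).all():
            raise FloatingPointError("tensor iteration produced non-finite maps")
        nrm = np.sqrt((np.abs(s_new) ** 2).sum(axis=0))
        s = s_new / np.maximum(nrm, np.finfo(float).tiny)
    return SensitivityMaps(maps=s, support=support)


def estimate_maps(
    data: KSpaceData,
    method: str = "tensor",
    weights: DensityWeights | None = None,
    plan: NufftPlan | None = None,
    matrix_size: int | None = None,
    center_radius: float = np.pi / 8,
    **kw,
) -> SensitivityMaps:
    """Convenience dispatcher over the three estimators."""
    if plan is None:
        if matrix_size is None:
            raise ValueError("matrix_size required when no plan is given")
        plan = NufftPlan(data.traj, matrix_size)
    if weights is None:
        weights = density_compensation(data.traj, plan.n, plan=plan)
    mask = make_center_mask(data.traj, radius=center_radius)
    if method == "tensor":
        return tensor_iteration_maps(data, mask, weights, plan=plan, **kw)
    coil_imgs = central_coil_images(data, mask, weights, plan=plan)
    if method == "rss":
        return rss_maps(coil_imgs, **kw)
    if method == "power":
        return power_iteration_maps(coil_imgs, **kw)
    raise ValueError(f"unknown coil-map method {method!r}")
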