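"""Encoding operators mapping an image to multi-coil k-space samples.

The SENSE-style encoding of a complex image ``u`` is

    A_j u = NUFFT(s_j * u)            (one output row per coil j),

i.e. a per-coil sensitivity multiplication followed by the non-uniform
Fourier transform onto the trajectory.  For single-coil work the
sensitivity factor is the identity.

Operators are spectrally normalised at construction (largest singular
value estimated by power iteration on ``A^H A``), so that downstream
solver parameters are scale-free; the estimated raw norm is kept on the
instance so reconstructions can be reported in the image's native
intensity units.
"""

from __future__ import annotations

import numpy as np

from .containers import KSpaceData, SensitivityMaps
from .geometry import KTrajectory
from .nufft import NufftPlan

__all__ = ["EncodingOperator", "IdentityOperator"]


class IdentityOperator:
    """Trivial encoding (image == data); used for denoising-style problems."""

    def __init__(self, matrix_size: int):
        self.n = int(matrix_size)
        self.n_coils = 1
        self.n_samples = self.n * self.n
        self.norm = 1.0

    def forward(self, img: np.ndarray) -> np.ndarray:
        return img.reshape(1, -1).astype(np.complex128)

    def adjoint(self, samples: np.ndarray) -> np.ndarray:
        return samples.reshape(self.n, self.n).astype(np.complex128)

    def normal(self, img: np.ndarray) -> np.ndarray:
        return np.asarray(img, dtype=np.complex128)


class EncodingOperator:
    """Sensitivity-weighted NUFFT encoding ``A`` and its adjoint.

    Parameters
    ----------
    traj : KTrajectory
        k-space sample coordinates.
    matrix_size : int
        Image side length.
    maps : SensitivityMaps, optional
        Coil sensitivities; ``None`` means one uniform virtual coil.
    plan : NufftPlan, optional
        Reuse an existing plan for the same trajectory/size.
    normalize : bool
        Scale the operator to unit spectral norm (default).
    """

    def __init__(
        self,
        traj: KTrajectory,
        matrix_size: int,
        maps: SensitivityMaps | None = None,
        plan: NufftPlan | None = None,
        normalize: bool = True,
        n_norm_iter: int = 20,
    ):
        self.plan = plan if plan is not None else NufftPlan(traj, matrix_size)
        if self.plan.n != matrix_size:
            raise ValueError("plan size does not match matrix_size")
        self.n = int(matrix_size)
        self.maps = maps
        if maps is not None:
            if maps.matrix_size != self.n:
                raise ValueError("sensitivity maps do not match matrix size")
            self.n_coils = maps.n_coils
        else:
            self.n_coils = 1
        self.n_samples = self.plan.n_samples
        self.norm = 1.0
        self._scale = 1.0
        if normalize:
            self.norm = self._estimate_norm(n_norm_iter)
            self._scale = 1.0 / self.norm

    # -- raw (unnormalised) transforms ------------------------------------

    def _forward_raw(self, img: np.ndarray) -> np.ndarray:
        if self.maps is None:
            return self.plan.forward(img)[None]
        return np.stack(
            [self.plan.forward(self.maps.maps[j] * img) for j in range(self.n_coils)]
        )

    def _adjoint_raw(self, samples: np.ndarray) -> np.ndarray:
        samples = np.atleast_2d(samples)
        if self.maps is None:
            return self.plan.adjoint(samples[0])
        out = np.zeros((self.n, self.n), dtype=np.complex128)
        for j in range(self.n_coils):
            out += np.conj(self.maps.maps[j]) * self.plan.adjoint(samples[j])
        return out

    def _estimate_norm(self, n_iter: int) -> float:
        # deterministic start: smooth non-degenerate test image
        x = np.arange(self.n) / self.n
        v = (1.0 + np.outer(np.sin(2 * np.pi * x), np.cos(2 * np.pi * x))).astype(
            np.complex128
        )
        lam = 1.0
        for _ in range(int(n_iter)):
            v = self._adjoint_raw(self._forward_raw(v))
            lam = np.linalg.norm(v)
            v = v / lam
        return float(np.sqrt(lam))

    # -- public, normalised -----------------------------------------------

    def forward(self, img: np.ndarray) -> np.ndarray:
        """``A u``: image (N, N) -> samples (n_coils, M)."""
        return self._forward_raw(img) * self._scale

    def adjoint(self, samples: np.ndarray) -> np.ndarray:
        """``A^H y``: samples (n_coils, M) -> image (N, N)."""
        return self._adjoint_raw(samples) * self._scale

    def normal(self, img: np.ndarray) -> np.ndarray:
        """``A^H A u`` in one call."""
        return self.adjoint(self.forward(img))
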