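"""In-memory containers shared across the reconstruction pipeline."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .geometry import KTrajectory

__all__ = ["KSpaceData", "SensitivityMaps"]


@dataclass
class KSpaceData:
    """Acquired (or simulated) multi-coil k-space samples.

    Attributes
    ----------
    samples : (n_coils, M) complex128
        One complex value per coil and trajectory sample.
    traj : KTrajectory
        The sampling trajectory, M samples.
    """

    samples: np.ndarray
    traj: KTrajectory

    def __post_init__(self) -> None:
        self.samples = np.ascontiguousarray(self.samples, dtype=np.complex128)
        if self.samples.ndim == 1:
            self.samples = self.samples[None, :]
        if self.samples.ndim != 2:
            raise ValueError("samples must have shape (n_coils, M)")
        if self.samples.shape[1] != len(self.traj):
            raise ValueError(
                f"sample count {self.samples.shape[1]} does not match "
                f"trajectory length {len(self.traj)}"
            )
        if not np.isfinite(self.samples).all():
            raise ValueError("samples contain non-finite values")

    @property
    def n_coils(self) -> int:
        return self.samples.shape[0]

    @property
    def n_samples(self) -> int:
        return self.samples.shape[1]

    def select_blades(self, keep) -> "KSpaceData":
        """Data counterpart of :func:`bladerecon.geometry.select_blades`."""
        from .geometry import select_blades

        keep = set(int(b) for b in keep)
        sub = select_blades(self.traj, keep)
        mask = np.isin(self.traj.blade_index, sorted(keep))
        return KSpaceData(samples=self.samples[:, mask], traj=sub)


@dataclass
class SensitivityMaps:
    """Per-coil complex sensitivity profiles on the image grid.

    On the support mask the per-voxel L2 norm across coils is 1; outside
    it the maps are zero (air / no signal).
    """

    maps: np.ndarray  # (n_coils, N, N) complex
    support: np.ndarray = field(default=None)  # (N, N) bool

    def __post_init__(self) -> None:
        self.maps = np.ascontiguousarray(self.maps, dtype=np.complex128)
        if self.maps.ndim == 2:
            self.maps = self.maps[None]
        if self.maps.ndim != 3 or self.maps.shape[1] != self.maps.shape[2]:
            raise ValueError("maps must have shape (n_coils, N, N), N square")
        if self.support is None:
            self.support = np.ones(self.maps.shape[1:], dtype=bool)
        self.support = np.asarray(self.support, dtype=bool)
        if self.support.shape != self.maps.shape[1:]:
            raise ValueError("support mask must match map shape")

    @property
    def n_coils(self) -> int:
        return self.maps.shape[0]

    @property
    def matrix_size(self) -> int:
        return self.maps.shape[1]

    def check_unit_norm(self, tol: float = 1e-6) -> bool:
        norm = np.sqrt((np.abs(self.maps) ** 2).sum(axis=0))
        on = np.abs(norm[self.support] - 1.0) <= tol
        off = np.abs(norm[~self.support]) <= tol
        return bool(on.all() and off.all())
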