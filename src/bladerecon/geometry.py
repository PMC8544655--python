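"""PROPELLER/BLADE k-space trajectory construction.

A BLADE (PROPELLER) acquisition covers k-space with rotated rectangular
strips ("blades").  Each blade is a Cartesian grid of ``n_lines``
phase-encode lines by ``n_readout`` readout samples, rotated about the
k-space origin; all blades share the low-frequency centre, which is what
makes the trajectory motion robust and what the coil-map estimators rely on.

Coordinates follow the convention of angular frequency in radians per
pixel: a fully sampled matrix of side ``matrix_size`` spans ``[-pi, pi)``
in each k-space direction, and the readout direction is oversampled twice
(``n_readout = 2 * matrix_size`` for full Nyquist readout coverage).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "BladeSpec",
    "KTrajectory",
    "blade_rotation_angles",
    "make_blade_trajectory",
    "select_blades",
]


@dataclass(frozen=True)
class BladeSpec:
    """Geometry of a BLADE acquisition.

    Parameters
    ----------
    n_readout : int
        Samples per readout line.  Readout-oversampled: must be at least
        ``matrix_size`` (conventionally twice it, e.g. 512 readout samples
        for a 256 matrix).
    n_lines : int
        Phase-encode lines per blade before undersampling.
    n_blades : int
        Number of rotated blades.
    matrix_size : int
        Side length of the reconstructed image in pixels.
    sense_factor : int
        SENSE-style line-skipping factor: every ``sense_factor``-th
        phase-encode line is acquired, starting from line 0 (or from a
        per-blade offset when ``interleave_offsets`` is set).
    rotation_offset : float
        Rotation of the first blade, radians.
    interleave_offsets : bool
        When True, blade ``b`` starts its line skipping at
        ``b % sense_factor`` instead of 0, interleaving the undersampling
        pattern across blades.
    """

    n_readout: int
    n_lines: int
    n_blades: int
    matrix_size: int
    sense_factor: int = 1
    rotation_offset: float = 0.0
    interleave_offsets: bool = False

    def __post_init__(self) -> None:
        for name in ("n_readout", "n_lines", "n_blades", "matrix_size", "sense_factor"):
            v = getattr(self, name)
            if not isinstance(v, (int, np.integer)) or v <= 0:
                raise ValueError(f"{name} must be a positive integer, got {v!r}")
        if self.n_readout < self.matrix_size:
            raise ValueError(
                "n_readout must be >= matrix_size (readout oversampling); "
                f"got {self.n_readout} < {self.matrix_size}"
            )
        if self.sense_factor > self.n_lines:
            raise ValueError("sense_factor cannot exceed n_lines")

    @property
    def n_lines_kept(self) -> int:
        """Phase-encode lines actually acquired per blade."""
        return int(-(-self.n_lines // self.sense_factor))  # ceil

    @property
    def n_samples(self) -> int:
        return self.n_blades * self.n_lines_kept * self.n_readout


@dataclass
class KTrajectory:
    """Non-Cartesian k-space sample coordinates with blade/line structure.

    Attributes
    ----------
    coords : (N, 2) float64
        k-space coordinates in radians, each component in ``[-pi, pi)``.
    blade_index, line_index : (N,) int32
        Which blade / which phase-encode line each sample belongs to.
    spec : BladeSpec or None
        The generating geometry, when known.
    """

    coords: np.ndarray
    blade_index: np.ndarray
    line_index: np.ndarray
    spec: BladeSpec | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        self.coords = np.ascontiguousarray(self.coords, dtype=np.float64)
        self.blade_index = np.ascontiguousarray(self.blade_index, dtype=np.int32)
        self.line_index = np.ascontiguousarray(self.line_index, dtype=np.int32)
        if self.coords.ndim != 2 or self.coords.shape[1] != 2:
            raise ValueError("coords must have shape (N, 2)")
        n = self.coords.shape[0]
        if self.blade_index.shape != (n,) or self.line_index.shape != (n,):
            raise ValueError("blade_index/line_index must align with coords")
        if n and (self.coords.min() < -np.pi or self.coords.max() >= np.pi):
            raise ValueError("coordinates must lie in [-pi, pi)")

    def __len__(self) -> int:
        return self.coords.shape[0]

    @property
    def n_samples(self) -> int:
        return len(self)

    @property
    def blades(self) -> np.ndarray:
        return np.unique(self.blade_index)


def blade_rotation_angles(n_blades: int, rotation_offset: float = 0.0) -> np.ndarray:
    """Uniform PROPELLER blade angles ``offset + b * pi / n_blades``.

    The blades span half a turn because a rotation by pi maps a symmetric
    blade onto itself (conjugate-symmetric coverage).
    """
    if n_blades < 1:
        raise ValueError("n_blades must be >= 1")
    return rotation_offset + np.arange(n_blades) * np.pi / n_blades


def _kept_lines(spec: BladeSpec, blade: int) -> np.ndarray:
    start = (blade % spec.sense_factor) if spec.interleave_offsets else 0
    lines = np.arange(start, spec.n_lines, spec.sense_factor)
    if lines.size == 0:  # offset pushed past the last line; fall back to 0
        lines = np.arange(0, spec.n_lines, spec.sense_factor)
    return lines


def make_blade_trajectory(spec: BladeSpec) -> KTrajectory:
    """Build the full BLADE trajectory for ``spec``.

    Each blade is an axis-aligned rectangular grid -- readout spanning the
    full Nyquist range at 2x oversampling, phase-encode span proportional
    to ``n_lines / matrix_size`` -- rotated by its blade angle.  With
    ``sense_factor > 1`` every ``sense_factor``-th line is kept.
    """
    angles = blade_rotation_angles(spec.n_blades, spec.rotation_offset)
    # Readout: n_readout points covering [-pi, pi) at spacing 2*pi/n_readout
    # scaled so that matrix_size pixels are resolved -> spacing pi*... ; with
    # 2x oversampling the extremes stay within the Nyquist band of the matrix.
    dk_read = 2.0 * np.pi * spec.matrix_size / spec.n_readout / spec.matrix_size
    kr = (np.arange(spec.n_readout) - spec.n_readout // 2) * dk_read
    # Phase encode: unit line spacing in k equals full Nyquist / matrix_size.
    dk_phase = 2.0 * np.pi / spec.matrix_size
    coords = []
    bidx = []
    lidx = []
    for b, theta in enumerate(angles):
        lines = _kept_lines(spec, b)
        kp = (lines - spec.n_lines // 2) * dk_phase
        krr, kpp = np.meshgrid(kr, kp)  # (n_lines_kept, n_readout)
        c, s = np.cos(theta), np.sin(theta)
        kx = c * krr - s * kpp
        ky = s * krr + c * kpp
        coords.append(np.stack([kx.ravel(), ky.ravel()], axis=1))
        bidx.append(np.full(kx.size, b, dtype=np.int32))
        lidx.append(np.repeat(lines, spec.n_readout).astype(np.int32))
    coords = np.concatenate(coords, axis=0)
    # Rotation can push the extreme corner samples infinitesimally past the
    # principal interval; wrap them back (the encoding is 2*pi-periodic).
    coords = (coords + np.pi) % (2.0 * np.pi) - np.pi
    return KTrajectory(
        coords=coords,
        blade_index=np.concatenate(bidx),
        line_index=np.concatenate(lidx),
        spec=spec,
    )


def select_blades(traj: KTrajectory, keep: Iterable[int] | Sequence[int]) -> KTrajectory:
    """Retain only the samples of the given blade indices.

    Blade and line indices are preserved, as is sample order within blades.
    Used both to emulate motion-corrupted blade rejection and to study
    partial k-space coverage.
    """
    keep = set(int(b) for b in keep)
    if not keep:
        raise ValueError("keep set must be non-empty")
    present = set(np.unique(traj.blade_index).tolist())
    if not keep <= present:
        raise ValueError(f"unknown blade indices: {sorted(keep - present)}")
    mask = np.isin(traj.blade_index, sorted(keep))
    return KTrajectory(
        coords=traj.coords[mask],
        blade_index=traj.blade_index[mask],
        line_index=traj.line_index[mask],
        spec=traj.spec,
    )
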