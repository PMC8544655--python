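"""Synthetic brain phantom, coil profiles and BLADE acquisition simulator.

The phantom emulates the piecewise-smooth appearance of a T1-weighted
sagittal head slice: elliptical compartments for scalp/skull, CSF, cortical
grey matter, white matter and the deep grey nuclei (thalamus, globus
pallidus, caudate nucleus, putamen), each with its own mean intensity, a
slowly varying intra-compartment texture and a smooth complex phase.  It is
deliberately synthetic - geometric compartments, not anatomy - so every
pipeline stage can be tested without any bundled patient data.

`simulate_acquisition` produces multi-coil BLADE k-space from a ground
truth image and coil profiles: NUFFT encoding per coil, complex Gaussian
noise, optional amplitude outliers (spike-like corruption) and optional
whole-blade rejection (the missing-blade model of patient motion).
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field

import numpy as np
from scipy.ndimage import gaussian_filter

from .containers import KSpaceData, SensitivityMaps
from .geometry import BladeSpec, KTrajectory, make_blade_trajectory, select_blades
from .nufft import NufftPlan

__all__ = [
    "PhantomSpec",
    "SimulationSpec",
    "TISSUE_LABELS",
    "make_phantom",
    "make_coil_profiles",
    "simulate_acquisition",
    "reference_fixture",
]

# Label roster: background plus the tissues reported in per-ROI CNR tables.
TISSUE_LABELS = {
    "background": 0,
    "skull": 1,
    "csf": 2,
    "gm": 3,
    "wm": 4,
    "thalamus": 5,
    "gp": 6,
    "cn": 7,
    "putamen": 8,
}

# (cx, cy, a, b, angle_deg, intensity, label) in a [-1, 1] field of view.
_DEFAULT_COMPARTMENTS = [
    (0.0, 0.0, 0.86, 0.92, 0.0, 0.30, "skull"),
    (0.0, 0.0, 0.78, 0.84, 0.0, 0.22, "csf"),
    (0.0, 0.0, 0.72, 0.78, 0.0, 0.55, "gm"),
    (0.0, 0.02, 0.60, 0.66, 0.0, 0.80, "wm"),
    (0.0, -0.08, 0.10, 0.16, 0.0, 0.22, "csf"),        # ventricle
    (0.18, 0.12, 0.13, 0.09, 20.0, 0.60, "thalamus"),
    (-0.22, 0.18, 0.08, 0.06, -15.0, 0.48, "gp"),
    (0.02, 0.34, 0.10, 0.05, 0.0, 0.58, "cn"),
    (-0.24, -0.05, 0.09, 0.13, 10.0, 0.52, "putamen"),
]


@dataclass(frozen=True)
class PhantomSpec:
    """Ground-truth phantom description.

    ``compartments`` entries are ``(cx, cy, a, b, angle_deg, intensity,
    label_name)`` with geometry in the ``[-1, 1]`` field of view; later
    entries overwrite earlier ones.  ``texture_amplitude`` is the relative
    std of the smooth intra-compartment modulation.
    """

    matrix_size: int = 256
    compartments: tuple = tuple(_DEFAULT_COMPARTMENTS)
    texture_amplitude: float = 0.05
    phase_amplitude: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        for comp in self.compartments:
            cx, cy, a, b, ang, inten, label = comp
            if inten < 0:
                raise ValueError("compartment intensities must be >= 0")
            if abs(cx) + a > 1.5 or abs(cy) + b > 1.5:
                raise ValueError("ellipse extends far outside the field of view")
            if label not in TISSUE_LABELS:
                raise ValueError(f"unknown tissue label {label!r}")


def make_phantom(spec: PhantomSpec) -> tuple[np.ndarray, np.ndarray]:
    """Build the complex ground-truth image and its integer label map.

    Returns ``(image, labels)``: ``image`` is (N, N) complex128 with
    piecewise-smooth magnitude and slowly varying phase; ``labels`` is
    (N, N) int16 using :data:`TISSUE_LABELS` codes.
    """
    n = spec.matrix_size
    y, x = np.meshgrid(
        np.linspace(-1, 1, n, endpoint=False) + 1.0 / n,
        np.linspace(-1, 1, n, endpoint=False) + 1.0 / n,
        indexing="ij",
    )
    mag = np.zeros((n, n))
    labels = np.zeros((n, n), dtype=np.int16)
    for cx, cy, a, b, ang, inten, label in spec.compartments:
        t = np.deg2rad(ang)
        xr = (x - cx) * np.cos(t) + (y - cy) * np.sin(t)
        yr = -(x - cx) * np.sin(t) + (y - cy) * np.cos(t)
        inside = (xr / a) ** 2 + (yr / b) ** 2 <= 1.0
        mag[inside] = inten
        labels[inside] = TISSUE_LABELS[label]

    rng = np.random.default_rng(spec.seed)
    if spec.texture_amplitude > 0:
        tex = gaussian_filter(rng.standard_normal((n, n)), sigma=n / 24)
        tex = tex / max(tex.std(), np.finfo(float).tiny)
        mag = mag * (1.0 + spec.texture_amplitude * tex)
        mag = np.clip(mag, 0.0, None)
    phase = np.zeros((n, n))
    if spec.phase_amplitude > 0:
        smooth = gaussian_filter(rng.standard_normal((n, n)), sigma=n / 8)
        smooth = smooth / max(np.abs(smooth).max(), np.finfo(float).tiny)
        phase = spec.phase_amplitude * (smooth + 0.3 * x + 0.2 * y)
    img = mag * np.exp(1j * phase)
    img[labels == 0] = 0.0
    return img.astype(np.complex128), labels


def make_coil_profiles(
    matrix_size: int,
    n_coils: int,
    seed: int = 0,
    null_in_first_coil: bool = False,
) -> SensitivityMaps:
    """Smooth complex Gaussian-lobe coil profiles (ground truth, unnormalised).

    Coils sit on a ring just outside the field of view with broad Gaussian
    magnitude lobes and slowly varying phase, i.e. band-limited profiles.
    ``null_in_first_coil`` carves a deep smooth notch into coil 1's
    magnitude inside the FOV to provoke the power-iteration phase
    singularity.
    """
    if n_coils < 1:
        raise ValueError("n_coils must be >= 1")
    n = matrix_size
    y, x = np.meshgrid(
        np.linspace(-1, 1, n, endpoint=False) + 1.0 / n,
        np.linspace(-1, 1, n, endpoint=False) + 1.0 / n,
        indexing="ij",
    )
    rng = np.random.default_rng(seed)
    if n_coils == 1:
        maps = np.ones((1, n, n), dtype=np.complex128)
        return SensitivityMaps(maps=maps, support=np.ones((n, n), dtype=bool))
    maps = np.empty((n_coils, n, n), dtype=np.complex128)
    angles = 2 * np.pi * np.arange(n_coils) / n_coils
    for j, th in enumerate(angles):
        cx, cy = 1.15 * np.cos(th), 1.15 * np.sin(th)
        width = 0.95 + 0.1 * rng.uniform(-1, 1)
        mag = np.exp(-(((x - cx) ** 2 + (y - cy) ** 2) / (2 * width**2)))
        ph = (
            0.6 * (x * np.cos(th) + y * np.sin(th))
            + 0.25 * rng.uniform(-1, 1) * (x**2 - y**2)
            + rng.uniform(0, 2 * np.pi)
        )
        maps[j] = mag * np.exp(1j * ph)
    if null_in_first_coil:
        # a genuine complex null: the sensitivity crosses zero with unit
        # phase winding (vortex), the configuration that makes any phase
        # reference to this coil singular
        dx, dy = x - 0.15, y - 0.1
        rad = np.hypot(dx, dy)
        notch = 1.0 - np.exp(-(rad**2) / (2 * 0.2**2))
        vortex = (dx + 1j * dy) / np.maximum(rad, 1e-12)
        maps[0] = maps[0] * notch * vortex
    return SensitivityMaps(maps=maps, support=np.ones((n, n), dtype=bool))


@dataclass(frozen=True)
class SimulationSpec:
    """Acquisition-simulation settings.

    ``noise_sigma`` is the complex-Gaussian standard deviation per k-space
    sample, expressed relative to the mean sample magnitude of the
    noiseless data.  ``outlier_fraction`` of all samples are multiplied by
    ``outlier_scale`` to emulate spike corruption.  ``rejected_blades``
    are removed wholesale (the missing-blade model of patient motion).
    """

    blade: BladeSpec = dc_field(
        default_factory=lambda: BladeSpec(512, 35, 20, 256)
    )
    n_coils: int = 1
    noise_sigma: float = 0.5
    outlier_fraction: float = 0.0
    outlier_scale: float = 50.0
    rejected_blades: frozenset = frozenset()
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 <= self.outlier_fraction < 1:
            raise ValueError("outlier_fraction must lie in [0, 1)")
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be >= 0")
        rej = frozenset(int(b) for b in self.rejected_blades)
        object.__setattr__(self, "rejected_blades", rej)
        if rej and not rej < set(range(self.blade.n_blades)):
            raise ValueError("rejected_blades must be a proper subset of blades")


def simulate_acquisition(
    truth: np.ndarray,
    maps: SensitivityMaps | None,
    sim: SimulationSpec,
    plan: NufftPlan | None = None,
) -> KSpaceData:
    """Simulate BLADE k-space data from a ground-truth image.

    ``f_j = NUFFT(s_j * u) + noise``, then outlier corruption, then
    rejection of whole blades.  Bit-for-bit reproducible for a given
    ``(sim, truth, maps)``.
    """
    traj = make_blade_trajectory(sim.blade)
    if plan is None:
        plan = NufftPlan(traj, sim.blade.matrix_size)
    if maps is None:
        profiles = np.ones((1,) + truth.shape, dtype=np.complex128)
    else:
        profiles = maps.maps
        if profiles.shape[0] != sim.n_coils:
            raise ValueError("maps do not match n_coils")
    samples = np.stack([plan.forward(profiles[j] * truth) for j in range(len(profiles))])
    rng = np.random.default_rng(sim.seed)
    if sim.noise_sigma > 0:
        sigma = sim.noise_sigma * float(np.abs(samples).mean())
        noise = rng.standard_normal(samples.shape) + 1j * rng.standard_normal(samples.shape)
        samples = samples + sigma / np.sqrt(2.0) * noise
    if sim.outlier_fraction > 0:
        n_out = int(round(sim.outlier_fraction * samples.size))
        flat_idx = rng.choice(samples.size, size=n_out, replace=False)
        flat = samples.ravel()
        flat[flat_idx] = flat[flat_idx] * sim.outlier_scale
        samples = flat.reshape(samples.shape)
    data = KSpaceData(samples=samples, traj=traj)
    if sim.rejected_blades:
        keep = set(range(sim.blade.n_blades)) - set(sim.rejected_blades)
        data = data.select_blades(keep)
    return data


def reference_fixture(
    matrix_size: int = 256,
    noise_sigma: float = 0.5,
    n_rejected: int = 6,
    outlier_fraction: float = 0.0,
    seed: int = 0,
):
    """The reference simulation: 20 blades, the last ``n_rejected`` rejected.

    Returns ``(truth, labels, data)`` for a single-coil acquisition whose
    blade geometry scales with ``matrix_size``: readout is 2x oversampled
    and the blade width keeps the clinical protocol's 35-lines-per-256
    ratio, so the 20-blade trajectory over-samples angularly and retains
    near-complete coverage when 6 interspersed blades are rejected.
    """
    n_blades = 20
    n_lines = max(int(round(35 * matrix_size / 256)), 5)
    blade = BladeSpec(2 * matrix_size, n_lines, n_blades, matrix_size)
    pspec = PhantomSpec(matrix_size=matrix_size, seed=seed)
    truth, labels = make_phantom(pspec)
    if n_rejected:
        # rejected blades interspersed through the acquisition (motion is
        # intermittent, not angle-selective)
        step = max(n_blades // n_rejected, 1)
        rejected = []
        i = 0
        while len(rejected) < n_rejected:
            cand = (2 + i * step) % n_blades
            if cand not in rejected:
                rejected.append(cand)
            i += 1
    else:
        rejected = []
    sim = SimulationSpec(
        blade=blade,
        n_coils=1,
        noise_sigma=noise_sigma,
        outlier_fraction=outlier_fraction,
        rejected_blades=frozenset(rejected),
        seed=seed,
    )
    data = simulate_acquisition(truth, None, sim)
    return truth, labels, data
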