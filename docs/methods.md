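# Methods

This note records the mathematical model, the numerical choices, and the
limitations of the `bladerecon` package. It makes no empirical claims
beyond what the test suite and `scripts/acceptance.py` compute.

## Acquisition model

A BLADE (PROPELLER) acquisition covers 2-D k-space with `n_blades`
rectangular strips ("blades"), each a Cartesian grid of `n_readout x
n_lines` samples rotated by

    theta_b = offset + b * pi / n_blades,        b = 0 .. n_blades - 1.

Every blade crosses the k-space centre, which provides intrinsic motion
robustness (corrupted blades can be rejected wholesale) and a shared
low-frequency region for coil calibration. Coordinates are expressed in
radians per pixel, `k in [-pi, pi)^2`; rotated samples falling outside the
principal interval wrap around (the discrete spectrum is 2*pi-periodic, so
wrapping is exact, not an approximation). SENSE-style undersampling keeps
every `sense_factor`-th phase-encode line.

The forward (encoding) model for coil `j` with sensitivity `s_j` is

    f_j(k) = sum_x s_j(x) u(x) exp(-i k . x) + noise,

with pixel positions `x = index - N//2`. This is a type-2 non-uniform
discrete Fourier transform (NUFFT) of the sensitivity-weighted image.

## NUFFT implementation

No NUFFT library is available in the target environment, so the package
implements Kaiser-Bessel gridding directly (`bladerecon/nufft.py`):

* **Forward**: deapodise the image, zero-pad onto a 2x oversampled grid,
  FFT (with `ifftshift`/`fftshift` to realise the centred convention),
  then interpolate onto the sample coordinates with a separable
  Kaiser-Bessel kernel.
* **Adjoint**: the exact algebraic transpose (spread, inverse FFT, crop,
  deapodise). Adjointness holds to machine precision for any kernel
  width; this is load-bearing for the iterative solvers.
* **Kernel**: support `width` grid cells (default 6), shape parameter
  `beta` from the standard oversampling-dependent formula that minimises
  worst-case aliasing. The kernel's image-domain transform uses
  `sinh(q)/q` with the `sin(q)/q` analytic continuation where the
  argument turns imaginary.
* **Accuracy/speed trade-off**: width 6 gives ~4e-4 relative error
  against the direct DFT sum, which is far below the noise floor of any
  experiment here; the oracle tests use width 10 (~4e-8). Inner
  gather/scatter loops are `numba`-jitted when numba is importable, with
  a pure-numpy fallback.

**Density compensation** uses the fixed-point iteration
`w <- w / (G w)` where `G` is the kernel-autocorrelation
(spread-then-interpolate, no FFT); at the fixed point the kernel-smoothed
weighted sampling density is flat. The gridding reconstruction
`scale * A^H (W f)` is calibrated by one extra operator application so its
DC gain is exactly 1 (`NufftPlan.gridding_scale`); this absorbs the
geometry-dependent discrete-sampling factor that an analytic kernel-area
correction misses.

## Reconstruction algorithms

All iterative solvers operate on a spectrally normalised operator
(largest singular value estimated by power iteration with a deterministic
smooth start) and internally rescale the image and data to unit peak
intensity. This makes the shrinkage thresholds `lam/rho` and `mu/rho_f`
scale-free: the same defaults work regardless of acquisition scaling.

1. **Gridding** - density-compensated adjoint; the non-iterative
   baseline, also used as the warm start for every iterative method.
2. **LSMR least squares** - `min_u ||A u - f||_2^2` via
   `scipy.sparse.linalg.lsmr`, fixed iteration count, no damping.
3. **L1TV-OLS** - `min_u mu/2 ||A u - f||_2^2 + lam TV(u)` by split
   Bregman: auxiliary gradient field `d ~ grad(u)` updated by isotropic
   (joint-magnitude) complex soft-thresholding, quadratic subproblem
   solved by a few warm-started conjugate-gradient steps on
   `(mu A^H A + rho grad^T grad) u = rhs`, Bregman variables accumulated.
4. **L1TV-LAD** - `min_u mu ||A u - f||_1 + lam TV(u)` with a second
   splitting `r ~ A u - f` updated by scalar complex soft-thresholding;
   the robust fidelity down-weights amplitude outliers and corrupted
   samples.

TV is the isotropic total variation with periodic forward differences;
`div` is implemented as the exact negative adjoint of `grad`. A
divergence guard aborts if the objective exceeds 10x its reference scale
(the larger of the initial and the zero-image objective).

### Parameter defaults and rationale

| parameter | default | why |
|---|---|---|
| `lam` (TV weight) | 0.7 | centre of the insensitive plateau 0.4-1.0 verified by the lambda-plateau acceptance test |
| `mu` (fidelity weight) | 1.0 | matched across OLS/LAD so their comparison isolates the fidelity norm; under unit-intensity scaling mu=1 reproduces the characteristic over-smoothed TV-OLS look |
| `n_outer` | 100 | objective is flat well before 100 on all fixtures |
| `n_inner` (CG steps) | 5 | inexact inner solves are standard for split Bregman; warm starts carry progress |
| `rho`, `rho_f` | 1.0 | canonical penalty scale after normalisation |
| `width` (KB kernel) | 6 | see NUFFT accuracy note above |
| `oversampling` | 2.0 | standard gridding choice; makes kernel wrap exact |
| `dens_iters` | 20 | Pipe-Menon fixed point converges in ~10 on blade geometries |
| `center_radius` | pi/8 | low-frequency disk covered by every blade at all tested geometries |

## Coil-sensitivity estimation

Calibration images come from the shared central disk: per coil, the
density-compensated adjoint of the centre-masked data. Three estimators:

* **RSS**: divide by the root-sum-of-squares magnitude. Inherits the
  object phase (can wrap).
* **Power iteration**: per-voxel dominant eigenvector of a local coil
  covariance built from 16 overlapping box-smoothed copies of the
  calibration images, phase-referenced to coil 1. Where coil 1 has a
  complex zero the reference is undefined and the maps acquire a phase
  singularity - the documented failure mode.
* **Tensor iteration**: alternate (i) virtual body image
  `m = sum_j conj(s_j) c_j`, (ii) map update
  `s_j <- P[c_j conj(m) / (|m|^2 + eps)]` where `P` projects onto the
  central k-space disk through the NUFFT chain with a Hann-tapered
  window, (iii) per-voxel L2 normalisation. The projection enforces
  smoothness by construction; `eps = 1e-2 * max|m|^2` keeps the division
  stable in air. The taper and the relatively large epsilon are
  stabilisations: with a hard disk and a tiny epsilon the maps ring and
  lose their smoothness advantage.

All estimators return unit per-voxel norm maps on a support mask (5% of
peak RSS intensity).

## Synthetic phantom and simulator

The phantom is a set of rotated ellipse compartments (skull, CSF,
ventricle, grey matter, white matter, thalamus, globus pallidus, caudate
nucleus, putamen) with a smooth Gaussian-filtered intra-tissue texture
(5% relative), a slowly varying phase map, and exactly zero background.
Coil profiles are broad Gaussian lobes on a ring outside the FOV with
smooth phase (band-limited by construction); an optional variant gives
coil 1 a genuine complex zero with unit phase winding to provoke the
power-iteration singularity.

The simulator evaluates the exact forward model per coil, then adds
complex Gaussian noise (standard deviation relative to the mean sample
magnitude), multiplies a chosen fraction of samples by an outlier factor
(default 50x), and finally drops rejected blades. The reference fixture
uses 20 blades with the clinical protocol's blade width (35 lines per 256
matrix, 2x readout oversampling) and rejects 6 *interspersed* blades -
intermittent motion corrupts scattered blades, and scattered rejection
avoids a missing angular wedge.

### What the generator does and does not emulate

Emulated: blade geometry and rotation, SENSE line skipping, coil
sensitivity weighting, complex Gaussian receiver noise, amplitude spike
outliers, whole-blade motion rejection.

Not emulated: intra-blade motion and phase errors (clinical scanner
pipelines correct these before reconstruction), off-resonance/chemical
shift, T2 decay along the echo train, gradient nonlinearity, concrete
receive-chain scaling. Background air is exactly zero, so air-referenced
CNR degenerates after TV denoising; quality reports therefore use white
matter as the noise ROI (recorded in the report metadata).

## Metrics

* **SSIM**: `skimage.metrics.structural_similarity` with the standard
  constants (Gaussian window sigma 1.5, K1=0.01, K2=0.03, population
  covariance), data range = max of the reference.
* **L1/L2 error**: norms of the magnitude difference, optionally
  normalised by the reference norm (the L2 version is NRMSE).
* **CNR**: `|mean(roi) - mean(reference)| / std(noise_roi)` on the
  magnitude image; ROI choices are part of the metric definition and are
  reported alongside the value.
* **Phase smoothness**: mean absolute wrapped phase difference between
  4-neighbours inside a support mask; a linear ramp of slope `s`
  rad/pixel scores `|s|` along its axis. Used to quantify coil-map phase
  singularities.

## Numerical and reproducibility choices

* Everything is deterministic given the seeds: simulation randomness uses
  `numpy.random.default_rng(seed)`; the solvers contain no randomness
  (power iterations start from fixed smooth vectors).
* Complex arithmetic is `complex128` throughout; shrinkage operators are
  the exact complex proximal maps.
* The LSMR convergence record holds only the initial and final objective
  (scipy does not expose per-iteration iterates); split-Bregman records
  the objective at every outer iteration.

## Limitations

* 2-D single-slice only; no 3-D or multi-slice handling.
* No intra-blade phase/motion correction; blades are either kept or
  rejected.
* The NUFFT is specialised to square grids and 2x oversampling.
* Acceptance thresholds are verified on the synthetic phantom, not on
  patient data; the in vivo reader-score and ICC results that motivated
  the method are out of scope by design.
* At default width 6 the NUFFT is accurate to ~4e-4 relative; use
  `width=10` where 1e-6-level agreement with the exact DFT matters.
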