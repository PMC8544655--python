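"""NUFFT oracle and property tests against direct DFT evaluation."""

import numpy as np
import pytest

from bladerecon.containers import KSpaceData
from bladerecon.geometry import BladeSpec, KTrajectory, make_blade_trajectory
from bladerecon.nufft import (
    DensityWeights,
    NufftPlan,
    density_compensation,
    gridding_recon,
    nufft_adjoint,
    nufft_forward,
)


def direct_dft(img, coords):
    """Slow reference type-2 DFT: F(k) = sum_x u(x) e^{-i k.x}, x centred."""
    n = img.shape[0]
    x = np.arange(n) - n // 2
    e0 = np.exp(-1j * np.outer(coords[:, 0], x))  # (M, n) axis-0 phase
    e1 = np.exp(-1j * np.outer(coords[:, 1], x))
    return np.einsum("mi,ij,mj->m", e0, img.astype(np.complex128), e1)


def direct_adjoint(samples, coords, n):
    x = np.arange(n) - n // 2
    e0 = np.exp(1j * np.outer(x, coords[:, 0]))  # (n, M)
    e1 = np.exp(1j * np.outer(x, coords[:, 1]))
    return np.einsum("im,m,jm->ij", e0, samples.astype(np.complex128), e1)


@pytest.fixture(scope="module")
def test_image():
    rng = np.random.default_rng(11)
    n = 32
    img = rng.standard_normal((n, n)) + 1j * rng.standard_normal((n, n))
    from scipy.ndimage import gaussian_filter

    return gaussian_filter(img.real, 2) + 1j * gaussian_filter(img.imag, 2)


class TestForwardOracle:
    def test_matches_direct_dft_high_accuracy(self, test_image, random_traj):
        """Wide-kernel evaluation agrees with the exact DFT to < 1e-6."""
        plan = NufftPlan(random_traj, 32, width=10)
        got = plan.forward(test_image)
        want = direct_dft(test_image, random_traj.coords)
        rel = np.linalg.norm(got - want) / np.linalg.norm(want)
        assert rel < 1e-6

    def test_default_width_is_reasonably_accurate(self, test_image, random_traj):
        got = nufft_forward(test_image, random_traj)
        want = direct_dft(test_image, random_traj.coords)
        rel = np.linalg.norm(got - want) / np.linalg.norm(want)
        assert rel < 1e-3

    def test_center_impulse_gives_unit_modulus(self, random_traj):
        n = 32
        img = np.zeros((n, n), dtype=np.complex128)
        img[n // 2, n // 2] = 1.0  # x = 0 -> F(k) = 1 for every k
        got = NufftPlan(random_traj, n, width=10).forward(img)
        np.testing.assert_allclose(got, np.ones(len(got)), atol=1e-6)

    def test_linearity(self, test_image, random_traj):
        plan = NufftPlan(random_traj, 32)
        a, b = 2.0 - 1.0j, 0.3 + 0.7j
        other = np.roll(test_image, 5, axis=1)
        lhs = plan.forward(a * test_image + b * other)
        rhs = a * plan.forward(test_image) + b * plan.forward(other)
        np.testing.assert_allclose(lhs, rhs, rtol=1e-12, atol=1e-12)

    def test_dft_matrix_rows_match_cartesian_fft(self):
        """On the full Cartesian grid the NUFFT equals the centred FFT."""
        n = 16
        rng = np.random.default_rng(3)
        img = rng.standard_normal((n, n)) + 1j * rng.standard_normal((n, n))
        traj = make_blade_trajectory(BladeSpec(n, n, 1, n))
        got = NufftPlan(traj, n, width=10).forward(img)
        want = direct_dft(img, traj.coords)
        rel = np.linalg.norm(got - want) / np.linalg.norm(want)
        assert rel < 1e-6


class TestAdjointOracle:
    def test_adjoint_matches_direct(self, random_traj):
        rng = np.random.default_rng(5)
        m = len(random_traj)
        samples = rng.standard_normal(m) + 1j * rng.standard_normal(m)
        got = nufft_adjoint(samples, random_traj, 32, width=10)
        want = direct_adjoint(samples, random_traj.coords, 32)
        rel = np.linalg.norm(got - want) / np.linalg.norm(want)
        assert rel < 1e-6

    def test_inner_product_identity_over_random_draws(self, random_traj):
        """<A x, y> == <x, A^H y> for 20 random pairs (exact algebraic adjoint)."""
        plan = NufftPlan(random_traj, 32)
        rng = np.random.default_rng(17)
        m = plan.n_samples
        for _ in range(20):
            x = rng.standard_normal((32, 32)) + 1j * rng.standard_normal((32, 32))
            y = rng.standard_normal(m) + 1j * rng.standard_normal(m)
            lhs = np.vdot(y, plan.forward(x))
            rhs = np.vdot(plan.adjoint(y), x)
            assert abs(lhs - rhs) / max(abs(lhs), 1e-30) < 1e-6

    def test_shape_validation(self, random_traj):
        plan = NufftPlan(random_traj, 32)
        with pytest.raises(ValueError):
            plan.forward(np.zeros((16, 16)))
        with pytest.raises(ValueError):
            plan.adjoint(np.zeros(7))


class TestPlanConstruction:
    def test_out_of_range_coordinates_rejected(self):
        coords = np.array([[0.0, np.pi]])  # pi is outside [-pi, pi)
        with pytest.raises(ValueError):
            KTrajectory(coords, np.zeros(1, int), np.zeros(1, int))

    def test_deapodisation_is_positive(self, random_traj):
        plan = NufftPlan(random_traj, 32)
        assert np.all(plan._deapod > 0)


class TestDensityCompensation:
    def test_zero_iterations_returns_ones(self, random_traj):
        w = density_compensation(random_traj, 32, n_iter=0)
        np.testing.assert_array_equal(w.w, np.ones(len(random_traj)))

    def test_uniform_on_full_cartesian_grid(self):
        n = 32
        traj = make_blade_trajectory(BladeSpec(n, n, 1, n))
        w = density_compensation(traj, n).w
        assert w.std() / w.mean() < 0.01

    def test_center_weight_below_periphery_for_blades(self):
        traj = make_blade_trajectory(BladeSpec(128, 9, 20, 64))
        w = density_compensation(traj, 64).w
        r = np.hypot(traj.coords[:, 0], traj.coords[:, 1])
        center = w[r < 0.2 * np.pi].mean()
        periphery = w[r > 0.7 * np.pi].mean()
        assert center < periphery

    def test_weights_positive_and_finite(self, plan_and_weights64):
        _, weights = plan_and_weights64
        assert np.isfinite(weights.w).all()
        assert (weights.w > 0).all()

    @pytest.mark.parametrize(
        "bad",
        [np.array([-1.0, 2.0]), np.array([np.nan, 1.0]), np.zeros(3)],
    )
    def test_invalid_weights_rejected(self, bad):
        with pytest.raises(ValueError):
            DensityWeights(w=bad)


class TestGriddingRecon:
    def test_cartesian_noiseless_recovery(self):
        """Full Cartesian sampling: gridding inverts the forward model."""
        from bladerecon.phantom import PhantomSpec, make_phantom

        n = 64
        truth, _ = make_phantom(PhantomSpec(matrix_size=n))
        traj = make_blade_trajectory(BladeSpec(n, n, 1, n))
        plan = NufftPlan(traj, n)
        data = KSpaceData(samples=plan.forward(truth)[None], traj=traj)
        weights = density_compensation(traj, n, plan=plan)
        recon = gridding_recon(data, weights, plan=plan)
        nrmse = np.linalg.norm(np.abs(recon) - np.abs(truth)) / np.linalg.norm(
            np.abs(truth)
        )
        assert nrmse < 0.05

    def test_blade_noiseless_recovery(self, plan_and_weights64, multicoil64):
        """Multi-blade single-coil gridding approximates the truth."""
        truth, _, _, _ = multicoil64
        plan, weights = plan_and_weights64
        data = KSpaceData(samples=plan.forward(truth)[None], traj=plan.traj)
        recon = gridding_recon(data, weights, plan=plan)
        nrmse = np.linalg.norm(np.abs(recon) - np.abs(truth)) / np.linalg.norm(
            np.abs(truth)
        )
        assert nrmse < 0.2

    def test_zero_data_gives_zero_image(self, plan_and_weights64):
        plan, weights = plan_and_weights64
        data = KSpaceData(
            samples=np.zeros((1, plan.n_samples), dtype=np.complex128),
            traj=plan.traj,
        )
        recon = gridding_recon(data, weights, plan=plan)
        np.testing.assert_array_equal(recon, 0)

    def test_misaligned_weights_rejected(self, plan_and_weights64):
        plan, _ = plan_and_weights64
        data = KSpaceData(
            samples=np.zeros((1, plan.n_samples), dtype=np.complex128),
            traj=plan.traj,
        )
        with pytest.raises(ValueError):
            gridding_recon(data, DensityWeights(w=np.ones(5)), plan=plan)
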