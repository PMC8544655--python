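"""Coil-sensitivity estimators: unit norm, fidelity, smoothness, failure modes."""

import numpy as np
import pytest

from bladerecon.coils import (
    CenterMask,
    central_coil_images,
    estimate_maps,
    make_center_mask,
    power_iteration_maps,
    rss_maps,
    tensor_iteration_maps,
)
from bladerecon.nufft import NufftPlan, density_compensation
from bladerecon.metrics import phase_smoothness


@pytest.fixture(scope="module")
def calib64(multicoil64, plan_and_weights64):
    """Center mask, calibration images and all three map estimates."""
    _, _, maps_true, data = multicoil64
    plan, weights = plan_and_weights64
    mask = make_center_mask(data.traj)
    cimgs = central_coil_images(data, mask, weights, plan=plan)
    return {
        "mask": mask,
        "cimgs": cimgs,
        "rss": rss_maps(cimgs),
        "power": power_iteration_maps(cimgs),
        "tensor": tensor_iteration_maps(data, mask, weights, plan=plan),
        "true": maps_true,
    }


class TestCenterMask:
    def test_every_blade_contributes(self, multicoil64):
        _, _, _, data = multicoil64
        mask = make_center_mask(data.traj)
        for b in np.unique(data.traj.blade_index):
            assert mask.mask[data.traj.blade_index == b].any()

    def test_radius_selects_low_frequencies_only(self, multicoil64):
        _, _, _, data = multicoil64
        mask = make_center_mask(data.traj, radius=np.pi / 8)
        r = np.hypot(data.traj.coords[:, 0], data.traj.coords[:, 1])
        assert (r[mask.mask] < np.pi / 8).all()
        assert (r[~mask.mask] >= np.pi / 8).all()

    def test_dc_samples_always_selected(self, multicoil64):
        # every blade passes through k = 0 exactly, so even a vanishing
        # radius keeps one sample per blade
        _, _, _, data = multicoil64
        mask = make_center_mask(data.traj, radius=1e-9)
        assert mask.mask.sum() == len(np.unique(data.traj.blade_index))

    def test_blade_without_center_samples_rejected(self, multicoil64):
        from bladerecon.geometry import KTrajectory

        _, _, _, data = multicoil64
        r = np.hypot(data.traj.coords[:, 0], data.traj.coords[:, 1])
        ring = r > 0.5
        traj = KTrajectory(
            data.traj.coords[ring],
            data.traj.blade_index[ring],
            data.traj.line_index[ring],
        )
        with pytest.raises(ValueError):
            make_center_mask(traj, radius=0.3)

    def test_empty_mask_rejected(self):
        with pytest.raises(ValueError):
            CenterMask(mask=np.zeros(10, dtype=bool), radius=0.1)


class TestUnitNorm:
    @pytest.mark.parametrize("method", ["rss", "power", "tensor"])
    def test_maps_have_unit_voxel_norm_on_support(self, calib64, method):
        m = calib64[method]
        nrm = np.sqrt((np.abs(m.maps) ** 2).sum(axis=0))
        np.testing.assert_allclose(nrm[m.support], 1.0, atol=1e-12)

    def test_rss_zero_outside_support(self, calib64):
        m = calib64["rss"]
        assert np.abs(m.maps[:, ~m.support]).max() == 0.0


class TestSimpleOracles:
    def test_single_coil_rss_has_unit_magnitude(self):
        rng = np.random.default_rng(0)
        c = rng.standard_normal((1, 16, 16)) + 1j * rng.standard_normal((1, 16, 16))
        m = rss_maps(c)
        np.testing.assert_allclose(np.abs(m.maps[0][m.support]), 1.0, atol=1e-12)

    def test_two_equal_coils_give_inverse_sqrt2(self):
        c = np.ones((2, 8, 8), dtype=np.complex128)
        m = rss_maps(c)
        np.testing.assert_allclose(m.maps, 1 / np.sqrt(2), atol=1e-12)

    def test_power_iteration_recovers_known_eigenvector(self):
        # constant coil images (3, 4i): covariance is rank-1 with dominant
        # eigenvector (0.6, 0.8i) after phase-referencing to coil 1
        c = np.stack(
            [3.0 * np.ones((16, 16)), 4.0j * np.ones((16, 16))]
        ).astype(np.complex128)
        m = power_iteration_maps(c, acs=4, kernel_squares=4, n_iter=20)
        np.testing.assert_allclose(m.maps[0][m.support], 0.6, atol=1e-10)
        np.testing.assert_allclose(m.maps[1][m.support], 0.8j, atol=1e-10)

    def test_power_iteration_matches_dense_eigensolver(self, calib64):
        from bladerecon.coils import _smoothed_stack

        cimgs = calib64["cimgs"]
        m = calib64["power"]
        B = np.moveaxis(_smoothed_stack(cimgs, 16, 16), (0, 1), (2, 3))
        rng = np.random.default_rng(1)
        ij = list(zip(rng.integers(16, 48, 10), rng.integers(16, 48, 10)))
        for i, j in ij:
            if not m.support[i, j]:
                continue
            C = B[i, j] @ B[i, j].conj().T
            evals, evecs = np.linalg.eigh(C)
            v = evecs[:, -1]
            v = v * np.exp(-1j * np.angle(v[0]))
            np.testing.assert_allclose(m.maps[:, i, j], v, atol=1e-6)


class TestFidelity:
    @pytest.mark.parametrize("method", ["rss", "power", "tensor"])
    def test_alignment_with_true_profiles(self, calib64, method):
        """Mean per-voxel |<s_est, s_true>| on support is close to one."""
        m = calib64[method]
        t = calib64["true"].maps
        tn = t / np.sqrt((np.abs(t) ** 2).sum(axis=0))
        dot = np.abs(np.einsum("cxy,cxy->xy", np.conj(m.maps), tn))
        assert dot[calib64["rss"].support].mean() > 0.9

    def test_calibration_images_are_smooth(self, calib64):
        """Central-disk gridding yields low-frequency calibration images."""
        cimgs = calib64["cimgs"]
        n = cimgs.shape[1]
        k = np.fft.fftshift(np.fft.fftfreq(n)) * 2 * np.pi
        KX, KY = np.meshgrid(k, k, indexing="ij")
        r = np.hypot(KX, KY)
        for c in cimgs:
            F = np.abs(np.fft.fftshift(np.fft.fft2(c))) ** 2
            assert F[r >= np.pi / 4].sum() / F.sum() < 0.05

    def test_tensor_maps_are_band_limited(self, calib64):
        """Tensor maps concentrate energy inside the calibration disk."""
        m = calib64["tensor"]
        n = m.maps.shape[1]
        k = np.fft.fftshift(np.fft.fftfreq(n)) * 2 * np.pi
        KX, KY = np.meshgrid(k, k, indexing="ij")
        r = np.hypot(KX, KY)
        for c in m.maps:
            F = np.abs(np.fft.fftshift(np.fft.fft2(c))) ** 2
            assert F[r >= np.pi / 8].sum() / F.sum() < 0.05


class TestSingularityFailureMode:
    def test_tensor_smoother_than_power_under_coil_null(self, singularity64):
        """A complex null in the reference coil creates a phase singularity
        in the eigenvector maps; the low-frequency-projected maps stay smooth."""
        _, _, _, data = singularity64
        plan = NufftPlan(data.traj, 64)
        weights = density_compensation(data.traj, 64, plan=plan)
        mask = make_center_mask(data.traj)
        cimgs = central_coil_images(data, mask, weights, plan=plan)
        m_rss = rss_maps(cimgs)
        m_pow = power_iteration_maps(cimgs)
        m_ten = tensor_iteration_maps(data, mask, weights, plan=plan)
        sup = m_rss.support

        def smooth(m):
            return np.mean(
                [phase_smoothness(m.maps[c], sup) for c in range(1, m.maps.shape[0])]
            )

        s_pow, s_rss, s_ten = smooth(m_pow), smooth(m_rss), smooth(m_ten)
        assert s_ten < s_pow
        assert s_ten < s_rss


class TestDispatcher:
    @pytest.mark.parametrize("method", ["rss", "power", "tensor"])
    def test_estimate_maps_dispatch(self, multicoil64, method):
        _, _, _, data = multicoil64
        m = estimate_maps(data, method=method, matrix_size=64)
        assert m.maps.shape == (6, 64, 64)

    def test_unknown_method_rejected(self, multicoil64):
        _, _, _, data = multicoil64
        with pytest.raises(ValueError):
            estimate_maps(data, method="magic", matrix_size=64)

    def test_pairwise_map_agreement(self, calib64):
        """All three estimators agree on the sensitivity magnitudes."""
        sup = calib64["rss"].support
        mags = {
            k: np.abs(calib64[k].maps[:, sup]) for k in ("rss", "power", "tensor")
        }
        for a in mags:
            for b in mags:
                nrmse = np.linalg.norm(mags[a] - mags[b]) / np.linalg.norm(mags[b])
                assert nrmse < 0.25
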