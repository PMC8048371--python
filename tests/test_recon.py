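import dataclasses

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.ndimage import gaussian_filter

import raddwi as rd
from raddwi.recon import ramp_kernel


def _centered_echo(n=64, width=5.0):
    idx = np.arange(n) - n // 2
    return np.exp(-(idx / width) ** 2).astype(complex)


class TestPhaseCorrectView:
    def test_centered_real_echo_unchanged(self):
        e = _centered_echo()
        out = rd.phase_correct_radial(e)
        assert np.allclose(out, e, atol=1e-12)

    def test_inverts_known_constant_plus_linear_phase(self):
        e = _centered_echo()
        n = e.size
        idx = np.arange(n) - n // 2
        corrupted = e * np.exp(1j * (0.4 + 0.11 * idx))
        out = rd.phase_correct_radial(corrupted)
        assert np.max(np.abs(out - e)) / np.max(np.abs(e)) < 1e-6

    def test_magnitude_profile_preserved(self):
        rng = np.random.default_rng(0)
        v = (rng.standard_normal(64) + 1j * rng.standard_normal(64))
        v[32] += 30  # dominant centered echo
        out = rd.phase_correct_radial(v)
        assert np.allclose(np.abs(out), np.abs(v), rtol=1e-12)

    def test_all_zero_view_flagged(self):
        out, info = rd.phase_correct_radial(np.zeros(16, complex),
                                            return_info=True)
        assert info["all_zero"] and not out.any()

    def test_off_center_echo_recentered(self):
        e = np.roll(_centered_echo(), 5)
        out, info = rd.phase_correct_radial(e, return_info=True)
        assert info["recentered"]
        assert int(np.argmax(np.abs(out))) == 32

    def test_too_short_view_rejected(self):
        with pytest.raises(ValueError):
            rd.phase_correct_radial(np.ones(4, complex))

    @settings(deadline=None, max_examples=20)
    @given(phi0=st.floats(-3, 3), slope=st.floats(-0.3, 0.3))
    def test_pure_phase_operation(self, phi0, slope):
        e = _centered_echo()
        idx = np.arange(e.size) - e.size // 2
        corrupted = e * np.exp(1j * (phi0 + slope * idx))
        out = rd.phase_correct_radial(corrupted)
        assert np.allclose(np.abs(out), np.abs(corrupted), rtol=1e-10)


class TestStackCorrection:
    def test_identity_on_clean_static_data(self, gated_radial_noiseless):
        out = rd.correct_radial_stack(gated_radial_noiseless)
        # a non-negative object's echo is center-peaked with ~zero DC phase
        assert np.allclose(out.samples, gated_radial_noiseless.samples,
                           rtol=1e-7, atol=1e-9)

    def test_removes_bulk_view_phases(self, gated_radial_noiseless):
        rng = np.random.default_rng(1)
        phases = rng.uniform(-1.5, 1.5, size=101)
        corrupted = dataclasses.replace(
            gated_radial_noiseless,
            samples=gated_radial_noiseless.samples
            * np.exp(1j * phases)[None, None, :, None])
        out = rd.correct_radial_stack(corrupted)
        assert np.allclose(out.samples, gated_radial_noiseless.samples,
                           rtol=1e-7, atol=1e-9)


class TestFBP:
    def test_all_zero_kspace_gives_zero_image(self, gated_radial_noiseless):
        zero = dataclasses.replace(
            gated_radial_noiseless,
            samples=np.zeros_like(gated_radial_noiseless.samples))
        st_ = rd.fbp_reconstruct(zero)
        assert not st_.images.any()

    def test_too_few_views_rejected(self, gated_radial_noiseless):
        few = dataclasses.replace(
            gated_radial_noiseless,
            samples=gated_radial_noiseless.samples[:, :, :5, :])
        with pytest.raises(ValueError):
            rd.fbp_reconstruct(few)

    def test_bandlimited_phantom_recovered(self, still_model):
        # a phantom without energy beyond the sampled band reconstructs to
        # a fraction of a percent
        spec = rd.PhantomSpec(fov=32.0, compartments=[
            rd.Compartment("disk", (0, 0), (6, 6), s0=1.0, d_true=1e-3)])
        maps = rd.rasterize(spec, 64)
        smooth = gaussian_filter(maps.s0_map, 1.5)
        maps = dataclasses.replace(maps, s0_map=smooth)
        p = rd.radial_params(b_values=(0.0,), polarities=(1,))
        ks = rd.simulate_radial_kspace(maps, p, still_model, seed=0)
        img = rd.fbp_reconstruct(ks).images[0, 0]
        nrmse = np.sqrt(((img - smooth) ** 2).mean() / (smooth ** 2).mean())
        assert nrmse < 0.005

    def test_point_source_psf_symmetric(self, still_model):
        maps = rd.rasterize(rd.PhantomSpec(fov=32.0, compartments=[
            rd.Compartment("bg", (0, 0), (15, 15), s0=0.0, d_true=0.0)]), 64)
        s0 = np.zeros((64, 64))
        # pixel centers are at (n - 32 + 0.5)*pix; a symmetric pair at the
        # two central pixels makes an exactly grid-symmetric source
        s0[31:33, 31:33] = 1.0
        maps = dataclasses.replace(maps, s0_map=s0)
        p = rd.radial_params(b_values=(0.0,), polarities=(1,), n_views=101)
        ks = rd.simulate_radial_kspace(maps, p, still_model, seed=0)
        img = rd.fbp_reconstruct(ks).images[0, 0]
        assert np.allclose(img, img[::-1, :], atol=1e-6 * img.max())
        assert np.allclose(img, img[:, ::-1], atol=1e-6 * img.max())

    def test_matches_skimage_iradon_oracle(self, still_model):
        # independent back-projection oracle on the same k-space samples;
        # a centered circularly symmetric object sidesteps axis-orientation
        # conventions, and the remaining half-pixel grid offset (iradon
        # centers projections on sample N//2, ours sit between samples) is
        # registered out with a spline shift
        skimage = pytest.importorskip("skimage.transform")
        from scipy.ndimage import shift as ndshift
        spec = rd.PhantomSpec(fov=32.0, compartments=[
            rd.Compartment("disk", (0, 0), (6, 6), s0=1.0, d_true=1e-3)])
        maps = rd.rasterize(spec, 64)
        smooth = dataclasses.replace(
            maps, s0_map=gaussian_filter(maps.s0_map, 1.5))
        p = rd.radial_params(b_values=(0.0,), polarities=(1,))
        ks = rd.simulate_radial_kspace(smooth, p, still_model, seed=0)
        mine = rd.fbp_reconstruct(ks).images[0, 0]
        # sinogram on iradon's integer-radius grid
        N, V = 64, 101
        t_int = np.arange(N) - N // 2
        kap = (np.arange(N) - N / 2) / N
        E = np.exp(2j * np.pi * np.outer(t_int, kap)) / N
        sino = np.real(E @ ks.samples[0, 0].T)  # (r, view)
        theta = np.degrees(np.arange(V) * np.pi / V)
        other = skimage.iradon(sino, theta=theta, filter_name="ramp",
                               circle=False, output_size=64)
        registered = ndshift(np.abs(other), (-0.5, -0.5), order=3,
                             mode="nearest")
        nrmse = np.sqrt(((mine - registered) ** 2).mean()
                        / (mine ** 2).mean())
        assert nrmse < 0.05

    def test_ramp_kernel_matches_integral(self):
        # h(t) = int_{-1/2}^{1/2} |k| e^{2 pi i k t} dk, checked by
        # numerical quadrature
        k = np.linspace(-0.5, 0.5, 20001)
        for t in (0.0, 0.5, 1.0, 2.7, 6.0):
            num = np.trapezoid(np.abs(k) * np.cos(2 * np.pi * k * t), k)
            assert ramp_kernel(np.array([t]))[0] == pytest.approx(
                num, abs=1e-6)


class TestEpiRecon:
    def test_noiseless_artifact_free_matches_phantom(self, still_model):
        maps = rd.rasterize(rd.default_phantom(), 128)
        maps = dataclasses.replace(
            maps, shift_map=np.zeros_like(maps.shift_map))
        p = rd.epi_params(n_averages=1)
        ks = rd.simulate_epi_kspace(maps, p, still_model, seed=0)
        img = rd.epi_reconstruct(ks).images[0, 0]
        truth = rd.true_signal(maps, p.b_values[0])
        nrmse = np.sqrt(((img - truth) ** 2).mean() / (truth ** 2).mean())
        assert nrmse < 0.01

    def test_all_zero_input_gives_zero(self, still_model):
        maps = rd.rasterize(rd.default_phantom(), 64)
        maps = dataclasses.replace(maps,
                                   s0_map=np.zeros_like(maps.s0_map))
        p = rd.epi_params(matrix_read=64, matrix_phase=64, n_averages=1)
        ks = rd.simulate_epi_kspace(maps, p, still_model, seed=0)
        assert not rd.epi_reconstruct(ks).images.any()

    def test_missing_interleave_rejected(self, still_model):
        maps = rd.rasterize(rd.default_phantom(), 64)
        p = rd.epi_params(matrix_read=64, matrix_phase=64, n_averages=1)
        ks = rd.simulate_epi_kspace(maps, p, still_model, seed=0)
        broken = dataclasses.replace(ks, samples=ks.samples[:, :, :3])
        with pytest.raises(ValueError, match="interleave"):
            rd.epi_reconstruct(broken)

    def test_off_resonance_corrupts_shifted_compartment_only(self,
                                                             still_model):
        maps = rd.rasterize(rd.default_phantom(), 128)
        p = rd.epi_params(n_averages=1)
        ks = rd.simulate_epi_kspace(maps, p, still_model, seed=0)
        img = rd.epi_reconstruct(ks).images[0, 0]
        rois = rd.roi_masks(maps, erode=2)
        truth = rd.true_signal(maps, p.b_values[0])
        butanol_loss = 1 - img[rois["butanol"]].mean() / truth[
            rois["butanol"]].mean()
        tumor_err = abs(img[rois["tumor"]].mean() / truth[
            rois["tumor"]].mean() - 1)
        assert butanol_loss > 0.5  # strongly corrupted
        assert tumor_err < 0.05    # on-resonance tissue preserved


class TestEnergyConservation:
    def test_radial_energy_within_2pct(self, still_model):
        spec = rd.PhantomSpec(fov=32.0, compartments=[
            rd.Compartment("disk", (1, -2), (7, 5), s0=1.0, d_true=1e-3)])
        maps = rd.rasterize(spec, 64)
        smooth = dataclasses.replace(
            maps, s0_map=gaussian_filter(maps.s0_map, 1.2))
        p = rd.radial_params(b_values=(0.0,), polarities=(1,))
        ks = rd.simulate_radial_kspace(smooth, p, still_model, seed=0)
        img = rd.fbp_reconstruct(ks).images[0, 0]
        ratio = (img ** 2).sum() / (smooth.s0_map ** 2).sum()
        assert ratio == pytest.approx(1.0, abs=0.02)

    def test_epi_energy_within_2pct(self, still_model):
        spec = rd.PhantomSpec(fov=32.0, compartments=[
            rd.Compartment("disk", (1, -2), (7, 5), s0=1.0, d_true=1e-3)])
        maps = rd.rasterize(spec, 64)
        p = rd.epi_params(matrix_read=64, matrix_phase=64, n_averages=1)
        ks = rd.simulate_epi_kspace(maps, p, still_model, seed=0)
        img = rd.epi_reconstruct(ks).images[0, 0]
        ratio = (img ** 2).sum() / (maps.s0_map ** 2).sum()
        assert ratio == pytest.approx(1.0, abs=0.02)


class TestSnr:
    def test_zero_background_flagged_infinite(self):
        img = np.ones((32, 32))
        sig = np.zeros((32, 32), bool)
        bg = np.zeros((32, 32), bool)
        sig[10:20, 10:20] = True
        bg[:4] = True
        assert rd.snr(img, sig, bg) == np.inf

    def test_monte_carlo_recovers_true_snr(self):
        rng = np.random.default_rng(0)
        s0, sigma = 5.0, 0.4
        sig = np.zeros((48, 48), bool)
        sig[16:32, 16:32] = True
        bg = np.zeros((48, 48), bool)
        bg[:8] = True
        vals = []
        for _ in range(20):
            z = (rng.standard_normal((48, 48))
                 + 1j * rng.standard_normal((48, 48))) * sigma
            img = np.abs(s0 * sig + z)
            vals.append(rd.snr(img, sig, bg))
        assert np.mean(vals) == pytest.approx(s0 / sigma, rel=0.10)

    def test_linear_in_signal(self):
        rng = np.random.default_rng(1)
        z = (rng.standard_normal((32, 32))
             + 1j * rng.standard_normal((32, 32))) * 0.3
        sig = np.zeros((32, 32), bool)
        sig[12:20, 12:20] = True
        bg = np.zeros((32, 32), bool)
        bg[:6] = True
        a = rd.snr(np.abs(2.0 * sig + z), sig, bg)
        b = rd.snr(np.abs(4.0 * sig + z), sig, bg)
        assert b == pytest.approx(2 * a, rel=0.05)

    def test_overlapping_masks_rejected(self):
        m = np.ones((8, 8), bool)
        with pytest.raises(ValueError):
            rd.snr(np.ones((8, 8)), m, m)
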