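"""Phantom geometry, FID synthesis, k-space truncation and noise injection."""

import numpy as np
import pytest

from dmirecon.core import AcquisitionGrid, temporal_fft
from dmirecon.phantom import (
    BACKGROUND,
    BODY,
    FAT,
    GLUCOSE,
    GLX,
    LIVER,
    STOMACH,
    WATER,
    LIPID,
    NoiseLevel,
    PhantomSpec,
    SpectralPeak,
    add_complex_noise,
    build_label_volume,
    compartment_fids,
    render_highres,
    simulate_acquisition,
    synthesize_fid,
    truncate_to_grid,
)

from conftest import SEED


class TestLabelVolume:
    def test_labels_partition_body_and_all_compartments_nonempty(self):
        labels = build_label_volume(PhantomSpec())
        present = set(np.unique(labels))
        assert present == {BACKGROUND, BODY, LIVER, STOMACH, FAT}

    def test_degenerate_liver_raises_naming_the_compartment(self):
        spec = PhantomSpec(liver_semiaxes=(0.0, 0.0, 0.0))
        with pytest.raises(ValueError, match="liver"):
            build_label_volume(spec)

    def test_fat_rim_is_the_erosion_shell_of_the_body(self, small_phantom):
        """Brute-force morphological erosion oracle for the fat rim.

        The rim must equal body-minus-eroded-body (in-plane cross
        structuring element, iterated), except where liver/stomach were
        painted on top.
        """
        labels = build_label_volume(small_phantom)
        body_all = labels != BACKGROUND
        # manual erosion: survive if all 4 in-plane neighbours are body,
        # iterated rim-thickness times
        eroded = body_all.copy()
        for _ in range(small_phantom.fat_rim_voxels):
            nxt = eroded.copy()
            for axis, shift in ((0, 1), (0, -1), (1, 1), (1, -1)):
                rolled = np.roll(eroded, shift, axis=axis)
                # non-periodic boundary: rolled-in edge counts as outside
                sl = [slice(None)] * 3
                sl[axis] = 0 if shift == 1 else -1
                rolled[tuple(sl)] = False
                nxt &= rolled
            eroded = nxt
        shell = body_all & ~eroded
        organs = (labels == LIVER) | (labels == STOMACH)
        np.testing.assert_array_equal(labels == FAT, shell & ~organs)


class TestSynthesizeFid:
    def test_t0_value_is_sum_of_amplitudes(self, grid):
        fid = synthesize_fid([WATER], grid)
        assert fid[0] == pytest.approx(1.0)
        fid = synthesize_fid([WATER, GLUCOSE, GLX], grid)
        assert abs(fid[0]) == pytest.approx(1.0 + 0.8 + 0.6)

    def test_absorption_linewidth_matches_fwhm_within_one_bin(self, grid):
        """The real (absorption) lineshape of a 30 Hz Lorentzian measures
        30 Hz FWHM on the discrete spectrum, within one spectral bin."""
        fid = synthesize_fid([SpectralPeak("w", 4.7, 1.0, fwhm_hz=30.0)], grid)
        spec = np.fft.fftshift(np.fft.fft(fid, norm="ortho")).real
        half = spec.max() / 2
        above = np.flatnonzero(spec >= half)
        bin_hz = grid.bandwidth_hz / grid.n_time
        measured = (above.max() - above.min()) * bin_hz
        assert measured == pytest.approx(30.0, abs=bin_hz)

    def test_four_resonances_appear_at_their_chemical_shifts(self, grid):
        peaks = [WATER, GLUCOSE, GLX, LIPID]
        fid = synthesize_fid(peaks, grid)
        # absorption (real) spectrum: zero-phase lines peak symmetrically
        spec = np.fft.fftshift(np.fft.fft(fid)).real
        ppm = grid.ppm_axis()
        bin_ppm = grid.bandwidth_hz / grid.n_time / grid.larmor_mhz
        for peak in peaks:
            window = np.abs(ppm - peak.shift_ppm) < 0.25
            local = np.flatnonzero(window)[np.argmax(spec[window])]
            assert abs(ppm[local] - peak.shift_ppm) <= bin_ppm / 2 + 1e-9

    def test_peak_outside_bandwidth_raises(self, grid):
        rogue = SpectralPeak("rogue", 4.7 + 60.0, 1.0)  # ~2.7 kHz offset
        with pytest.raises(ValueError, match="rogue"):
            synthesize_fid([rogue], grid)


class TestRenderAndTruncate:
    def test_rendered_voxels_carry_their_compartment_fid(self, small_phantom):
        grid = AcquisitionGrid(nx=12, ny=12, nz=5, n_time=64)
        data = render_highres(small_phantom, grid)
        labels = build_label_volume(small_phantom)
        fids = compartment_fids(small_phantom, grid)
        liver_vox = np.argwhere(labels == LIVER)[0]
        np.testing.assert_allclose(data.values[tuple(liver_vox)], fids[LIVER])
        bg_vox = np.argwhere(labels == BACKGROUND)[0]
        assert np.all(data.values[tuple(bg_vox)] == 0)

    def test_total_energy_equals_compartment_sum(self, small_phantom):
        """Direct-summation oracle: total signal energy is the sum over
        compartments of voxel count times single-FID energy."""
        grid = AcquisitionGrid(nx=12, ny=12, nz=5, n_time=64)
        data = render_highres(small_phantom, grid)
        labels = build_label_volume(small_phantom)
        fids = compartment_fids(small_phantom, grid)
        expected = sum(
            np.sum(labels == code) * np.sum(np.abs(fid) ** 2)
            for code, fid in fids.items()
        )
        assert np.sum(np.abs(data.values) ** 2) == pytest.approx(expected)

    def test_truncation_to_same_dims_is_identity(self, small_phantom):
        grid = AcquisitionGrid(nx=12, ny=12, nz=5, n_time=64)
        data = render_highres(small_phantom, grid)
        hi_grid = data.grid
        out = truncate_to_grid(data, hi_grid)
        np.testing.assert_allclose(out.values, data.values, atol=1e-10)

    def test_constant_volume_stays_constant_with_preserved_level(self):
        grid_hi = AcquisitionGrid(nx=16, ny=16, nz=8, n_time=4)
        from dmirecon.core import SpatioSpectralData

        const = SpatioSpectralData(
            np.full((16, 16, 8, 4), 2.5 + 0j), grid_hi, "image", "time"
        )
        lo = truncate_to_grid(const, AcquisitionGrid(nx=8, ny=6, nz=4, n_time=4))
        np.testing.assert_allclose(lo.values, 2.5, atol=1e-12)

    def test_truncation_matches_brute_force_dft_oracle(self):
        """Centered k-space crop of a rect profile against an explicit DFT."""
        rng = np.random.default_rng(SEED)
        nx, lx = 16, 8
        x = np.zeros(nx, dtype=complex)
        x[5:11] = 1.0  # rect
        # oracle: explicit centered DFT matrices
        n = np.arange(nx)
        k = n - nx // 2
        F = np.exp(-2j * np.pi * np.outer(k, n - nx // 2) / nx) / np.sqrt(nx)
        kfull = F @ x
        crop = kfull[nx // 2 - lx // 2 : nx // 2 + lx // 2]
        m = np.arange(lx)
        kk = m - lx // 2
        Fi = np.exp(2j * np.pi * np.outer(m - lx // 2, kk) / lx) / np.sqrt(lx)
        expected = Fi @ crop * np.sqrt(lx / nx)

        from dmirecon.core import SpatioSpectralData

        grid_hi = AcquisitionGrid(nx=nx, ny=1, nz=1, n_time=2)
        data = SpatioSpectralData(
            np.tile(x[:, None, None, None], (1, 1, 1, 2)), grid_hi, "image", "time"
        )
        lo = truncate_to_grid(data, AcquisitionGrid(nx=lx, ny=1, nz=1, n_time=2))
        np.testing.assert_allclose(lo.values[:, 0, 0, 0], expected, atol=1e-10)

    def test_energy_never_increases_and_projection_is_idempotent(
        self, small_phantom
    ):
        grid = AcquisitionGrid(nx=12, ny=12, nz=5, n_time=16)
        data = render_highres(small_phantom, grid)
        lo_grid = AcquisitionGrid(nx=6, ny=8, nz=3, n_time=16)
        lo = truncate_to_grid(data, lo_grid)
        assert np.sum(np.abs(lo.values) ** 2) <= np.sum(np.abs(data.values) ** 2)
        lo2 = truncate_to_grid(lo, lo_grid)
        np.testing.assert_allclose(lo2.values, lo.values, atol=1e-10)

    def test_oversized_target_raises(self, small_phantom):
        grid = AcquisitionGrid(nx=12, ny=12, nz=5, n_time=16)
        data = render_highres(small_phantom, grid)
        with pytest.raises(ValueError):
            truncate_to_grid(data, AcquisitionGrid(nx=64, ny=12, nz=5, n_time=16))

    def test_simulate_acquisition_equals_render_then_truncate(self, small_phantom):
        """The factored per-compartment path is exactly the rendered path."""
        lo_grid = AcquisitionGrid(nx=8, ny=8, nz=5, n_time=32)
        hi = render_highres(small_phantom, lo_grid)
        expected = truncate_to_grid(hi, lo_grid)
        fast = simulate_acquisition(small_phantom, lo_grid)
        np.testing.assert_allclose(fast.values, expected.values, atol=1e-10)

    def test_noise_free_casorati_has_rank_four(self, study_inputs):
        """Partial separability: four distinct compartment spectra give a
        rank-4 Casorati matrix; singular values 5+ vanish."""
        C = study_inputs.rho.values.reshape(-1, study_inputs.grid.n_time)
        s = np.linalg.svd(C, compute_uv=False)
        assert s[4] / s[0] < 1e-10


class TestNoise:
    def test_zero_alpha_is_identity(self, small_phantom):
        grid = AcquisitionGrid(nx=8, ny=8, nz=5, n_time=32)
        data = simulate_acquisition(small_phantom, grid)
        out = add_complex_noise(data, NoiseLevel(0.0, seed=1))
        np.testing.assert_array_equal(out.values, data.values)

    def test_component_sd_is_alpha_over_sqrt2(self, small_phantom):
        grid = AcquisitionGrid(nx=16, ny=16, nz=8, n_time=1024)  # 2e6 samples
        data = simulate_acquisition(
            PhantomSpec(highres_dims=(16, 16, 8), fat_rim_voxels=1), grid
        )
        noisy = add_complex_noise(data, NoiseLevel(2.0, seed=3))
        diff = noisy.values - data.values
        assert np.std(diff.real) == pytest.approx(2.0 / np.sqrt(2), rel=0.01)
        assert np.std(diff.imag) == pytest.approx(2.0 / np.sqrt(2), rel=0.01)

    def test_deterministic_given_seed(self, small_phantom):
        grid = AcquisitionGrid(nx=8, ny=8, nz=5, n_time=32)
        data = simulate_acquisition(small_phantom, grid)
        a = add_complex_noise(data, NoiseLevel(1.0, seed=42))
        b = add_complex_noise(data, NoiseLevel(1.0, seed=42))
        np.testing.assert_array_equal(a.values, b.values)

    def test_snr_scales_inversely_with_alpha(self, study_inputs):
        """log-log regression of measured SNR against alpha has slope -1."""
        from dmirecon.experiment import roi_snr_samples

        alphas = np.array([0.05, 0.1, 0.2, 0.4])
        means = [
            roi_snr_samples(study_inputs, a, 40, seed=SEED).mean()
            for a in alphas
        ]
        slope = np.polyfit(np.log(alphas), np.log(means), 1)[0]
        assert slope == pytest.approx(-1.0, abs=0.02)
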