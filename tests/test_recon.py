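"""Forward model, PDHG subspace reconstruction, and the FFT baseline."""

import numpy as np
import pytest

from dmirecon.coils import CoilSensitivityMaps, combine_coils, normalize_csm, synthesize_csm
from dmirecon.core import (
    AcquisitionGrid,
    SpatioSpectralData,
    spatial_fft,
    spatial_ifft,
    temporal_fft,
)
from dmirecon.phantom import NoiseLevel, add_complex_noise
from dmirecon.recon import (
    ReconConfig,
    adjoint_model,
    compose_spatiospectral,
    fft_reconstruction,
    forward_model,
    solve_subspace_recon,
)
from dmirecon.sampling import SamplingMask, apply_sampling, generate_poisson_disk_mask
from dmirecon.subspace import TemporalBasis, build_casorati, estimate_temporal_basis

from conftest import SEED


def _random_basis(rng, L, M):
    A = rng.standard_normal((M, L)) + 1j * rng.standard_normal((M, L))
    Q, _ = np.linalg.qr(A)
    return TemporalBasis(V=Q.T[:L].copy(), singular_values=np.ones(M), L=L)


@pytest.fixture()
def small_problem(small_grid, rng):
    csm = normalize_csm(synthesize_csm(3, small_grid.shape, seed=SEED))
    basis = _random_basis(rng, 3, small_grid.n_time)
    mask = generate_poisson_disk_mask(small_grid.shape, 1.3, (3, 3, 3), seed=SEED)
    return small_grid, csm, basis, mask


class TestForwardModel:
    def test_zero_coefficients_give_zero_data(self, small_problem):
        grid, csm, basis, mask = small_problem
        U = np.zeros(grid.shape + (basis.L,), dtype=complex)
        out = forward_model(U, basis, csm, mask)
        assert np.all(out == 0)

    def test_reduces_to_plain_fft_for_trivial_operator(self, rng):
        """Single coil of ones, full sampling, identity temporal basis:
        the forward model is the plain spatial FFT of the image series."""
        grid = AcquisitionGrid(nx=4, ny=4, nz=2, n_time=8)
        csm = CoilSensitivityMaps(np.ones((1,) + grid.shape, dtype=complex), True)
        basis = TemporalBasis(
            V=np.eye(grid.n_time, dtype=complex),
            singular_values=np.ones(grid.n_time),
            L=grid.n_time,
        )
        mask = generate_poisson_disk_mask(grid.shape, 1.0, (2, 2, 2), seed=0)
        img = rng.standard_normal(grid.shape + (grid.n_time,)) + 1j * rng.standard_normal(
            grid.shape + (grid.n_time,)
        )
        out = forward_model(img, basis, csm, mask)
        np.testing.assert_allclose(out[..., 0], spatial_fft(img), atol=1e-12)

    def test_adjoint_inner_product_identity(self, small_problem, rng):
        grid, csm, basis, mask = small_problem
        U = rng.standard_normal(grid.shape + (basis.L,)) + 1j * rng.standard_normal(
            grid.shape + (basis.L,)
        )
        d = rng.standard_normal(
            grid.shape + (grid.n_time, csm.n_coil)
        ) + 1j * rng.standard_normal(grid.shape + (grid.n_time, csm.n_coil))
        lhs = np.vdot(forward_model(U, basis, csm, mask), d)
        rhs = np.vdot(U, adjoint_model(d, basis, csm, mask))
        assert abs(lhs - rhs) / abs(lhs) < 1e-10

    def test_dimension_mismatch_raises(self, small_problem, rng):
        grid, csm, basis, mask = small_problem
        bad = rng.standard_normal((2, 2, 2, basis.L)) + 0j
        with pytest.raises(ValueError):
            forward_model(bad, basis, csm, mask)


class TestSolveSubspaceRecon:
    def _simulate(self, grid, csm, basis, mask, U_true, alpha=0.0, seed=0):
        data = forward_model(U_true, basis, csm, mask)
        kdata = SpatioSpectralData(data, grid, "kspace", "time")
        if alpha > 0:
            kdata = add_complex_noise(kdata, NoiseLevel(alpha, seed=seed))
            kdata = apply_sampling(kdata, mask)
        return kdata

    def test_noiseless_fully_sampled_recovery(self, small_grid, rng):
        grid = small_grid
        csm = normalize_csm(synthesize_csm(3, grid.shape, seed=SEED))
        basis = _random_basis(rng, 3, grid.n_time)
        mask = generate_poisson_disk_mask(grid.shape, 1.0, (3, 3, 3), seed=0)
        U_true = rng.standard_normal(grid.shape + (3,)) + 1j * rng.standard_normal(
            grid.shape + (3,)
        )
        kdata = self._simulate(grid, csm, basis, mask, U_true)
        out = solve_subspace_recon(kdata, basis, csm, mask, ReconConfig(lam=0.0))
        rel = np.linalg.norm(out.U - U_true) / np.linalg.norm(U_true)
        assert rel < 1e-4

    def test_lambda_zero_matches_dense_normal_equations_oracle(
        self, small_grid, rng
    ):
        """8x8x3, L=3, single coil, full sampling: PDHG with lambda=0 equals
        the dense least-squares solution assembled column by column."""
        grid = small_grid
        csm = CoilSensitivityMaps(np.ones((1,) + grid.shape, dtype=complex), True)
        basis = _random_basis(rng, 3, grid.n_time)
        mask = generate_poisson_disk_mask(grid.shape, 1.0, (3, 3, 3), seed=0)
        U_true = rng.standard_normal(grid.shape + (3,)) + 1j * rng.standard_normal(
            grid.shape + (3,)
        )
        kdata = self._simulate(grid, csm, basis, mask, U_true)
        # add complex noise so the solution is a genuine LS solve
        kdata = add_complex_noise(kdata, NoiseLevel(0.3, seed=SEED))

        out = solve_subspace_recon(kdata, basis, csm, mask, ReconConfig(lam=0.0))

        # dense oracle on the flattened unknowns
        n_unknown = int(np.prod(grid.shape)) * basis.L
        nk = int(np.prod(grid.shape)) * grid.n_time
        A = np.zeros((nk, n_unknown), dtype=complex)
        for j in range(n_unknown):
            e = np.zeros(n_unknown)
            e[j] = 1.0
            col = forward_model(
                e.reshape(grid.shape + (basis.L,)), basis, csm, mask
            )[..., 0].ravel()
            A[:, j] = col
        rhs = kdata.values[..., 0].ravel()
        U_ls, *_ = np.linalg.lstsq(A, rhs, rcond=None)
        rel = np.linalg.norm(out.U.ravel() - U_ls) / np.linalg.norm(U_ls)
        assert rel < 1e-6

    def test_lambda_zero_pdgh_equals_cg_normal_equations_when_undersampled(
        self, small_problem, rng
    ):
        """PDHG and conjugate-gradient normal equations converge to the same
        minimizer of the undersampled least-squares problem."""
        from scipy.sparse.linalg import LinearOperator, cg

        grid, csm, basis, mask = small_problem
        U_true = rng.standard_normal(grid.shape + (3,)) + 1j * rng.standard_normal(
            grid.shape + (3,)
        )
        kdata = self._simulate(grid, csm, basis, mask, U_true, alpha=0.2, seed=3)

        cfg = ReconConfig(lam=0.0, n_iter=1500)
        out = solve_subspace_recon(kdata, basis, csm, mask, cfg)

        shape = grid.shape + (basis.L,)
        n = int(np.prod(shape))

        def normal_op(x):
            U = x.reshape(shape)
            return adjoint_model(
                forward_model(U, basis, csm, mask), basis, csm, mask
            ).ravel()

        op = LinearOperator((n, n), matvec=normal_op, dtype=complex)
        b = adjoint_model(kdata.values, basis, csm, mask).ravel()
        x, info = cg(op, b, rtol=1e-12, maxiter=2000)
        assert info == 0
        assert np.linalg.norm(out.U.ravel() - x) / np.linalg.norm(x) < 1e-6

    def test_objective_reported_and_negative_lambda_rejected(self, small_problem, rng):
        grid, csm, basis, mask = small_problem
        U_true = rng.standard_normal(grid.shape + (3,)) + 0j
        kdata = self._simulate(grid, csm, basis, mask, U_true, alpha=0.1, seed=1)
        out = solve_subspace_recon(
            kdata, basis, csm, mask, ReconConfig(lam=0.001, n_iter=10)
        )
        assert len(out.info["objective"]) == 10
        assert out.info["objective"][-1] <= out.info["objective"][0] * (1 + 1e-6)
        with pytest.raises(ValueError):
            ReconConfig(lam=-1.0)

    def test_solution_spectra_lie_in_the_subspace(self, small_problem, rng):
        grid, csm, basis, mask = small_problem
        U_true = rng.standard_normal(grid.shape + (3,)) + 0j
        kdata = self._simulate(grid, csm, basis, mask, U_true, alpha=0.2, seed=2)
        out = solve_subspace_recon(kdata, basis, csm, mask, ReconConfig())
        series = compose_spatiospectral(out, basis, grid).values
        flat = series.reshape(-1, grid.n_time)
        resid = flat - basis.project(flat)
        assert np.abs(resid).max() < 1e-10


class TestFftReconstruction:
    def test_noise_free_full_sampling_recovers_liver_spectrum(self, study_inputs):
        """At R=1.0 the baseline inverts the simulation exactly: a liver
        voxel shows its three resonances and nothing else."""
        spectra = fft_reconstruction(study_inputs.coil_kspace, study_inputs.csm)
        roi = np.argwhere(study_inputs.liver_roi)
        vox = tuple(roi[len(roi) // 2])
        spec = spectra.values[vox]
        direct = temporal_fft(
            study_inputs.rho.values[vox][None, None, None, :]
        )[0, 0, 0]
        np.testing.assert_allclose(spec, direct, atol=1e-8 * np.abs(direct).max())

    def test_parseval(self, study_inputs):
        spectra = fft_reconstruction(study_inputs.coil_kspace, study_inputs.csm)
        time_energy = np.sum(np.abs(spectra.to_time().values) ** 2)
        freq_energy = np.sum(np.abs(spectra.values) ** 2)
        assert freq_energy == pytest.approx(time_energy, rel=1e-10)

    def test_zero_filled_undersampled_matches_step_oracle(self, study_inputs):
        mask = generate_poisson_disk_mask(
            study_inputs.grid.shape, 1.3, (3, 5, 3), seed=SEED
        )
        noisy = add_complex_noise(
            study_inputs.coil_kspace, NoiseLevel(0.15, seed=SEED)
        )
        sampled = apply_sampling(noisy, mask)
        out = fft_reconstruction(sampled, study_inputs.csm)

        masked = noisy.values * mask.mask[..., None, None]
        imgs = spatial_ifft(masked)
        combined = combine_coils(imgs, study_inputs.csm)
        expected = temporal_fft(combined)
        np.testing.assert_allclose(out.values, expected, atol=1e-12)


class TestCompose:
    def test_rank_one_reproduces_the_fid_everywhere(self, small_grid):
        v = np.exp(-np.arange(small_grid.n_time) / 7.0).astype(complex)
        v /= np.linalg.norm(v)
        basis = TemporalBasis(V=v[None], singular_values=np.ones(1), L=1)
        U = np.ones(small_grid.shape + (1,), dtype=complex)
        out = compose_spatiospectral(U, basis, small_grid)
        np.testing.assert_allclose(out.values[2, 3, 1], v, atol=1e-14)

    def test_exact_subspace_round_trip(self, study_inputs):
        cas = build_casorati(study_inputs.rho)
        basis = estimate_temporal_basis(cas, 4)
        flat = study_inputs.rho.values.reshape(-1, study_inputs.grid.n_time)
        U = (flat @ basis.V.conj().T).reshape(
            study_inputs.grid.shape + (4,)
        )
        out = compose_spatiospectral(U, basis, study_inputs.grid)
        scale = np.abs(study_inputs.rho.values).max()
        np.testing.assert_allclose(
            out.values, study_inputs.rho.values, atol=1e-8 * scale
        )

    def test_frobenius_energy_identity_for_orthonormal_basis(self, small_grid, rng):
        basis = _random_basis(rng, 4, small_grid.n_time)
        U = rng.standard_normal(small_grid.shape + (4,)) + 1j * rng.standard_normal(
            small_grid.shape + (4,)
        )
        out = compose_spatiospectral(U, basis, small_grid)
        assert np.linalg.norm(out.values) == pytest.approx(
            np.linalg.norm(U), rel=1e-12
        )


def test_noise_floor_reduction_close_to_sqrt_M_over_L(small_grid, rng):
    """Rank-L projection of pure white noise reduces the per-sample SD by
    about sqrt(M/L) (the mechanism behind the SNR gain)."""
    M, L = small_grid.n_time, 4
    basis = _random_basis(rng, L, M)
    noise = rng.standard_normal((500, M)) + 1j * rng.standard_normal((500, M))
    projected = basis.project(noise)
    reduction = np.std(noise) / np.std(projected)
    assert reduction == pytest.approx(np.sqrt(M / L), rel=0.15)


def test_power_iteration_failure_raises(small_grid, rng):
    """An all-zero sampling pattern has zero operator norm; the step-size
    estimation must fail loudly instead of dividing by zero."""
    csm = normalize_csm(synthesize_csm(2, small_grid.shape, seed=0))
    basis = _random_basis(rng, 2, small_grid.n_time)
    mask = generate_poisson_disk_mask(small_grid.shape, 1.0, (2, 2, 2), seed=0)
    mask.mask[:] = False
    mask.mask[0, 0, 0] = True  # keep the mask "non-empty" but degenerate
    kdata = SpatioSpectralData(
        np.zeros(small_grid.shape + (small_grid.n_time, 2), dtype=complex),
        small_grid, "kspace", "time",
    )
    mask.mask[0, 0, 0] = False
    with pytest.raises(RuntimeError):
        solve_subspace_recon(kdata, basis, csm, mask, ReconConfig(lam=0.0))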