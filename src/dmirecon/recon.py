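"""Forward model and TV-regularized subspace reconstruction.

The discrete forward model for coil c is ``d_c = Omega F S_c U V + xi_c``:
spatial coefficient maps U (one per temporal basis function) are modulated by
the coil sensitivity, Fourier encoded, expanded through the temporal basis
and sampled on the k-space mask. The reconstruction solves

    min_U  1/2 sum_c || Omega F S_c U V - d_c ||_2^2  +  lambda ||D U||_1

with D the spatial finite-difference operator (anisotropic total variation
over the three axes, applied to each coefficient map), using the primal-dual
hybrid gradient (Chambolle-Pock) algorithm.

Because the rows of V are orthonormal and the sampling is spatial-only, the
data term can be contracted onto the subspace: with ``D_c = Omega(d_c V^H)``,
``||Omega F S_c U V - d_c||^2 = ||Omega F S_c U - D_c||^2 + const``. All
iterations therefore run on N x L arrays; the cost per iteration is
independent of the number of time points. The reported data objective is this
contracted form (it differs from the full residual by a U-independent
constant, the energy of the data outside the subspace).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .coils import CoilSensitivityMaps, combine_coils
from .core import SpatioSpectralData, spatial_fft, spatial_ifft, temporal_fft
from .sampling import SamplingMask
from .subspace import TemporalBasis


@dataclass
class SpatialCoefficients:
    """Subspace coefficient maps U of shape ``(nx, ny, nz, L)``."""

    U: np.ndarray
    info: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.U = np.asarray(self.U, dtype=np.complex128)
        if self.U.ndim != 4:
            raise ValueError("U must be (nx, ny, nz, L)")


@dataclass(frozen=True)
class ReconConfig:
    """Solver settings for the subspace reconstruction."""

    lam: float = 0.001
    n_iter: int = 30
    power_iters: int = 20
    step_scale: float = 0.99
    theta: float = 1.0
    tv_mode: str = "anisotropic"  # or "isotropic" (joint over the 3 axes)

    def __post_init__(self) -> None:
        if self.lam < 0:
            raise ValueError("lambda must be >= 0")
        if self.n_iter < 1:
            raise ValueError("n_iter must be >= 1")
        if self.tv_mode not in ("anisotropic", "isotropic"):
            raise ValueError(f"unknown tv_mode {self.tv_mode!r}")


# ----------------------------------------------------------------------
# linear operators
# ----------------------------------------------------------------------

def _coef_forward(
    U: np.ndarray, csm: CoilSensitivityMaps, mask: np.ndarray
) -> np.ndarray:
    """A: U (nx,ny,nz,L) -> per-coil sampled coefficient k-space (...,L,C)."""
    out = np.empty(U.shape + (csm.n_coil,), dtype=np.complex128)
    for c in range(csm.n_coil):
        out[..., c] = spatial_fft(csm.maps[c][..., None] * U)
    return out * mask[..., None, None]


def _coef_adjoint(
    Y: np.ndarray, csm: CoilSensitivityMaps, mask: np.ndarray
) -> np.ndarray:
    """A^H: per-coil coefficient k-space -> U domain."""
    Ym = Y * mask[..., None, None]
    out = np.zeros(Y.shape[:-1], dtype=np.complex128)
    for c in range(csm.n_coil):
        out += np.conj(csm.maps[c])[..., None] * spatial_ifft(Ym[..., c])
    return out


def forward_model(
    U: SpatialCoefficients | np.ndarray,
    basis: TemporalBasis,
    csm: CoilSensitivityMaps,
    mask: SamplingMask,
) -> np.ndarray:
    """Full forward model ``Omega F S_c (U V)`` per coil.

    Returns the sampled k-space data array of shape
    ``(nx, ny, nz, n_time, n_coil)`` (zeros at unsampled locations).
    """
    Ua = U.U if isinstance(U, SpatialCoefficients) else np.asarray(U)
    if Ua.shape[3] != basis.L:
        raise ValueError("U coefficient count does not match basis L")
    if csm.maps.shape[1:] != Ua.shape[:3] or mask.mask.shape != Ua.shape[:3]:
        raise ValueError("spatial dimension mismatch")
    coef_k = _coef_forward(Ua, csm, mask.mask)  # (x,y,z,L,C)
    return np.einsum("xyzlc,lm->xyzmc", coef_k, basis.V, optimize=True)


def adjoint_model(
    data: np.ndarray,
    basis: TemporalBasis,
    csm: CoilSensitivityMaps,
    mask: SamplingMask,
) -> np.ndarray:
    """Adjoint of :func:`forward_model`: data -> U domain."""
    D = np.einsum("xyzmc,lm->xyzlc", data, np.conj(basis.V), optimize=True)
    return _coef_adjoint(D, csm, mask.mask)


def _tv_forward(U: np.ndarray) -> np.ndarray:
    """Periodic forward differences along x, y, z: (3, nx, ny, nz, L)."""
    return np.stack(
        [np.roll(U, -1, axis=a) - U for a in range(3)], axis=0
    )


def _tv_adjoint(P: np.ndarray) -> np.ndarray:
    """Adjoint of `_tv_forward` (negative periodic divergence)."""
    out = np.zeros(P.shape[1:], dtype=P.dtype)
    for a in range(3):
        out += np.roll(P[a], 1, axis=a) - P[a]
    return out


def tv_norm(U: np.ndarray, mode: str = "anisotropic") -> float:
    """||D U||_1 on complex finite differences."""
    G = _tv_forward(U)
    if mode == "anisotropic":
        return float(np.sum(np.abs(G)))
    return float(np.sum(np.sqrt(np.sum(np.abs(G) ** 2, axis=0))))


# ----------------------------------------------------------------------
# solvers
# ----------------------------------------------------------------------

def _estimate_operator_norm(
    csm: CoilSensitivityMaps,
    mask: np.ndarray,
    L: int,
    lam: float,
    n_iter: int,
    seed: int = 0,
) -> float:
    """Power iteration on K^H K for the stacked operator K = [A; D]."""
    rng = np.random.default_rng(seed)
    shape = csm.maps.shape[1:] + (L,)
    x = rng.standard_normal(shape) + 1j * rng.standard_normal(shape)
    x /= np.linalg.norm(x)
    norm = 0.0
    for _ in range(n_iter):
        y = _coef_adjoint(_coef_forward(x, csm, mask), csm, mask)
        if lam > 0:
            y = y + _tv_adjoint(_tv_forward(x))
        norm = np.linalg.norm(y)
        if not np.isfinite(norm) or norm == 0:
            raise RuntimeError("power iteration for the operator norm failed")
        x = y / norm
    return float(np.sqrt(norm))


def solve_subspace_recon(
    data: SpatioSpectralData,
    basis: TemporalBasis,
    csm: CoilSensitivityMaps,
    mask: SamplingMask,
    cfg: ReconConfig = ReconConfig(),
) -> SpatialCoefficients:
    """TV-regularized subspace reconstruction by PDHG.

    ``data`` is the sampled multi-coil k-space (zeros at unsampled points).
    Returns the coefficient maps after ``cfg.n_iter`` iterations, with the
    per-iteration objective trace in ``info["objective"]``. Steps use
    sigma = tau = step_scale / ||K|| with the operator norm from power
    iteration; the primal is warm-started from the adjoint of the data.
    """
    if data.spatial_domain != "kspace" or data.temporal_domain != "time":
        raise ValueError("solver expects (kspace, time) data")
    if data.values.ndim != 5:
        raise ValueError("solver expects multi-coil data (x,y,z,t,coil)")
    m = mask.mask
    # contracted data D_c = Omega(d_c V^H), shape (x,y,z,L,C)
    D = np.einsum(
        "xyzmc,lm->xyzlc", data.values, np.conj(basis.V), optimize=True
    ) * m[..., None, None]

    op_norm = _estimate_operator_norm(
        csm, m, basis.L, cfg.lam, cfg.power_iters
    )
    sigma = tau = cfg.step_scale / op_norm

    U = _coef_adjoint(D, csm, m)  # adjoint warm start
    U_bar = U.copy()
    y1 = np.zeros_like(D)
    y2 = np.zeros((3,) + U.shape, dtype=np.complex128) if cfg.lam > 0 else None

    objective = []
    for _ in range(cfg.n_iter):
        # dual update, data term: prox of the conjugate of (1/2)||. - D||^2
        y1 = (y1 + sigma * (_coef_forward(U_bar, csm, m) - D)) / (1 + sigma)
        # dual update, TV term: projection onto the lambda ball
        if y2 is not None:
            v = y2 + sigma * _tv_forward(U_bar)
            if cfg.tv_mode == "anisotropic":
                mag = np.abs(v)
            else:
                mag = np.sqrt(np.sum(np.abs(v) ** 2, axis=0, keepdims=True))
            scale = np.maximum(1.0, mag / cfg.lam)
            y2 = v / scale
        # primal update
        grad = _coef_adjoint(y1, csm, m)
        if y2 is not None:
            grad = grad + _tv_adjoint(y2)
        U_new = U - tau * grad
        U_bar = U_new + cfg.theta * (U_new - U)
        U = U_new

        res = _coef_forward(U, csm, m) - D
        obj = 0.5 * float(np.sum(np.abs(res) ** 2))
        if cfg.lam > 0:
            obj += cfg.lam * tv_norm(U, cfg.tv_mode)
        objective.append(obj)

    info = {"objective": objective, "op_norm": op_norm, "sigma": sigma}
    if len(objective) > 1 and objective[-1] > objective[0] * (1 + 1e-6):
        info["warning"] = "objective increased over the run"
    return SpatialCoefficients(U, info)


def compose_spatiospectral(
    U: SpatialCoefficients | np.ndarray,
    basis: TemporalBasis,
    grid,
    to_frequency: bool = False,
) -> SpatioSpectralData:
    """Expand coefficient maps through the basis: ``rho(r, t) = U V``."""
    Ua = U.U if isinstance(U, SpatialCoefficients) else np.asarray(U)
    vals = np.einsum("xyzl,lm->xyzm", Ua, basis.V, optimize=True)
    out = SpatioSpectralData(vals, grid, "image", "time")
    return out.to_frequency() if to_frequency else out


def fft_reconstruction(
    data: SpatioSpectralData, csm: CoilSensitivityMaps | None = None
) -> SpatioSpectralData:
    """Zero-filled inverse-FFT baseline reconstruction.

    Inverse spatial FFT of the (zero-filled) k-space, conjugate-sensitivity
    coil combination when multi-coil, then unitary temporal FFT to spectra.
    """
    if data.spatial_domain != "kspace":
        raise ValueError("fft_reconstruction expects k-space data")
    imgs = spatial_ifft(data.values)
    if data.values.ndim == 5:
        if csm is None:
            raise ValueError("multi-coil data requires sensitivity maps")
        imgs = combine_coils(imgs, csm)
    if data.temporal_domain == "time":
        imgs = temporal_fft(imgs)
    return SpatioSpectralData(imgs, data.grid, "image", "frequency")
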