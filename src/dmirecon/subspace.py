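"""Temporal-subspace estimation from the fully sampled central k-space.

The spatiotemporal MRSI signal is partially separable: each voxel's FID is a
mixture of a handful of metabolite decay patterns, so the Casorati matrix
(voxels x time points) is low rank. The temporal basis V-hat is taken as the
L principal right singular vectors of the Casorati matrix built from the
coil-combined image time series of the central D1 k-space block.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .coils import CoilSensitivityMaps, combine_coils
from .core import SpatioSpectralData, center_slices, spatial_ifft


@dataclass
class CasoratiMatrix:
    """Voxels-by-time matrix with the index map back to the volume."""

    matrix: np.ndarray  # (N_kept, M)
    voxel_index: np.ndarray  # (N_kept,) flat indices into the volume (C order)
    shape: tuple[int, int, int]

    def to_volume(self) -> np.ndarray:
        """Scatter rows back to a (nx, ny, nz, M) volume (zeros elsewhere)."""
        out = np.zeros(
            (int(np.prod(self.shape)), self.matrix.shape[1]),
            dtype=self.matrix.dtype,
        )
        out[self.voxel_index] = self.matrix
        return out.reshape(self.shape + (self.matrix.shape[1],))


@dataclass
class TemporalBasis:
    """Orthonormal temporal basis rows spanning the signal subspace."""

    V: np.ndarray  # (L, M)
    singular_values: np.ndarray  # full spectrum, descending
    L: int
    d1_dims: tuple[int, int, int] | None = None

    def __post_init__(self) -> None:
        self.V = np.asarray(self.V)
        if self.V.shape[0] != self.L:
            raise ValueError("V row count does not match L")

    def project(self, series: np.ndarray) -> np.ndarray:
        """Project time series (..., M) onto span(V)."""
        coef = series @ self.V.conj().T
        return coef @ self.V


def extract_central_image(
    kdata: SpatioSpectralData,
    csm: CoilSensitivityMaps | None,
    d1_dims: tuple[int, int, int],
    mask: np.ndarray | None = None,
) -> SpatioSpectralData:
    """Coil-combined low-resolution image time series from the D1 core.

    The centered ``d1_dims`` k-space block is extracted per coil, zero-filled
    to the acquisition grid, inverse Fourier transformed, and combined with
    conjugate sensitivities. Raises if the provided sampling mask does not
    fully cover D1.
    """
    if kdata.spatial_domain != "kspace" or kdata.temporal_domain != "time":
        raise ValueError("extract_central_image expects (kspace, time) data")
    dims = kdata.values.shape[:3]
    sl = center_slices(dims, d1_dims)
    if mask is not None and not np.asarray(mask, dtype=bool)[sl].all():
        raise ValueError("D1 region is not fully sampled")
    kcrop = np.zeros_like(kdata.values)
    kcrop[sl] = kdata.values[sl]
    imgs = spatial_ifft(kcrop)
    if kdata.values.ndim == 5:
        if csm is None:
            raise ValueError("multi-coil data requires sensitivity maps")
        combined = combine_coils(imgs, csm)
    else:
        combined = imgs
    return SpatioSpectralData(combined, kdata.grid, "image", "time")


def build_casorati(
    image_time: SpatioSpectralData, support_mask: np.ndarray | None = None
) -> CasoratiMatrix:
    """Arrange the image time series as a Casorati matrix (one row per voxel).

    Row ordering is C order over (x, y, z); an optional support mask retains
    only in-support voxels.
    """
    if image_time.spatial_domain != "image" or image_time.temporal_domain != "time":
        raise ValueError("build_casorati expects (image, time) data")
    vals = image_time.values
    if vals.ndim != 4:
        raise ValueError("build_casorati expects single-channel data")
    shape = vals.shape[:3]
    flat = vals.reshape(-1, vals.shape[3])
    if support_mask is None:
        idx = np.arange(flat.shape[0])
    else:
        support_mask = np.asarray(support_mask, dtype=bool)
        if support_mask.shape != shape:
            raise ValueError("support mask shape mismatch")
        idx = np.flatnonzero(support_mask.reshape(-1))
        if idx.size == 0:
            raise ValueError("empty support mask")
    return CasoratiMatrix(flat[idx], idx, shape)


def estimate_temporal_basis(cas: CasoratiMatrix, L: int) -> TemporalBasis:
    """Top-L right singular vectors of the Casorati matrix.

    The unit-modulus phase ambiguity of each singular vector is fixed by
    rotating its largest-magnitude entry to the positive real axis, making
    runs reproducible.
    """
    n, m = cas.matrix.shape
    if not 1 <= L <= min(n, m):
        raise ValueError(f"L={L} outside [1, {min(n, m)}]")
    _, s, vh = np.linalg.svd(cas.matrix, full_matrices=False)
    V = vh[:L].copy()
    for row in V:
        k = np.argmax(np.abs(row))
        if row[k] != 0:
            row *= np.conj(row[k]) / np.abs(row[k])
    return TemporalBasis(V=V, singular_values=s, L=L)


def estimate_basis_from_kspace(
    kdata: SpatioSpectralData,
    csm: CoilSensitivityMaps | None,
    d1_dims: tuple[int, int, int],
    L: int,
    mask: np.ndarray | None = None,
    support_mask: np.ndarray | None = None,
) -> TemporalBasis:
    """Full pre-estimation chain: D1 crop -> combine -> Casorati -> SVD."""
    img = extract_central_image(kdata, csm, d1_dims, mask=mask)
    cas = build_casorati(img, support_mask=support_mask)
    basis = estimate_temporal_basis(cas, L)
    return TemporalBasis(basis.V, basis.singular_values, L, tuple(d1_dims))


def estimate_basis_fast(
    kdata: SpatioSpectralData,
    csm: CoilSensitivityMaps,
    d1_dims: tuple[int, int, int],
    L: int,
    mask: np.ndarray | None = None,
    support_mask: np.ndarray | None = None,
) -> TemporalBasis:
    """Exact fast path for :func:`estimate_basis_from_kspace`.

    The D1-cropped, coil-combined Casorati matrix factorizes as
    ``C = B K`` where ``K`` stacks the (few) retained k-space FIDs per coil
    and ``B`` collects the zero-fill/inverse-FFT impulse responses weighted
    by the conjugate sensitivities. Its right singular vectors are those of
    ``G^(1/2) K`` with the small Gram matrix ``G = B^H B``, so the SVD runs
    on a (n_coil * |D1|) x M matrix instead of N x M. Produces the same
    basis and (nonzero) singular values as the reference chain.
    """
    if kdata.spatial_domain != "kspace" or kdata.temporal_domain != "time":
        raise ValueError("estimate_basis_fast expects (kspace, time) data")
    if kdata.values.ndim != 5:
        raise ValueError("estimate_basis_fast expects multi-coil data")
    dims = kdata.values.shape[:3]
    n_coil = kdata.values.shape[4]
    sl = center_slices(dims, d1_dims)
    if mask is not None and not np.asarray(mask, dtype=bool)[sl].all():
        raise ValueError("D1 region is not fully sampled")

    # impulse responses of crop -> zero-fill -> unitary inverse FFT
    j = int(np.prod(d1_dims))
    impulses = np.zeros(dims + (j,), dtype=np.complex128)
    impulses[sl] = np.eye(j).reshape(tuple(d1_dims) + (j,))
    A = spatial_ifft(impulses).reshape(-1, j)  # (N, |D1|)

    n = int(np.prod(dims))
    s_flat = np.conj(csm.maps.reshape(n_coil, n))  # conj sensitivities
    if support_mask is not None:
        keep = np.asarray(support_mask, dtype=bool).reshape(-1)
        if not keep.any():
            raise ValueError("empty support mask")
        A = A[keep]
        s_flat = s_flat[:, keep]
    B = np.concatenate(
        [s_flat[c][:, None] * A for c in range(n_coil)], axis=1
    )  # (N_kept, n_coil * |D1|)
    K = np.concatenate(
        [kdata.values[sl][..., c].reshape(j, -1) for c in range(n_coil)],
        axis=0,
    )  # (n_coil * |D1|, M)

    G = B.conj().T @ B
    evals, evecs = np.linalg.eigh(G)
    root = (evecs * np.sqrt(np.clip(evals, 0.0, None))) @ evecs.conj().T
    _, s, vh = np.linalg.svd(root @ K, full_matrices=False)
    if not 1 <= L <= s.size:
        raise ValueError(f"L={L} outside [1, {s.size}]")
    V = vh[:L].copy()
    for row in V:
        k = np.argmax(np.abs(row))
        if row[k] != 0:
            row *= np.conj(row[k]) / np.abs(row[k])
    return TemporalBasis(V=V, singular_values=s, L=L, d1_dims=tuple(d1_dims))


def model_order_report(
    basis: TemporalBasis,
    significance: float = 0.1,
    flatness_tol: float = 0.05,
    zero_tol: float = 1e-8,
) -> dict:
    """Normalized singular-value spectrum and a suggested model order.

    The suggestion is the onset of the singular-value noise floor. Scanning
    the spectrum (normalized to the leading value) in descending order, a
    value marks the floor when it has dropped below ``significance`` and the
    relative step to its successor is smaller than ``flatness_tol`` — i.e.
    the spectrum has flattened into the plateau produced by measurement
    noise. The first plateau component is still counted (it carries whatever
    signal remains at the floor), so noisy data suggest one order more than
    the exact algebraic rank. A floor at numerical zero (below ``zero_tol``)
    is excluded instead: noise-free data suggest exactly their rank. A
    spectrum that never develops a floor (e.g. all values comparable) keeps
    every order.
    """
    s = np.asarray(basis.singular_values, dtype=float)
    if s.size == 0:
        raise ValueError("empty singular-value spectrum")
    normalized = s / s[0]
    n = normalized.size

    suggested = int(np.count_nonzero(normalized > zero_tol))
    zeros = np.flatnonzero(normalized <= zero_tol)
    limit = int(zeros[0]) if zeros.size else n  # suggested <= rank
    for i in range(limit - 1):
        if normalized[i] < significance and (
            normalized[i] - normalized[i + 1]
        ) < flatness_tol * normalized[i]:
            suggested = i + 1  # first floor component, kept as guard
            break
    else:
        suggested = min(suggested, limit)

    return {
        "normalized_singular_values": normalized,
        "suggested_L": suggested,
        "significance": significance,
        "flatness_tol": flatness_tol,
    }
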