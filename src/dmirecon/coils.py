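"""Coil sensitivity maps: synthesis, normalization, low-resolution estimation.

The simulation emulates a small receive array of surface loop coils placed
around the torso: each synthetic sensitivity is a smooth complex Gaussian
lobe centered outside the field of view with a gentle linear phase ramp.
Maps are normalized so that the sum of squared magnitudes is one at every
supported voxel, which makes conjugate-sensitivity coil combination unbiased
and keeps the noise scale alpha meaningful after combination.

For measured data a simplified estimator is provided: low-pass (central
k-space) per-coil images divided by their root sum of squares. It is a
deliberately simple surrogate for a full auto-calibrating method and is
labeled as such.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core import SpatioSpectralData, center_slices, spatial_ifft


@dataclass
class CoilSensitivityMaps:
    """Complex receive sensitivities, coil-leading: ``(n_coil, nx, ny, nz)``."""

    maps: np.ndarray
    normalized: bool = False

    def __post_init__(self) -> None:
        self.maps = np.asarray(self.maps, dtype=np.complex128)
        if self.maps.ndim != 4:
            raise ValueError("maps must be (n_coil, nx, ny, nz)")

    @property
    def n_coil(self) -> int:
        return self.maps.shape[0]

    def rss(self) -> np.ndarray:
        return np.sqrt(np.sum(np.abs(self.maps) ** 2, axis=0))


def synthesize_csm(
    n_coil: int,
    grid_dims: tuple[int, int, int],
    seed: int = 0,
    lobe_width: float = 0.9,
    phase_ramp_cycles: float = 0.25,
) -> CoilSensitivityMaps:
    """Smooth synthetic sensitivities for ``n_coil`` loop coils.

    Coil centers are spread around an ellipse just outside the in-plane field
    of view; magnitudes are Gaussian lobes (width ``lobe_width`` in normalized
    units) and each coil carries a distinct linear phase ramp plus a seeded
    random phase offset. Every voxel retains nonzero sensitivity on at least
    one coil.
    """
    if n_coil < 1:
        raise ValueError("n_coil must be >= 1")
    nx, ny, nz = grid_dims
    rng = np.random.default_rng(seed)
    x, y, z = np.meshgrid(
        np.linspace(-1, 1, nx), np.linspace(-1, 1, ny), np.linspace(-1, 1, nz),
        indexing="ij",
    )
    maps = np.empty((n_coil,) + tuple(grid_dims), dtype=np.complex128)
    for c in range(n_coil):
        ang = 2 * np.pi * c / n_coil + rng.uniform(-0.2, 0.2)
        cx, cy = 1.25 * np.cos(ang), 1.25 * np.sin(ang)
        d2 = (x - cx) ** 2 + (y - cy) ** 2 + 0.15 * z**2
        mag = np.exp(-d2 / (2 * lobe_width**2))
        ramp = phase_ramp_cycles * (
            np.cos(ang) * x + np.sin(ang) * y
        ) + rng.uniform(0, 1)
        maps[c] = mag * np.exp(2j * np.pi * ramp)
    return CoilSensitivityMaps(maps, normalized=False)


def normalize_csm(
    csm: CoilSensitivityMaps, support: np.ndarray | None = None
) -> CoilSensitivityMaps:
    """Normalize so that ``sum_c |s_c(r)|^2 = 1`` on the support.

    Relative inter-coil phases are preserved; voxels outside the support are
    zeroed. Raises if a supported voxel has zero sensitivity on every coil.
    """
    rss = csm.rss()
    if support is None:
        support = rss > 0
    support = np.asarray(support, dtype=bool)
    if support.shape != csm.maps.shape[1:]:
        raise ValueError("support shape does not match maps")
    if np.any(support & (rss == 0)):
        raise ValueError("all-zero sensitivity inside declared support")
    out = np.zeros_like(csm.maps)
    np.divide(csm.maps, rss[None], out=out, where=support[None])
    return CoilSensitivityMaps(out, normalized=True)


def combine_coils(images: np.ndarray, csm: CoilSensitivityMaps) -> np.ndarray:
    """Conjugate-sensitivity coil combination.

    ``images`` has the coil axis last: ``(nx, ny, nz, ..., n_coil)``; returns
    ``sum_c conj(s_c) * x_c`` with the coil axis removed.
    """
    if images.shape[-1] != csm.n_coil:
        raise ValueError("coil axis mismatch")
    s = np.moveaxis(csm.maps, 0, -1)  # (nx, ny, nz, n_coil)
    extra = images.ndim - s.ndim
    s = s.reshape(s.shape[:3] + (1,) * extra + (s.shape[-1],))
    return np.sum(np.conj(s) * images, axis=-1)


def estimate_csm_lowres(
    kdata: SpatioSpectralData,
    calib_dims: tuple[int, int, int],
    mask: np.ndarray | None = None,
    support_threshold: float = 0.05,
) -> CoilSensitivityMaps:
    """Estimate sensitivities from the fully sampled central k-space.

    Synthetic-data surrogate for auto-calibrated estimation: the central
    ``calib_dims`` block of each coil's k-space (at the first FID sample,
    water-dominated) is zero-filled and inverse transformed; maps are the
    per-coil low-pass images divided by their root sum of squares, then
    normalized and phase-referenced to coil 1.
    """
    if kdata.spatial_domain != "kspace":
        raise ValueError("estimate_csm_lowres expects k-space data")
    if kdata.values.ndim != 5:
        raise ValueError("estimate_csm_lowres expects multi-coil data")
    dims = kdata.values.shape[:3]
    if any(c > d for c, d in zip(calib_dims, dims)):
        raise ValueError("calib_dims exceed grid dims")
    sl = center_slices(dims, calib_dims)
    if mask is not None and not np.asarray(mask, dtype=bool)[sl].all():
        raise ValueError("calibration region is not fully sampled")

    k0 = kdata.values[..., 0, :]  # (nx, ny, nz, n_coil), first FID sample
    kcal = np.zeros_like(k0)
    kcal[sl] = k0[sl]
    imgs = spatial_ifft(kcal)
    rss = np.sqrt(np.sum(np.abs(imgs) ** 2, axis=-1))
    support = rss > support_threshold * rss.max()
    maps = np.zeros_like(imgs)
    np.divide(imgs, rss[..., None], out=maps, where=support[..., None])
    maps = np.moveaxis(maps, -1, 0)
    # phase-reference to coil 1 so maps are comparable across estimates
    ref = maps[0]
    phase = np.ones_like(ref)
    nz = np.abs(ref) > 0
    phase[nz] = ref[nz] / np.abs(ref[nz])
    maps = maps * np.conj(phase)[None]
    return normalize_csm(CoilSensitivityMaps(maps), support=support)
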