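"""Digital torso phantom for 3D deuterium metabolic imaging simulations.

A three-compartment torso (liver, stomach, rest-of-body with a subcutaneous
fat rim) is rasterized procedurally at high resolution (default 256 x 256 x 15),
filled with compartment-specific deuterium FIDs (Lorentzian resonances for
deuterated water, glucose, Glx and lipid), truncated in k-space to the
acquisition matrix (default 12 x 18 x 15) to create realistic partial-volume
mixing, and finally corrupted with calibrated complex white Gaussian noise.

Compartment spectral content:

* liver:   water (4.7 ppm, amp 1.0) + glucose (3.8 ppm, 0.8) + Glx (2.25 ppm, 0.6)
* stomach: water + glucose
* body:    water only
* fat rim: water + lipid (1.3 ppm, 0.6)

All resonances use a 30 Hz Lorentzian linewidth (FWHM); the time-domain decay
rate is pi * FWHM and the amplitude is the t=0 FID magnitude.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np
from scipy import ndimage

from .core import (
    AcquisitionGrid,
    SpatioSpectralData,
    center_slices,
    spatial_fft,
    spatial_ifft,
)

# Label codes of the rasterized phantom volume.
BACKGROUND, BODY, LIVER, STOMACH, FAT = 0, 1, 2, 3, 4
LABEL_NAMES = {BODY: "body", LIVER: "liver", STOMACH: "stomach", FAT: "fat"}

#: Noise scales (alpha) as printed for nominal SNR 60 / 30 / 15 / 5. Only the
#: ratios are meaningful across signal conventions; absolute levels are
#: re-calibrated against the phantom (experiment.calibrate_alpha).
ALPHA_BY_SNR = {60: 0.923, 30: 1.830, 15: 3.700, 5: 10.900}

METABOLITES = ("water", "glucose", "glx", "lipid")


@dataclass(frozen=True)
class SpectralPeak:
    """One Lorentzian resonance of the FID model."""

    name: str
    shift_ppm: float
    amplitude: float
    fwhm_hz: float = 30.0
    phase_rad: float = 0.0

    def __post_init__(self) -> None:
        if self.fwhm_hz <= 0:
            raise ValueError(f"peak {self.name!r}: fwhm_hz must be positive")
        if self.amplitude < 0:
            raise ValueError(f"peak {self.name!r}: amplitude must be >= 0")


WATER = SpectralPeak("water", 4.7, 1.0)
GLUCOSE = SpectralPeak("glucose", 3.8, 0.8)
GLX = SpectralPeak("glx", 2.25, 0.6)
LIPID = SpectralPeak("lipid", 1.3, 0.6)

DEFAULT_COMPARTMENT_PEAKS: dict[int, tuple[SpectralPeak, ...]] = {
    LIVER: (WATER, GLUCOSE, GLX),
    STOMACH: (WATER, GLUCOSE),
    BODY: (WATER,),
    FAT: (WATER, LIPID),
}


@dataclass(frozen=True)
class PhantomSpec:
    """Procedural geometry + spectral content of the torso phantom.

    Geometry parameters are fractions of the high-resolution matrix so the
    phantom scales with ``highres_dims``. The body is a superellipse cylinder,
    liver and stomach are ellipsoids, and the subcutaneous fat rim is the
    in-plane boundary shell of the body of ``fat_rim_voxels`` thickness.
    """

    highres_dims: tuple[int, int, int] = (256, 256, 15)
    body_semiaxes: tuple[float, float] = (0.36, 0.46)
    body_exponent: float = 2.5
    liver_center: tuple[float, float, float] = (0.45, 0.41, 0.50)
    liver_semiaxes: tuple[float, float, float] = (0.26, 0.30, 0.48)
    stomach_center: tuple[float, float, float] = (0.64, 0.67, 0.50)
    stomach_semiaxes: tuple[float, float, float] = (0.13, 0.14, 0.36)
    fat_rim_voxels: int = 10
    compartment_peaks: Mapping[int, tuple[SpectralPeak, ...]] = field(
        default_factory=lambda: dict(DEFAULT_COMPARTMENT_PEAKS)
    )

    def peaks_for(self, label: int) -> tuple[SpectralPeak, ...]:
        return tuple(self.compartment_peaks[label])


@dataclass(frozen=True)
class NoiseLevel:
    """Complex-noise scale alpha, its nominal SNR, and the RNG seed."""

    alpha: float
    target_snr: float | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.alpha < 0:
            raise ValueError("alpha must be >= 0")


# ----------------------------------------------------------------------
# geometry
# ----------------------------------------------------------------------

def build_label_volume(spec: PhantomSpec) -> np.ndarray:
    """Rasterize the phantom into an integer label volume.

    Returns an int8 array of ``spec.highres_dims`` where every voxel carries
    exactly one of BACKGROUND/BODY/LIVER/STOMACH/FAT. Raises ``ValueError``
    naming the first compartment that rasterizes empty.
    """
    dims = spec.highres_dims
    if min(dims) < 8:
        raise ValueError("highres_dims must all be >= 8")
    nx, ny, nz = dims
    x, y, z = np.meshgrid(
        np.arange(nx), np.arange(ny), np.arange(nz), indexing="ij"
    )
    # normalized coordinates in [-1, 1] per axis
    xr = (x - (nx - 1) / 2) / (nx / 2)
    yr = (y - (ny - 1) / 2) / (ny / 2)
    zr = (z - (nz - 1) / 2) / (nz / 2)

    ax, ay = spec.body_semiaxes
    p = spec.body_exponent
    if ax <= 0 or ay <= 0:
        raise ValueError("degenerate geometry: compartment 'body' is empty")
    body = (np.abs(xr / (2 * ax)) ** p + np.abs(yr / (2 * ay)) ** p) <= 1.0

    labels = np.where(body, BODY, BACKGROUND).astype(np.int8)

    # subcutaneous fat = in-plane boundary shell of the body
    if spec.fat_rim_voxels > 0:
        struct = np.zeros((3, 3, 1), dtype=bool)
        struct[1, :, 0] = True
        struct[:, 1, 0] = True
        eroded = ndimage.binary_erosion(
            body, structure=struct, iterations=spec.fat_rim_voxels
        )
        labels[body & ~eroded] = FAT

    def ellipsoid(center, semi):
        cx, cy, cz = center
        sx, sy, sz = semi
        if min(sx, sy, sz) <= 0:
            return np.zeros(dims, dtype=bool)
        return (
            ((xr - (2 * cx - 1)) / (2 * sx)) ** 2
            + ((yr - (2 * cy - 1)) / (2 * sy)) ** 2
            + ((zr - (2 * cz - 1)) / (2 * sz)) ** 2
        ) <= 1.0

    stomach = ellipsoid(spec.stomach_center, spec.stomach_semiaxes) & body
    labels[stomach] = STOMACH
    liver = ellipsoid(spec.liver_center, spec.liver_semiaxes) & body
    labels[liver] = LIVER

    for code, name in LABEL_NAMES.items():
        if not np.any(labels == code):
            raise ValueError(
                f"degenerate geometry: compartment {name!r} is empty"
            )
    return labels


# ----------------------------------------------------------------------
# spectroscopy
# ----------------------------------------------------------------------

def synthesize_fid(
    peaks: Iterable[SpectralPeak], grid: AcquisitionGrid
) -> np.ndarray:
    """Noise-free FID of a sum of Lorentzian resonances.

    ``s(t) = sum_p a_p exp(i phi_p) exp(i 2 pi f_p t) exp(-pi FWHM_p t)``
    with ``f_p`` the offset of ``shift_ppm`` from the carrier. Raises if a
    resonance falls outside the spectral window (it would alias silently).
    """
    t = grid.time_axis()
    s = np.zeros(grid.n_time, dtype=np.complex128)
    half_bw = grid.bandwidth_hz / 2.0
    for p in peaks:
        f = float(grid.ppm_to_hz(p.shift_ppm))
        if abs(f) >= half_bw:
            raise ValueError(
                f"peak {p.name!r} at {p.shift_ppm} ppm ({f:+.1f} Hz) lies "
                f"outside the +/-{half_bw:.0f} Hz spectral window"
            )
        s += (
            p.amplitude
            * np.exp(1j * p.phase_rad)
            * np.exp((2j * np.pi * f - np.pi * p.fwhm_hz) * t)
        )
    return s


def compartment_fids(
    spec: PhantomSpec, grid: AcquisitionGrid
) -> dict[int, np.ndarray]:
    """FID of each compartment label."""
    return {
        code: synthesize_fid(spec.peaks_for(code), grid)
        for code in LABEL_NAMES
    }


def render_highres(spec: PhantomSpec, grid: AcquisitionGrid) -> SpatioSpectralData:
    """Materialize the full high-resolution spatiotemporal phantom.

    Memory scales as ``prod(highres_dims) * n_time``; at the full study size
    this is impractically large, so the acquisition-grid pipeline uses
    :func:`simulate_acquisition` (mathematically identical). This op is meant
    for reduced sizes and verification.
    """
    labels = build_label_volume(spec)
    fids = compartment_fids(spec, grid)
    hi_grid = grid.with_shape(spec.highres_dims)
    values = np.zeros(spec.highres_dims + (grid.n_time,), dtype=np.complex128)
    for code, fid in fids.items():
        values[labels == code] = fid
    return SpatioSpectralData(values, hi_grid, "image", "time")


def truncate_to_grid(
    highres: SpatioSpectralData, grid: AcquisitionGrid
) -> SpatioSpectralData:
    """Down-sample by centered k-space truncation.

    The image is transformed to k-space, the central ``grid.shape`` block is
    extracted, and the result transformed back at the low resolution. The crop
    is rescaled by ``sqrt(N_low / N_high)`` so voxel intensities (e.g. the DC
    level of a constant object) are preserved rather than the array norm;
    total energy can only decrease. Partial-volume mixing and Gibbs ringing of
    the low-resolution maps arise here.
    """
    if highres.spatial_domain != "image":
        raise ValueError("truncate_to_grid expects image-domain data")
    hi_dims = highres.values.shape[:3]
    lo_dims = grid.shape
    if any(l > h for l, h in zip(lo_dims, hi_dims)):
        raise ValueError(
            f"acquisition dims {lo_dims} exceed high-res dims {hi_dims}"
        )
    k = spatial_fft(highres.values)
    crop = k[center_slices(hi_dims, lo_dims)]
    scale = np.sqrt(np.prod(lo_dims) / np.prod(hi_dims))
    lo = spatial_ifft(crop * scale)
    return SpatioSpectralData(
        lo, grid, "image", highres.temporal_domain
    )


def lowres_compartment_maps(
    spec: PhantomSpec, grid: AcquisitionGrid
) -> dict[int, np.ndarray]:
    """Partial-volume (k-space-truncated) indicator map of each compartment.

    Each map is the centered k-space truncation of the binary high-resolution
    compartment mask, complex-valued because of Gibbs ringing; interior voxels
    approach 1.
    """
    labels = build_label_volume(spec)
    hi_dims = spec.highres_dims
    lo_dims = grid.shape
    scale = np.sqrt(np.prod(lo_dims) / np.prod(hi_dims))
    sl = center_slices(hi_dims, lo_dims)
    maps = {}
    for code in LABEL_NAMES:
        mask = (labels == code).astype(np.float64)
        maps[code] = spatial_ifft(spatial_fft(mask)[sl] * scale)
    return maps


def simulate_acquisition(
    spec: PhantomSpec, grid: AcquisitionGrid
) -> SpatioSpectralData:
    """Noise-free acquisition-grid phantom data (image space, time domain).

    Equivalent to ``truncate_to_grid(render_highres(spec, grid), grid)`` but
    computed compartment-by-compartment: k-space truncation is linear and
    spatial-only, and each compartment's signal is the outer product of its
    indicator map with a single FID, so only ``n_compartments`` 3D FFTs of the
    high-resolution masks are needed.
    """
    maps = lowres_compartment_maps(spec, grid)
    fids = compartment_fids(spec, grid)
    values = np.zeros(grid.shape + (grid.n_time,), dtype=np.complex128)
    for code, m in maps.items():
        values += m[..., None] * fids[code][None, None, None, :]
    return SpatioSpectralData(values, grid, "image", "time")


def true_amplitude_maps(
    spec: PhantomSpec, grid: AcquisitionGrid
) -> dict[str, np.ndarray]:
    """Ground-truth metabolite amplitude maps on the acquisition grid.

    Magnitude of the sum over compartments of (metabolite amplitude x
    partial-volume map); the reference for bias maps.
    """
    maps = lowres_compartment_maps(spec, grid)
    out: dict[str, np.ndarray] = {}
    for met in METABOLITES:
        acc = np.zeros(grid.shape, dtype=np.complex128)
        for code, m in maps.items():
            for p in spec.peaks_for(code):
                if p.name == met:
                    acc += p.amplitude * m
        out[met] = np.abs(acc)
    return out


def liver_roi_mask(
    spec: PhantomSpec, grid: AcquisitionGrid, threshold: float = 0.5
) -> np.ndarray:
    """Boolean acquisition-grid mask of voxels dominated by liver tissue."""
    maps = lowres_compartment_maps(spec, grid)
    return np.real(maps[LIVER]) > threshold


def body_support_mask(
    spec: PhantomSpec, grid: AcquisitionGrid, threshold: float = 0.25
) -> np.ndarray:
    """Boolean mask of voxels with appreciable tissue signal (any label)."""
    maps = lowres_compartment_maps(spec, grid)
    total = sum(np.real(m) for m in maps.values())
    return total > threshold


# ----------------------------------------------------------------------
# noise
# ----------------------------------------------------------------------

def add_complex_noise(
    data: SpatioSpectralData, level: NoiseLevel
) -> SpatioSpectralData:
    """Add i.i.d. complex white Gaussian noise of total SD ``alpha``.

    Each complex sample receives ``alpha/sqrt(2) * (g_re + i g_im)`` with
    ``g ~ N(0, 1)`` — independent across voxels, time points and coils, and
    deterministic given ``level.seed``. Under the unitary transforms the same
    alpha describes the noise in every domain.
    """
    if level.alpha == 0:
        return data.copy()
    rng = np.random.default_rng(level.seed)
    shape = data.values.shape
    noise = (level.alpha / np.sqrt(2.0)) * (
        rng.standard_normal(shape) + 1j * rng.standard_normal(shape)
    )
    return SpatioSpectralData(
        data.values + noise, data.grid, data.spatial_domain, data.temporal_domain
    )
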