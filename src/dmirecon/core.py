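"""Core containers for spatiotemporal MRSI data.

The package works with 3D phase-encoded CSI data: every spatial location
(image voxel or k-space point) carries a complete free-induction decay (FID).
Arrays are stored as complex ndarrays of shape ``(nx, ny, nz, n_time)`` with an
optional trailing coil axis, together with two domain flags that say whether
the spatial axes live in image or k-space and whether the last spectroscopic
axis is time (FID) or frequency (spectrum).

All Fourier transforms are unitary (``norm="ortho"``), so the l2 norm of the
data — and therefore the meaning of a noise standard deviation — is identical
in every domain.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np

SPATIAL_AXES = (0, 1, 2)


@dataclass(frozen=True)
class AcquisitionGrid:
    """Acquisition matrix and spectral axis of a 3D CSI experiment.

    Parameters
    ----------
    nx, ny, nz
        Phase-encoding matrix size (default 12 x 18 x 15).
    n_time
        Number of FID time points (default 1024).
    bandwidth_hz
        Spectral bandwidth in Hz; the dwell time is ``1 / bandwidth_hz``.
    carrier_ppm
        Chemical shift at the center of the spectral window. Water
        (4.7 ppm) is placed on-resonance by default.
    larmor_mhz
        Larmor frequency in MHz used for Hz <-> ppm conversion.
        Deuterium at 7 T resonates near 45.7 MHz.
    """

    nx: int = 12
    ny: int = 18
    nz: int = 15
    n_time: int = 1024
    bandwidth_hz: float = 5000.0
    carrier_ppm: float = 4.7
    larmor_mhz: float = 45.7

    def __post_init__(self) -> None:
        if self.n_time < 2:
            raise ValueError("n_time must be >= 2")
        if self.bandwidth_hz <= 0:
            raise ValueError("bandwidth_hz must be positive")
        if min(self.nx, self.ny, self.nz) < 1:
            raise ValueError("grid dimensions must be positive")

    @property
    def shape(self) -> tuple[int, int, int]:
        return (self.nx, self.ny, self.nz)

    @property
    def n_voxels(self) -> int:
        return self.nx * self.ny * self.nz

    @property
    def dwell_s(self) -> float:
        return 1.0 / self.bandwidth_hz

    def time_axis(self) -> np.ndarray:
        """FID sampling times in seconds, starting at t = 0."""
        return np.arange(self.n_time) * self.dwell_s

    def freq_axis_hz(self) -> np.ndarray:
        """Frequency axis (Hz offset from carrier) after the unitary FFT.

        Monotonically increasing, fftshift ordering applied.
        """
        return np.fft.fftshift(np.fft.fftfreq(self.n_time, d=self.dwell_s))

    def ppm_axis(self) -> np.ndarray:
        """Chemical-shift axis in ppm, monotonically increasing."""
        return self.carrier_ppm + self.freq_axis_hz() / self.larmor_mhz

    def ppm_to_hz(self, ppm: float | np.ndarray) -> np.ndarray:
        """Offset frequency in Hz of a resonance at chemical shift `ppm`."""
        return (np.asarray(ppm) - self.carrier_ppm) * self.larmor_mhz

    def hz_to_ppm(self, hz: float | np.ndarray) -> np.ndarray:
        return self.carrier_ppm + np.asarray(hz) / self.larmor_mhz

    def with_shape(self, shape: Sequence[int]) -> "AcquisitionGrid":
        nx, ny, nz = (int(s) for s in shape)
        return replace(self, nx=nx, ny=ny, nz=nz)


@dataclass
class SpatioSpectralData:
    """Complex spatiotemporal array with explicit domain bookkeeping.

    ``values`` has shape ``(nx, ny, nz, n_time)`` or
    ``(nx, ny, nz, n_time, n_coil)``. ``spatial_domain`` is ``"image"`` or
    ``"kspace"``; ``temporal_domain`` is ``"time"`` or ``"frequency"``.
    """

    values: np.ndarray
    grid: AcquisitionGrid
    spatial_domain: str = "image"
    temporal_domain: str = "time"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        if not np.iscomplexobj(self.values):
            self.values = self.values.astype(np.complex128)
        if self.values.ndim not in (4, 5):
            raise ValueError("values must be 4D (x,y,z,t) or 5D (x,y,z,t,coil)")
        if self.values.shape[:3] != self.grid.shape:
            raise ValueError(
                f"spatial shape {self.values.shape[:3]} does not match grid "
                f"{self.grid.shape}"
            )
        if self.values.shape[3] != self.grid.n_time:
            raise ValueError("temporal length does not match grid.n_time")
        if self.spatial_domain not in ("image", "kspace"):
            raise ValueError(f"bad spatial_domain {self.spatial_domain!r}")
        if self.temporal_domain not in ("time", "frequency"):
            raise ValueError(f"bad temporal_domain {self.temporal_domain!r}")

    @property
    def n_coil(self) -> int | None:
        return self.values.shape[4] if self.values.ndim == 5 else None

    def copy(self) -> "SpatioSpectralData":
        return SpatioSpectralData(
            self.values.copy(), self.grid, self.spatial_domain, self.temporal_domain
        )

    # -- domain flips -----------------------------------------------------

    def to_kspace(self) -> "SpatioSpectralData":
        if self.spatial_domain == "kspace":
            return self
        vals = spatial_fft(self.values)
        return SpatioSpectralData(vals, self.grid, "kspace", self.temporal_domain)

    def to_image(self) -> "SpatioSpectralData":
        if self.spatial_domain == "image":
            return self
        vals = spatial_ifft(self.values)
        return SpatioSpectralData(vals, self.grid, "image", self.temporal_domain)

    def to_frequency(self) -> "SpatioSpectralData":
        if self.temporal_domain == "frequency":
            return self
        vals = temporal_fft(self.values)
        return SpatioSpectralData(vals, self.grid, self.spatial_domain, "frequency")

    def to_time(self) -> "SpatioSpectralData":
        if self.temporal_domain == "time":
            return self
        vals = temporal_ifft(self.values)
        return SpatioSpectralData(vals, self.grid, self.spatial_domain, "time")


# -- unitary transforms ---------------------------------------------------

def spatial_fft(x: np.ndarray) -> np.ndarray:
    """Unitary centered 3D FFT over the first three axes (image -> k-space)."""
    return np.fft.fftshift(
        np.fft.fftn(np.fft.ifftshift(x, axes=SPATIAL_AXES), axes=SPATIAL_AXES,
                    norm="ortho"),
        axes=SPATIAL_AXES,
    )


def spatial_ifft(k: np.ndarray) -> np.ndarray:
    """Unitary centered 3D inverse FFT over the first three axes."""
    return np.fft.fftshift(
        np.fft.ifftn(np.fft.ifftshift(k, axes=SPATIAL_AXES), axes=SPATIAL_AXES,
                     norm="ortho"),
        axes=SPATIAL_AXES,
    )


def temporal_fft(x: np.ndarray, axis: int = 3) -> np.ndarray:
    """Unitary FFT time -> frequency, fftshifted so the axis is monotonic."""
    return np.fft.fftshift(np.fft.fft(x, axis=axis, norm="ortho"), axes=axis)


def temporal_ifft(s: np.ndarray, axis: int = 3) -> np.ndarray:
    return np.fft.ifft(np.fft.ifftshift(s, axes=axis), axis=axis, norm="ortho")


def center_slices(big: Sequence[int], small: Sequence[int]) -> tuple[slice, ...]:
    """Slices selecting the centered `small` block inside a `big` array.

    The center convention matches the fftshifted k-space origin at index
    ``n // 2``, so a centered crop always retains the DC sample.
    """
    out = []
    for b, s in zip(big, small):
        if s > b:
            raise ValueError(f"crop size {s} exceeds array size {b}")
        start = b // 2 - s // 2
        out.append(slice(start, start + s))
    return tuple(out)
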