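"""Quantification: spectral SNR, overall NRMSE, and bias maps."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .core import SpatioSpectralData


def compute_snr(
    spectra: SpatioSpectralData,
    noise_ppm_range: tuple[float, float] = (8.0, 12.0),
    water_ppm: float = 4.7,
    water_window_ppm: float = 0.0,
) -> np.ndarray:
    """Per-voxel water SNR of frequency-domain data.

    SNR = (water signal height of the real part) / (SD of the real part
    within the signal-free noise band). By default the signal
    height is read at the spectral bin of the known water resonance, which
    keeps the statistic unbiased by noise; with ``water_window_ppm > 0`` the
    maximum within that window is used instead (upward-biased at low SNR,
    but applicable when the resonance position is uncertain). Noise-free
    voxels (zero band SD) are reported as infinite.
    """
    if spectra.temporal_domain != "frequency":
        raise ValueError("compute_snr expects frequency-domain data")
    ppm = spectra.grid.ppm_axis()
    lo, hi = noise_ppm_range
    if lo >= hi:
        raise ValueError("empty noise band")
    if hi > ppm.max() + 1e-9 or lo < ppm.min() - 1e-9:
        raise ValueError("noise band extends outside the spectral window")
    band = (ppm >= lo) & (ppm <= hi)
    vals = spectra.values.real
    if water_window_ppm > 0:
        win = np.abs(ppm - water_ppm) <= water_window_ppm
        peak = vals[..., win].max(axis=-1)
    else:
        peak = vals[..., int(np.argmin(np.abs(ppm - water_ppm)))]
    sd = vals[..., band].std(axis=-1)
    with np.errstate(divide="ignore", invalid="ignore"):
        snr = peak / sd
    snr[sd == 0] = np.inf
    return snr


def compute_nrmse(theta_ref: np.ndarray, theta_hat: np.ndarray) -> float:
    """Overall normalized RMSE ``||theta - theta_hat||_2 / ||theta||_2``."""
    theta_ref = np.asarray(theta_ref, dtype=float)
    theta_hat = np.asarray(theta_hat, dtype=float)
    if theta_ref.shape != theta_hat.shape:
        raise ValueError("shape mismatch between reference and estimate")
    denom = np.linalg.norm(theta_ref)
    if denom == 0:
        raise ValueError("reference map is all-zero")
    return float(np.linalg.norm(theta_ref - theta_hat) / denom)


def compute_bias_maps(
    fitted: np.ndarray, truth: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Voxelwise mean and SD of (fit - truth) across repetitions.

    ``fitted`` stacks repetitions on the leading axis. The sign convention
    (fit minus truth) is fixed here; SD uses the n-1 normalization.
    """
    fitted = np.asarray(fitted, dtype=float)
    truth = np.asarray(truth, dtype=float)
    if fitted.ndim != truth.ndim + 1 or fitted.shape[1:] != truth.shape:
        raise ValueError("fitted stack shape must be (n_rep,) + truth.shape")
    if fitted.shape[0] < 2:
        raise ValueError("bias maps require at least 2 repetitions")
    diff = fitted - truth[None]
    return diff.mean(axis=0), diff.std(axis=0, ddof=1)


@dataclass
class MetricsReport:
    """Per-run quantification summary with provenance of the settings."""

    snr_mean: float | None = None
    nrmse: dict[str, float] = field(default_factory=dict)
    crlb_mean: dict[str, float] = field(default_factory=dict)
    config: dict = field(default_factory=dict)
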