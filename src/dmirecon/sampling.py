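"""Poisson-disk k-space undersampling with a fully sampled central core.

Undersampling is spatial only: each sampled phase-encode carries a complete
FID. The central D1 block (default 3 x 5 x 3) is always fully sampled — it is
the calibration region from which the temporal basis is later estimated. The
acceleration factor is R = (total k-space points) / (sampled points).

The sampling pattern outside D1 is a Poisson-disk (blue-noise) set generated
by dart throwing over a seeded random permutation of the grid, with the disk
radius tuned by bisection so that the point budget implied by the requested R
is met exactly by a maximal-radius configuration.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core import SpatioSpectralData, center_slices


@dataclass
class SamplingMask:
    """Boolean k-space mask with its D1 core and bookkeeping."""

    mask: np.ndarray
    d1_dims: tuple[int, int, int]
    target_R: float
    achieved_R: float
    seed: int
    radius: float = 0.0

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.mask.ndim != 3:
            raise ValueError("mask must be 3D")
        if not self.mask.any():
            raise ValueError("mask is empty")

    @property
    def n_sampled(self) -> int:
        return int(self.mask.sum())

    def d1_slices(self) -> tuple[slice, ...]:
        return center_slices(self.mask.shape, self.d1_dims)

    def d1_fully_sampled(self) -> bool:
        return bool(self.mask[self.d1_slices()].all())


def _dart_throw(
    order: np.ndarray,
    coords: np.ndarray,
    radius: float,
    n_extra: int,
) -> np.ndarray | None:
    """Greedy Poisson-disk selection of ``n_extra`` points from `coords`.

    Visits candidates in the given order, accepting a point if it is at least
    ``radius`` (Euclidean, index units) from every previously accepted point.
    Returns indices into `coords`, or None if the budget cannot be met.
    """
    accepted: list[int] = []
    pts = np.empty((n_extra, 3))
    r2 = radius * radius
    for idx in order:
        c = coords[idx]
        if accepted:
            d2 = np.sum((pts[: len(accepted)] - c) ** 2, axis=1)
            if d2.min() < r2:
                continue
        pts[len(accepted)] = c
        accepted.append(int(idx))
        if len(accepted) == n_extra:
            return np.asarray(accepted)
    return None


def generate_poisson_disk_mask(
    grid_dims: tuple[int, int, int],
    target_R: float,
    d1_dims: tuple[int, int, int] = (3, 5, 3),
    seed: int = 0,
    r_tolerance: float = 1e-3,
) -> SamplingMask:
    """Generate a Poisson-disk undersampling mask at acceleration ``target_R``.

    The D1 core is always sampled. The disk radius is maximized by bisection
    subject to the point budget ``round(total / target_R)`` being reachable,
    so achieved_R matches target_R to within rounding (well inside 2%).
    """
    if target_R < 1:
        raise ValueError("target_R must be >= 1")
    if any(d > g for d, g in zip(d1_dims, grid_dims)):
        raise ValueError("d1_dims must fit inside grid_dims")
    total = int(np.prod(grid_dims))
    n_target = int(round(total / target_R))

    d1 = np.zeros(grid_dims, dtype=bool)
    d1[center_slices(grid_dims, d1_dims)] = True
    n_d1 = int(d1.sum())
    if n_target < n_d1:
        min_R = total / n_d1
        raise ValueError(
            f"target_R={target_R} leaves a budget of {n_target} points, fewer "
            f"than the {n_d1}-point D1 core; minimum feasible R is {min_R:.3f}"
        )

    if n_target >= total:
        return SamplingMask(
            np.ones(grid_dims, dtype=bool), tuple(d1_dims), target_R, 1.0, seed
        )

    coords = np.argwhere(~d1).astype(np.float64)
    n_extra = n_target - n_d1
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(coords))

    mask = np.zeros(grid_dims, dtype=bool)
    mask[d1] = True
    if n_extra == 0:
        achieved = total / n_d1
        return SamplingMask(mask, tuple(d1_dims), target_R, achieved, seed)

    # bisection for the largest feasible disk radius
    lo, hi = 0.0, float(np.linalg.norm(grid_dims))
    best = _dart_throw(order, coords, lo, n_extra)
    if best is None:  # cannot happen: radius 0 accepts everything
        raise RuntimeError("dart throwing failed at radius 0")
    best_r = 0.0
    while hi - lo > r_tolerance:
        mid = 0.5 * (lo + hi)
        sel = _dart_throw(order, coords, mid, n_extra)
        if sel is not None:
            lo, best, best_r = mid, sel, mid
        else:
            hi = mid

    chosen = coords[best].astype(int)
    mask[chosen[:, 0], chosen[:, 1], chosen[:, 2]] = True
    achieved = total / int(mask.sum())
    return SamplingMask(mask, tuple(d1_dims), target_R, achieved, seed, best_r)


def apply_sampling(
    kdata: SpatioSpectralData, mask: SamplingMask
) -> SpatioSpectralData:
    """Apply the sampling operator: zero every unsampled k-space location.

    Sampled entries are returned bit-identical; the operation is idempotent
    and, followed by this same zero-filling, an orthogonal projection.
    """
    if kdata.spatial_domain != "kspace":
        raise ValueError("apply_sampling expects k-space data")
    if mask.mask.shape != kdata.values.shape[:3]:
        raise ValueError(
            f"mask shape {mask.mask.shape} does not match data "
            f"{kdata.values.shape[:3]}"
        )
    m = mask.mask
    extra = (1,) * (kdata.values.ndim - 3)
    out = kdata.values * m.reshape(m.shape + extra)
    return SpatioSpectralData(
        out, kdata.grid, "kspace", kdata.temporal_domain
    )
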