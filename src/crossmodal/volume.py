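"""Volumetric containers and low-level image operations.

Provides the :class:`VolumeMap` / :class:`DynamicSeries` data structures and
the stateless operations used throughout the pipeline: temporal integration
into sum images, whole-brain mean normalization, voxelwise group medians,
mask-renormalized Gaussian smoothing, and empirical FWHM selection.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np
from scipy.ndimage import gaussian_filter

__all__ = [
    "FWHM_PER_SIGMA",
    "fwhm_to_sigma_vox",
    "VolumeMap",
    "DynamicSeries",
    "IntegrationWindow",
    "UptakeNotDetectedError",
    "detect_uptake_start",
    "sum_image",
    "normalize_global_mean",
    "group_median",
    "gaussian_smooth",
    "optimize_fwhm",
]

#: Ratio between the full width at half maximum of a Gaussian and its
#: standard deviation: FWHM = 2 * sqrt(2 ln 2) * sigma.
FWHM_PER_SIGMA = 2.0 * np.sqrt(2.0 * np.log(2.0))


def fwhm_to_sigma_vox(fwhm_mm: float, voxel_size_mm: float) -> float:
    """Convert a kernel FWHM in mm to a standard deviation in voxel units."""
    return fwhm_mm / FWHM_PER_SIGMA / voxel_size_mm


class UptakeNotDetectedError(ValueError):
    """Raised when a dynamic series shows no detectable signal increase."""


@dataclass
class VolumeMap:
    """One 3D scalar field on a fixed grid.

    Parameters
    ----------
    values : ndarray, shape (nx, ny, nz)
        Voxel intensities (arbitrary units).
    voxel_size_mm : float
        Isotropic voxel edge length in millimetres.
    """

    values: np.ndarray
    voxel_size_mm: float

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 3:
            raise ValueError(f"VolumeMap values must be 3D, got ndim={self.values.ndim}")
        if not self.voxel_size_mm > 0:
            raise ValueError("voxel_size_mm must be positive")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.values.shape  # type: ignore[return-value]

    def with_values(self, values: np.ndarray) -> "VolumeMap":
        """Return a new map on the same grid with replaced values."""
        return VolumeMap(values, self.voxel_size_mm)

    def mean_in(self, mask: np.ndarray) -> float:
        return float(self.values[mask].mean())


@dataclass
class DynamicSeries:
    """Ordered dynamic frames with acquisition times.

    Parameters
    ----------
    data : ndarray, shape (nx, ny, nz, n_frames)
    frame_times_s : ndarray, shape (n_frames,)
        Strictly increasing, nonnegative frame onset times in seconds.
    voxel_size_mm : float
    """

    data: np.ndarray
    frame_times_s: np.ndarray
    voxel_size_mm: float

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        self.frame_times_s = np.asarray(self.frame_times_s, dtype=float)
        if self.data.ndim != 4:
            raise ValueError("DynamicSeries data must be 4D (x, y, z, t)")
        if self.frame_times_s.ndim != 1 or self.frame_times_s.size != self.data.shape[3]:
            raise ValueError("frame_times_s must match the number of frames")
        if self.n_frames < 1:
            raise ValueError("series needs at least one frame")
        if np.any(self.frame_times_s < 0):
            raise ValueError("frame times must be nonnegative")
        if self.n_frames > 1 and np.any(np.diff(self.frame_times_s) <= 0):
            raise ValueError("frame times must be strictly increasing")
        if not self.voxel_size_mm > 0:
            raise ValueError("voxel_size_mm must be positive")

    @property
    def n_frames(self) -> int:
        return self.data.shape[3]

    def frame(self, i: int) -> VolumeMap:
        return VolumeMap(self.data[..., i], self.voxel_size_mm)


@dataclass(frozen=True)
class IntegrationWindow:
    """Temporal window selecting dynamic frames for a sum image.

    ``all_frames`` sums every frame; ``fixed_window`` sums frames with
    onset in the half-open interval ``[start_s, start_s + duration_s)``;
    ``last_minutes`` sums frames in the final ``tail_min`` minutes of the
    series (inclusive of the boundary).
    """

    mode: Literal["all_frames", "fixed_window", "last_minutes"]
    start_s: float = 0.0
    duration_s: float = 0.0
    tail_min: float = 0.0

    @classmethod
    def all_frames(cls) -> "IntegrationWindow":
        return cls(mode="all_frames")

    @classmethod
    def fixed(cls, start_s: float, duration_s: float) -> "IntegrationWindow":
        if duration_s <= 0:
            raise ValueError("duration_s must be positive")
        return cls(mode="fixed_window", start_s=start_s, duration_s=duration_s)

    @classmethod
    def last_minutes(cls, tail_min: float) -> "IntegrationWindow":
        if tail_min <= 0:
            raise ValueError("tail_min must be positive")
        return cls(mode="last_minutes", tail_min=tail_min)

    def select(self, frame_times_s: np.ndarray) -> np.ndarray:
        """Boolean selector over frames for this window."""
        t = np.asarray(frame_times_s, dtype=float)
        if self.mode == "all_frames":
            return np.ones(t.size, dtype=bool)
        if self.mode == "fixed_window":
            return (t >= self.start_s) & (t < self.start_s + self.duration_s)
        if self.mode == "last_minutes":
            return t >= t[-1] - self.tail_min * 60.0
        raise ValueError(f"unknown window mode {self.mode!r}")


# Fraction of the dynamic range the whole-brain mean must rise above the
# first frame before a frame counts as uptake.
UPTAKE_THRESHOLD_FRAC = 0.05


def detect_uptake_start(series: DynamicSeries, mask: np.ndarray) -> float:
    """Time of the first frame whose whole-brain mean shows an increase.

    The threshold is the first frame's within-mask mean plus 5% of the
    dynamic range of the frame-mean curve; the first frame strictly above
    it defines the uptake start.

    Raises
    ------
    UptakeNotDetectedError
        If the series is flat or never exceeds the threshold.
    """
    if series.n_frames < 3:
        raise ValueError("need at least 3 frames to detect uptake")
    mask = np.asarray(mask, dtype=bool)
    means = series.data[mask].mean(axis=0)
    dyn_range = float(means.max() - means.min())
    if dyn_range <= 0:
        raise UptakeNotDetectedError("frame-mean curve is constant; no uptake")
    threshold = means[0] + UPTAKE_THRESHOLD_FRAC * dyn_range
    above = np.nonzero(means > threshold)[0]
    if above.size == 0:
        raise UptakeNotDetectedError("no frame mean exceeds the uptake threshold")
    return float(series.frame_times_s[above[0]])


def sum_image(series: DynamicSeries, window: IntegrationWindow) -> VolumeMap:
    """Voxelwise sum of the frames selected by ``window``."""
    sel = window.select(series.frame_times_s)
    if not sel.any():
        raise ValueError("integration window selects no frames")
    return VolumeMap(series.data[..., sel].sum(axis=3), series.voxel_size_mm)


def normalize_global_mean(vmap: VolumeMap, mask: np.ndarray) -> VolumeMap:
    """Scale so the within-mask mean is 1; voxels outside the mask become 0."""
    mask = np.asarray(mask, dtype=bool)
    mean = float(vmap.values[mask].mean())
    if not mean > 0:
        raise ValueError(f"within-mask mean must be positive, got {mean}")
    out = np.zeros_like(vmap.values)
    out[mask] = vmap.values[mask] / mean
    return vmap.with_values(out)


def group_median(maps: Sequence[VolumeMap]) -> VolumeMap:
    """Voxelwise median across maps; even counts average the central pair."""
    if len(maps) < 1:
        raise ValueError("need at least one map")
    first = maps[0]
    for m in maps[1:]:
        if m.shape != first.shape or m.voxel_size_mm != first.voxel_size_mm:
            raise ValueError("all maps must share the same grid")
    stack = np.stack([m.values for m in maps], axis=0)
    return first.with_values(np.median(stack, axis=0))


def gaussian_smooth(vmap: VolumeMap, fwhm_mm: float, mask: np.ndarray) -> VolumeMap:
    """Mask-renormalized Gaussian smoothing.

    Computes ``smooth(map * mask) / smooth(mask)`` within the mask, which
    prevents edge attenuation from zero padding and preserves constants
    exactly. ``fwhm_mm == 0`` is the identity.
    """
    if fwhm_mm < 0:
        raise ValueError("fwhm_mm must be nonnegative")
    if fwhm_mm == 0:
        return vmap.with_values(vmap.values.copy())
    mask = np.asarray(mask, dtype=bool)
    sigma = fwhm_to_sigma_vox(fwhm_mm, vmap.voxel_size_mm)
    num = gaussian_filter(vmap.values * mask, sigma, mode="constant", cval=0.0)
    den = gaussian_filter(mask.astype(float), sigma, mode="constant", cval=0.0)
    out = np.zeros_like(vmap.values)
    out[mask] = num[mask] / den[mask]
    return vmap.with_values(out)


def optimize_fwhm(
    maps_a: Sequence[VolumeMap],
    maps_b: Sequence[VolumeMap],
    mask: np.ndarray,
    fwhm_grid: Sequence[float],
) -> float:
    """Grid value maximizing mean voxelwise Spearman rho after smoothing B.

    Every map in ``maps_b`` is smoothed at each candidate FWHM and rank
    correlated with its paired map in ``maps_a``; the candidate with the
    highest mean correlation wins, ties going to the smaller FWHM.
    """
    from .stats import spearman_rho

    if len(maps_a) == 0 or len(maps_a) != len(maps_b):
        raise ValueError("maps_a and maps_b must be nonempty and paired")
    grid = sorted(float(f) for f in fwhm_grid)
    if not grid:
        raise ValueError("fwhm_grid must be nonempty")
    mask = np.asarray(mask, dtype=bool)
    best_fwhm, best_score = grid[0], -np.inf
    for fwhm in grid:
        rhos = [
            spearman_rho(a.values[mask], gaussian_smooth(b, fwhm, mask).values[mask])
            for a, b in zip(maps_a, maps_b)
        ]
        score = float(np.mean(rhos))
        if score > best_score:
            best_fwhm, best_score = fwhm, score
    return best_fwhm
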