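"""Synthetic multi-subject paired volumetric datasets with known structure.

Two imaging "modalities" are simulated on a shared coarse grid: a
three-channel dynamic block (pyruvate / lactate / bicarbonate analogs) and
a four-channel block (cmrglc / cbf / cmro2 / cbv analogs). Both are linear
mixtures of a small set of spatially autocorrelated latent fields through
known mixing matrices, so downstream correlation and PLS stages can be
checked against planted ground truth. A dedicated vascular latent loads
the pyruvate-like and cbv-like channels, mirroring the dominance of
vascular signal in both.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import gaussian_filter

from .parcellation import Parcellation
from .stats import random_rotation
from .volume import DynamicSeries, VolumeMap, fwhm_to_sigma_vox

__all__ = [
    "LatentFieldSpec",
    "MixingSpec",
    "DynamicSpec",
    "ellipsoid_mask",
    "ellipsoid_radius",
    "generate_latent_fields",
    "generate_subject_dataset",
    "generate_spherical_parcellation",
    "default_mixing_spec",
]

HP_CHANNELS = ("pyruvate", "lactate", "bicarbonate")
PET_CHANNELS = ("cmrglc", "cbf", "cmro2", "cbv")

#: Fraction of grid voxels covered by the ellipsoidal brain mask.
MASK_VOLUME_FRAC = 0.40
#: Outer radial band of the mask treated as the cortical shell.
SHELL_FRAC = 0.30


@dataclass(frozen=True)
class LatentFieldSpec:
    """Geometry and autocorrelation of the latent spatial fields."""

    grid_shape: tuple[int, int, int] = (32, 32, 32)
    voxel_size_mm: float = 6.0
    n_latents: int = 3
    smooth_fwhm_mm: float = 24.0
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.grid_shape) != 3 or any(int(d) < 8 for d in self.grid_shape):
            raise ValueError("grid_shape must be a triple with every dim >= 8")
        if not self.voxel_size_mm > 0:
            raise ValueError("voxel_size_mm must be positive")
        if not 2 <= self.n_latents <= 10:
            raise ValueError("n_latents must be in [2, 10]")
        if self.smooth_fwhm_mm < 0:
            raise ValueError("smooth_fwhm_mm must be nonnegative")


@dataclass(frozen=True)
class MixingSpec:
    """Channel mixing of latent fields plus subject-level noise."""

    hp_channels: tuple[str, ...] = HP_CHANNELS
    pet_channels: tuple[str, ...] = PET_CHANNELS
    mixing_hp: np.ndarray = field(default=None)  # (n_hp, n_latents)
    mixing_pet: np.ndarray = field(default=None)  # (n_pet, n_latents)
    vascular_latent_index: int = 1
    subject_noise_sd: float = 0.1
    voxel_noise_sd: float = 0.02
    n_subjects: int = 35

    def __post_init__(self) -> None:
        object.__setattr__(self, "mixing_hp", np.asarray(self.mixing_hp, dtype=float))
        object.__setattr__(self, "mixing_pet", np.asarray(self.mixing_pet, dtype=float))
        if self.mixing_hp.ndim != 2 or self.mixing_hp.shape[0] != len(self.hp_channels):
            raise ValueError("mixing_hp must be (n_hp_channels, n_latents)")
        if self.mixing_pet.ndim != 2 or self.mixing_pet.shape[0] != len(self.pet_channels):
            raise ValueError("mixing_pet must be (n_pet_channels, n_latents)")
        if self.mixing_hp.shape[1] != self.mixing_pet.shape[1]:
            raise ValueError("mixing matrices must agree on latent count")
        if not (np.isfinite(self.mixing_hp).all() and np.isfinite(self.mixing_pet).all()):
            raise ValueError("mixing matrices must be finite")
        if not 0 <= self.vascular_latent_index < self.mixing_hp.shape[1]:
            raise ValueError("vascular_latent_index out of range")
        if self.subject_noise_sd < 0 or self.voxel_noise_sd < 0:
            raise ValueError("noise SDs must be nonnegative")
        if self.n_subjects < 3:
            raise ValueError("n_subjects must be at least 3")

    @property
    def n_latents(self) -> int:
        return int(self.mixing_hp.shape[1])


def default_mixing_spec(
    n_subjects: int = 35,
    subject_noise_sd: float = 0.1,
    voxel_noise_sd: float = 0.02,
) -> MixingSpec:
    """Three-latent mixing: shared metabolic, vascular, and nuisance.

    Latent 0 (metabolic) loads lactate/bicarbonate and cmrglc/cbf/cmro2;
    latent 1 (vascular) loads pyruvate and cbv; latent 2 is weak nuisance.
    """
    mixing_hp = np.array(
        [
            [0.20, 1.00, 0.10],  # pyruvate: vascular-dominated
            [1.00, 0.30, 0.10],  # lactate
            [0.90, 0.25, 0.10],  # bicarbonate
        ]
    )
    mixing_pet = np.array(
        [
            [1.00, 0.10, 0.10],  # cmrglc
            [0.95, 0.20, 0.10],  # cbf
            [0.90, 0.15, 0.10],  # cmro2
            [0.15, 1.00, 0.10],  # cbv: vascular-dominated
        ]
    )
    return MixingSpec(
        mixing_hp=mixing_hp,
        mixing_pet=mixing_pet,
        vascular_latent_index=1,
        subject_noise_sd=subject_noise_sd,
        voxel_noise_sd=voxel_noise_sd,
        n_subjects=n_subjects,
    )


@dataclass(frozen=True)
class DynamicSpec:
    """Frame timing and per-channel time-course weights."""

    n_frames: int = 12
    frame_interval_s: float = 5.0
    timecourses: dict | None = None  # channel -> weight vector summing to 1

    def __post_init__(self) -> None:
        if self.n_frames < 3:
            raise ValueError("n_frames must be at least 3")
        if not self.frame_interval_s > 0:
            raise ValueError("frame_interval_s must be positive")
        if self.timecourses is not None:
            for ch, w in self.timecourses.items():
                w = np.asarray(w, dtype=float)
                if w.shape != (self.n_frames,):
                    raise ValueError(f"timecourse for {ch!r} must have n_frames entries")
                if np.any(w < 0):
                    raise ValueError(f"timecourse for {ch!r} must be nonnegative")
                if abs(w.sum() - 1.0) > 1e-8:
                    raise ValueError(f"timecourse for {ch!r} must sum to 1")

    @property
    def frame_times_s(self) -> np.ndarray:
        return np.arange(self.n_frames) * self.frame_interval_s

    def weights_for(self, channel: str) -> np.ndarray:
        if self.timecourses is not None and channel in self.timecourses:
            return np.asarray(self.timecourses[channel], dtype=float)
        # default gamma-like uptake bump
        t = self.frame_times_s + self.frame_interval_s
        w = t**2 * np.exp(-t / (3.0 * self.frame_interval_s))
        return w / w.sum()


def _ellipsoid_scale() -> float:
    # semi-axis fraction giving an ellipsoid of MASK_VOLUME_FRAC grid volume
    return float((MASK_VOLUME_FRAC / (np.pi / 6.0)) ** (1.0 / 3.0))


def ellipsoid_radius(grid_shape: tuple[int, int, int]) -> np.ndarray:
    """Normalized ellipsoidal radius; the brain mask is ``radius <= 1``."""
    f = _ellipsoid_scale()
    axes = [
        (np.arange(n) - (n - 1) / 2.0) / (f * n / 2.0) for n in grid_shape
    ]
    gx, gy, gz = np.meshgrid(*axes, indexing="ij")
    return np.sqrt(gx**2 + gy**2 + gz**2)


def ellipsoid_mask(grid_shape: tuple[int, int, int]) -> np.ndarray:
    """Centered ellipsoidal brain mask covering ~40% of the grid."""
    return ellipsoid_radius(grid_shape) <= 1.0


def generate_latent_fields(spec: LatentFieldSpec) -> list[VolumeMap]:
    """Spatially autocorrelated latent fields, z-scored within the mask.

    Each field starts as white Gaussian noise, is smoothed to the spec's
    FWHM, z-scored over the ellipsoidal brain mask, and zeroed outside it.
    Fully deterministic given the spec's seed.
    """
    rng = np.random.default_rng(spec.seed)
    mask = ellipsoid_mask(spec.grid_shape)
    sigma = fwhm_to_sigma_vox(spec.smooth_fwhm_mm, spec.voxel_size_mm)
    fields = []
    for _ in range(spec.n_latents):
        f = rng.standard_normal(spec.grid_shape)
        if sigma > 0:
            f = gaussian_filter(f, sigma, mode="constant", cval=0.0)
        inside = f[mask]
        f = (f - inside.mean()) / inside.std()
        f[~mask] = 0.0
        fields.append(VolumeMap(f, spec.voxel_size_mm))
    return fields


def _nonneg_shift(values: np.ndarray, mask: np.ndarray) -> np.ndarray:
    """Shift so the within-mask minimum is 0.1x the within-mask range."""
    inside = values[mask]
    lo, hi = float(inside.min()), float(inside.max())
    return values - lo + 0.1 * (hi - lo)


def generate_subject_dataset(
    latents: list[VolumeMap],
    mixing: MixingSpec,
    dyn: DynamicSpec,
    subject_seed: int,
    mask: np.ndarray | None = None,
) -> dict[str, DynamicSeries]:
    """One subject's dynamic series for every HP and PET channel.

    Each channel's static map is a nonnegativity-shifted linear mix of the
    latent fields, scaled by a subject-specific lognormal gain and
    perturbed by voxel noise; frames are the static map times the
    channel's time-course weights, so the frame sum is proportional to the
    static map.
    """
    if len(latents) != mixing.n_latents:
        raise ValueError(
            f"mixing expects {mixing.n_latents} latents, got {len(latents)}"
        )
    grid_shape = latents[0].shape
    voxel = latents[0].voxel_size_mm
    if mask is None:
        mask = ellipsoid_mask(grid_shape)
    mask = np.asarray(mask, dtype=bool)
    latent_stack = np.stack([lt.values for lt in latents], axis=-1)  # (...,L)
    rng = np.random.default_rng(subject_seed)
    times = dyn.frame_times_s

    out: dict[str, DynamicSeries] = {}
    for channels, matrix in (
        (mixing.hp_channels, mixing.mixing_hp),
        (mixing.pet_channels, mixing.mixing_pet),
    ):
        for row, channel in enumerate(channels):
            static = latent_stack @ matrix[row]
            static = _nonneg_shift(static, mask)
            gain = rng.lognormal(mean=0.0, sigma=mixing.subject_noise_sd)
            static = static * gain
            if mixing.voxel_noise_sd > 0:
                scale = float(static[mask].std())
                static = static + rng.normal(
                    0.0, mixing.voxel_noise_sd * scale, size=grid_shape
                )
            static = np.clip(static, 0.0, None)
            static[~mask] = 0.0
            weights = dyn.weights_for(channel)
            frames = static[..., None] * weights
            out[channel] = DynamicSeries(frames, times, voxel)
    return out


def _fibonacci_sphere(n: int) -> np.ndarray:
    """Fibonacci lattice: ``n`` near-uniform points on the unit sphere."""
    i = np.arange(n)
    z = 1.0 - 2.0 * (i + 0.5) / n
    theta = np.pi * (1.0 + np.sqrt(5.0)) * i
    r = np.sqrt(1.0 - z**2)
    pts = np.column_stack([r * np.cos(theta), r * np.sin(theta), z])
    return pts / np.linalg.norm(pts, axis=1, keepdims=True)


def generate_spherical_parcellation(
    grid_shape: tuple[int, int, int],
    mask: np.ndarray,
    n_parcels: int = 200,
    seed: int = 0,
) -> Parcellation:
    """Partition the cortical-shell voxels by nearest spherical centroid.

    Centroids come from a Fibonacci lattice on the unit sphere, randomly
    rotated by the seed. Shell voxels (the outer radial band of the mask)
    are projected radially onto the sphere and labeled by the centroid with
    maximal dot product; empty parcels are repaired by stealing their
    closest shell voxel from a multi-voxel parcel.
    """
    mask = np.asarray(mask, dtype=bool)
    radius = ellipsoid_radius(grid_shape)
    shell = mask & (radius > 1.0 - SHELL_FRAC)
    n_shell = int(shell.sum())
    if n_shell == 0:
        raise ValueError("mask has no shell voxels")
    if n_parcels > n_shell:
        raise ValueError(f"n_parcels={n_parcels} exceeds {n_shell} shell voxels")
    if n_parcels < 1:
        raise ValueError("n_parcels must be positive")

    rotation = random_rotation(np.random.default_rng(seed))
    centroids = _fibonacci_sphere(n_parcels) @ rotation.T

    # radial projection of shell voxels onto the unit sphere
    f = _ellipsoid_scale()
    coords = np.argwhere(shell).astype(float)
    for axis, n in enumerate(grid_shape):
        coords[:, axis] = (coords[:, axis] - (n - 1) / 2.0) / (f * n / 2.0)
    directions = coords / np.linalg.norm(coords, axis=1, keepdims=True)

    dots = directions @ centroids.T  # (n_shell, n_parcels)
    assign = np.argmax(dots, axis=1)

    # ensure every parcel is nonempty
    counts = np.bincount(assign, minlength=n_parcels)
    while np.any(counts == 0):
        empty = int(np.nonzero(counts == 0)[0][0])
        donors = counts[assign] >= 2
        if not donors.any():
            raise ValueError("cannot repair empty parcels")
        candidates = np.nonzero(donors)[0]
        steal = candidates[np.argmax(dots[candidates, empty])]
        counts[assign[steal]] -= 1
        assign[steal] = empty
        counts[empty] += 1

    labels = np.zeros(grid_shape, dtype=np.int32)
    labels[shell] = assign + 1
    return Parcellation(
        labels=labels,
        parcel_ids=np.arange(1, n_parcels + 1),
        centroids=centroids,
    )
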