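"""Rank correlation, spin-permutation inference, and FDR control.

Voxelwise correlations between brain maps are reported descriptively; all
inference happens at the parcel level, where the permutation null is built
by randomly rotating parcel values on a spherical representation of the
parcel centroids. This preserves the spatial autocorrelation of the data,
which a naive permutation would destroy.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.stats import rankdata

from .parcellation import Parcellation

__all__ = [
    "CorrelationResult",
    "SpinNull",
    "spearman_rho",
    "random_rotation",
    "random_rotations",
    "spin_permute",
    "spin_permutation_indices",
    "spin_test",
    "fdr_bh",
]


@dataclass
class CorrelationResult:
    """One map-pair comparison: descriptive voxel rho plus parcel inference."""

    pair: tuple[str, str]
    rho_voxel: float
    rho_parcel: float
    p_spin: float
    q_flag: bool


@dataclass
class SpinNull:
    """Null distribution from spherical rotations of parcel data."""

    n_perm: int
    seed: int
    null_rhos: np.ndarray
    rotations: np.ndarray | None = None


def spearman_rho(x: np.ndarray, y: np.ndarray) -> float:
    """Spearman rank-order correlation with average ranks for ties.

    Parameters
    ----------
    x, y : array_like, shape (n,)
        Paired observations, ``n >= 3``, all finite.

    Returns
    -------
    float
        Pearson correlation of the average ranks of ``x`` and ``y``.

    Raises
    ------
    ValueError
        On length mismatch, fewer than 3 observations, non-finite values,
        or zero-variance input.
    """
    x = np.asarray(x, dtype=float).ravel()
    y = np.asarray(y, dtype=float).ravel()
    if x.size != y.size:
        raise ValueError("x and y must have equal length")
    if x.size < 3:
        raise ValueError("need at least 3 observations")
    if not (np.isfinite(x).all() and np.isfinite(y).all()):
        raise ValueError("inputs must be finite")
    rx = rankdata(x)
    ry = rankdata(y)
    rx = rx - rx.mean()
    ry = ry - ry.mean()
    denom = np.sqrt((rx @ rx) * (ry @ ry))
    if denom == 0:
        raise ValueError("zero-variance input")
    return float((rx @ ry) / denom)


def random_rotations(n: int, rng: np.random.Generator) -> np.ndarray:
    """Draw ``n`` rotations uniform under Haar measure on SO(3).

    Uses QR orthonormalization of Gaussian matrices with the sign of the
    R diagonal absorbed (Mezzadri's correction), then flips the first
    column of any reflection so every determinant is +1.
    """
    gauss = rng.standard_normal((n, 3, 3))
    q, r = np.linalg.qr(gauss)
    diag_sign = np.sign(np.diagonal(r, axis1=1, axis2=2))
    diag_sign[diag_sign == 0] = 1.0
    q = q * diag_sign[:, None, :]
    det = np.linalg.det(q)
    q[det < 0, :, 0] *= -1.0
    return q


def random_rotation(rng: np.random.Generator | int | None = None) -> np.ndarray:
    """Single Haar-uniform 3x3 rotation matrix (determinant +1)."""
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    return random_rotations(1, rng)[0]


def spin_permute(values: np.ndarray, parc: Parcellation, rotation: np.ndarray) -> np.ndarray:
    """Reassign parcel values under one spherical rotation.

    Each parcel receives the value of the parcel whose centroid is nearest
    (maximum dot product) to its own rotated centroid. The output is a
    surjection of the input values: duplicates and drops are allowed when
    the rotated geometry maps several parcels onto one.
    """
    values = np.asarray(values, dtype=float)
    if values.size != parc.n_parcels:
        raise ValueError("values must have one entry per parcel")
    rotated = parc.centroids @ np.asarray(rotation, dtype=float).T
    idx = np.argmax(rotated @ parc.centroids.T, axis=1)
    return values[idx]


def spin_permutation_indices(
    parc: Parcellation,
    n_perm: int,
    seed: int,
    chunk: int = 128,
) -> tuple[np.ndarray, np.ndarray]:
    """Precompute nearest-centroid reassignments for ``n_perm`` rotations.

    Returns
    -------
    idx : ndarray, shape (n_perm, n_parcels)
        ``idx[k, i]`` is the source parcel whose value parcel ``i``
        receives under rotation ``k``.
    rotations : ndarray, shape (n_perm, 3, 3)
    """
    if n_perm < 1:
        raise ValueError("n_perm must be positive")
    rng = np.random.default_rng(seed)
    rotations = random_rotations(n_perm, rng)
    cent = parc.centroids
    idx = np.empty((n_perm, parc.n_parcels), dtype=np.intp)
    for lo in range(0, n_perm, chunk):
        hi = min(lo + chunk, n_perm)
        rotated = np.einsum("kab,nb->kna", rotations[lo:hi], cent)
        idx[lo:hi] = np.argmax(rotated @ cent.T, axis=2)
    return idx, rotations


def spin_test(
    x: np.ndarray,
    y: np.ndarray,
    parc: Parcellation | None = None,
    n_perm: int = 10_000,
    seed: int = 0,
    perm_idx: np.ndarray | None = None,
    keep_rotations: bool = False,
) -> tuple[float, float, SpinNull]:
    """Spin-permutation test of the Spearman correlation of parcel vectors.

    The observed statistic is ``spearman_rho(x, y)``. Each null draw
    rotates ``x`` on the sphere (nearest-centroid reassignment) and
    re-correlates it with the unrotated ``y``. The two-sided p-value uses
    the add-one correction ``(1 + #{|null| >= |obs|}) / (n_perm + 1)`` and
    therefore never falls below ``1 / (n_perm + 1)``.

    ``perm_idx`` (from :func:`spin_permutation_indices`) can be passed to
    reuse one set of rotations across many map pairs on the same
    parcellation.
    """
    x = np.asarray(x, dtype=float).ravel()
    y = np.asarray(y, dtype=float).ravel()
    rho_obs = spearman_rho(x, y)
    rotations = None
    if perm_idx is None:
        if parc is None:
            raise ValueError("either parc or perm_idx is required")
        perm_idx, rotations = spin_permutation_indices(parc, n_perm, seed)
        if not keep_rotations:
            rotations = None
    else:
        n_perm = perm_idx.shape[0]
    if n_perm < 100:
        raise ValueError("n_perm must be at least 100")

    x_perm_ranks = rankdata(x[perm_idx], axis=1)
    y_ranks = rankdata(y)
    xc = x_perm_ranks - x_perm_ranks.mean(axis=1, keepdims=True)
    yc = y_ranks - y_ranks.mean()
    denom = np.sqrt((xc * xc).sum(axis=1) * (yc @ yc))
    null = np.zeros(n_perm)
    ok = denom > 0  # degenerate rotated vectors contribute rho = 0
    null[ok] = (xc @ yc)[ok] / denom[ok]
    p = float((1 + np.count_nonzero(np.abs(null) >= np.abs(rho_obs))) / (n_perm + 1))
    return rho_obs, p, SpinNull(n_perm=n_perm, seed=seed, null_rhos=null, rotations=rotations)


def fdr_bh(pvals: np.ndarray, alpha: float = 0.05) -> np.ndarray:
    """Benjamini-Hochberg step-up procedure.

    Parameters
    ----------
    pvals : array_like, values in (0, 1]
    alpha : float in (0, 1)

    Returns
    -------
    ndarray of bool
        True where the hypothesis is rejected at FDR level ``alpha``.
    """
    p = np.asarray(pvals, dtype=float).ravel()
    if p.size == 0:
        return np.zeros(0, dtype=bool)
    if np.any(~np.isfinite(p)) or np.any(p <= 0) or np.any(p > 1):
        raise ValueError("p-values must lie in (0, 1]")
    if not 0 < alpha < 1:
        raise ValueError("alpha must lie in (0, 1)")
    m = p.size
    order = np.argsort(p, kind="stable")
    thresholds = alpha * np.arange(1, m + 1) / m
    passed = p[order] <= thresholds
    reject = np.zeros(m, dtype=bool)
    if passed.any():
        k = int(np.nonzero(passed)[0].max())
        reject[order[: k + 1]] = True
    return reject
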