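"""Integer-labeled parcellations with spherical centroid geometry."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .volume import VolumeMap

__all__ = ["Parcellation", "parcel_medians", "relabel_contiguous"]

_CENTROID_NORM_TOL = 1e-6


@dataclass
class Parcellation:
    """Label volume plus per-parcel unit-sphere centroids.

    Parameters
    ----------
    labels : ndarray of int, shape (nx, ny, nz)
        0 is background; positive integers are parcel labels.
    parcel_ids : ndarray of int, shape (n,)
        Ordered parcel identifiers; every id must occur in ``labels``.
    centroids : ndarray, shape (n, 3)
        Unit-norm spherical coordinates, one row per parcel id.
    """

    labels: np.ndarray
    parcel_ids: np.ndarray
    centroids: np.ndarray

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        self.parcel_ids = np.asarray(self.parcel_ids, dtype=int)
        self.centroids = np.asarray(self.centroids, dtype=float)
        if self.labels.ndim != 3 or not np.issubdtype(self.labels.dtype, np.integer):
            raise ValueError("labels must be a 3D integer array")
        if self.parcel_ids.ndim != 1 or self.parcel_ids.size == 0:
            raise ValueError("parcel_ids must be a nonempty 1D array")
        if np.unique(self.parcel_ids).size != self.parcel_ids.size:
            raise ValueError("parcel_ids must be unique")
        if np.any(self.parcel_ids <= 0):
            raise ValueError("parcel ids must be positive (0 is background)")
        if self.centroids.shape != (self.parcel_ids.size, 3):
            raise ValueError("centroids must be (n_parcels, 3)")
        norms = np.linalg.norm(self.centroids, axis=1)
        if np.any(np.abs(norms - 1.0) > _CENTROID_NORM_TOL):
            raise ValueError("centroids must have unit norm")
        present = np.unique(self.labels[self.labels > 0])
        missing = np.setdiff1d(self.parcel_ids, present)
        if missing.size:
            raise ValueError(f"parcel ids absent from label volume: {missing.tolist()}")

    @property
    def n_parcels(self) -> int:
        return int(self.parcel_ids.size)


def parcel_medians(vmap: VolumeMap, parc: Parcellation) -> np.ndarray:
    """Per-parcel median of within-parcel voxel values.

    Returns one value per parcel, ordered as ``parc.parcel_ids``. Even
    parcel sizes average the two central values (numpy convention).
    """
    if vmap.shape != parc.labels.shape:
        raise ValueError("map grid does not match parcellation grid")
    out = np.empty(parc.n_parcels)
    for i, pid in enumerate(parc.parcel_ids):
        vox = vmap.values[parc.labels == pid]
        if vox.size == 0:
            raise ValueError(f"parcel {pid} is empty")
        out[i] = np.median(vox)
    if not np.isfinite(out).all():
        raise ValueError("non-finite parcel median")
    return out


def relabel_contiguous(parc: Parcellation) -> Parcellation:
    """Renumber parcels 1..n by order of first appearance in the volume.

    The centroid table is reordered so each new label keeps its original
    centroid.
    """
    flat = parc.labels.ravel()
    nonzero = flat[flat > 0]
    if nonzero.size == 0:
        raise ValueError("no nonzero labels to relabel")
    uniq, first_pos = np.unique(nonzero, return_index=True)
    old_order = uniq[np.argsort(first_pos)]  # ids by first appearance

    lut = np.zeros(int(parc.labels.max()) + 1, dtype=parc.labels.dtype)
    for new_id, old_id in enumerate(old_order, start=1):
        lut[old_id] = new_id
    new_labels = lut[parc.labels]

    id_row = {int(pid): i for i, pid in enumerate(parc.parcel_ids)}
    rows = [id_row[int(old)] for old in old_order]
    return Parcellation(
        labels=new_labels,
        parcel_ids=np.arange(1, old_order.size + 1),
        centroids=parc.centroids[rows],
    )
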