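"""NIfTI and CSV input/output for maps, series, and parcellations."""

from __future__ import annotations

from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

from .parcellation import Parcellation
from .volume import DynamicSeries, VolumeMap

__all__ = [
    "default_affine",
    "load_volume",
    "save_volume",
    "load_series",
    "save_series",
    "load_mask",
    "save_mask",
    "load_parcellation",
    "save_parcellation",
    "save_parcel_vector",
]


def default_affine(shape: tuple[int, int, int], voxel_size_mm: float) -> np.ndarray:
    """Scaling affine with the grid center at the world origin."""
    affine = np.diag([voxel_size_mm] * 3 + [1.0])
    affine[:3, 3] = -voxel_size_mm * (np.asarray(shape) - 1) / 2.0
    return affine


def _voxel_size(img: nib.Nifti1Image) -> float:
    return float(img.header.get_zooms()[0])


def load_volume(path: str | Path) -> VolumeMap:
    img = nib.load(str(path))
    data = np.asarray(img.dataobj, dtype=float)
    if data.ndim == 4 and data.shape[3] == 1:
        data = data[..., 0]
    if data.ndim != 3:
        raise ValueError(f"{path}: expected a 3D volume, got shape {data.shape}")
    return VolumeMap(data, _voxel_size(img))


def save_volume(path: str | Path, vmap: VolumeMap) -> None:
    affine = default_affine(vmap.shape, vmap.voxel_size_mm)
    nib.save(nib.Nifti1Image(vmap.values.astype(np.float64), affine), str(path))


def load_series(path: str | Path) -> DynamicSeries:
    """Load a 4D series; frame times come from the header TR (pixdim[4])."""
    img = nib.load(str(path))
    data = np.asarray(img.dataobj, dtype=float)
    if data.ndim != 4:
        raise ValueError(f"{path}: expected a 4D series, got shape {data.shape}")
    zooms = img.header.get_zooms()
    dt = float(zooms[3]) if len(zooms) > 3 and zooms[3] > 0 else 1.0
    times = np.arange(data.shape[3]) * dt
    return DynamicSeries(data, times, float(zooms[0]))


def save_series(path: str | Path, series: DynamicSeries) -> None:
    intervals = np.diff(series.frame_times_s)
    dt = float(intervals[0]) if intervals.size else 1.0
    affine = default_affine(series.data.shape[:3], series.voxel_size_mm)
    img = nib.Nifti1Image(series.data.astype(np.float64), affine)
    img.header.set_zooms((series.voxel_size_mm,) * 3 + (dt,))
    nib.save(img, str(path))


def load_mask(path: str | Path) -> np.ndarray:
    img = nib.load(str(path))
    return np.asarray(img.dataobj) > 0


def save_mask(path: str | Path, mask: np.ndarray, voxel_size_mm: float) -> None:
    affine = default_affine(mask.shape, voxel_size_mm)
    nib.save(nib.Nifti1Image(mask.astype(np.uint8), affine), str(path))


def load_parcellation(
    labels_path: str | Path,
    centroids_path: str | Path,
    renormalize: bool = False,
) -> Parcellation:
    """Load a label NIfTI plus a centroid CSV (parcel_id, x, y, z)."""
    img = nib.load(str(labels_path))
    labels = np.asarray(img.dataobj).astype(np.int32)
    table = pd.read_csv(centroids_path)
    required = {"parcel_id", "x", "y", "z"}
    if not required.issubset(table.columns):
        raise ValueError(f"centroid CSV must have columns {sorted(required)}")
    centroids = table[["x", "y", "z"]].to_numpy(dtype=float)
    if renormalize:
        centroids = centroids / np.linalg.norm(centroids, axis=1, keepdims=True)
    return Parcellation(
        labels=labels,
        parcel_ids=table["parcel_id"].to_numpy(dtype=int),
        centroids=centroids,
    )


def save_parcellation(
    labels_path: str | Path,
    centroids_path: str | Path,
    parc: Parcellation,
    voxel_size_mm: float,
) -> None:
    affine = default_affine(parc.labels.shape, voxel_size_mm)
    nib.save(nib.Nifti1Image(parc.labels.astype(np.int32), affine), str(labels_path))
    pd.DataFrame(
        {
            "parcel_id": parc.parcel_ids,
            "x": parc.centroids[:, 0],
            "y": parc.centroids[:, 1],
            "z": parc.centroids[:, 2],
        }
    ).to_csv(centroids_path, index=False)


def save_parcel_vector(path: str | Path, parc: Parcellation, values: np.ndarray) -> None:
    values = np.asarray(values, dtype=float)
    if values.size != parc.n_parcels:
        raise ValueError("values must have one entry per parcel")
    pd.DataFrame({"parcel_id": parc.parcel_ids, "value": values}).to_csv(path, index=False)
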