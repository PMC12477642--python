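"""End-to-end study orchestration.

Runs the full analysis on simulated (or user-supplied) multi-subject data:
per-subject sum images and whole-brain normalization, per-subject residual
and ratio maps, voxelwise group medians, smoothing of one modality,
within- and between-modality correlation matrices with spin-permutation
p-values and FDR flags, and a two-block PLS — writing CSV tables, NIfTI
maps, and a JSON provenance record.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from itertools import combinations, product
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .derived import compute_gi, compute_oef, spatial_regress_out
from .io import save_mask, save_parcellation, save_volume
from .parcellation import Parcellation, parcel_medians
from .pls import PLSModel, fit_pls, normalize_scores, score_correlations
from .stats import fdr_bh, spearman_rho, spin_permutation_indices, spin_test
from .synthetic import (
    DynamicSpec,
    LatentFieldSpec,
    MixingSpec,
    default_mixing_spec,
    ellipsoid_mask,
    generate_latent_fields,
    generate_spherical_parcellation,
    generate_subject_dataset,
)
from .volume import (
    IntegrationWindow,
    VolumeMap,
    gaussian_smooth,
    group_median,
    normalize_global_mean,
    optimize_fwhm,
    sum_image,
)

__all__ = ["RunConfig", "StudyResult", "run_study"]

logger = logging.getLogger("crossmodal")

HP_LABELS = ("pyruvate", "lactate", "bicarbonate", "lpr", "bpr", "lbr")
PET_LABELS = ("cmrglc", "cbf", "cmro2", "cbv", "oef", "gi")


@dataclass
class RunConfig:
    """Configuration for one full study run. Defaults follow the study design."""

    out_dir: str = "crossmodal_out"
    seed: int = 0
    # synthetic-data block
    n_subjects: int = 35
    grid_shape: tuple[int, int, int] = (32, 32, 32)
    voxel_size_mm: float = 6.0
    n_latents: int = 3
    latent_fwhm_mm: float = 24.0
    subject_noise_sd: float = 0.1
    voxel_noise_sd: float = 0.02
    n_frames: int = 12
    frame_interval_s: float = 5.0
    n_parcels: int = 200
    # analysis
    fwhm_mm: float = 14.0
    fwhm_grid: tuple[float, ...] | None = None
    smooth_block: str = "pet"
    n_perm: int = 10_000
    alpha: float = 0.05
    denom_floor: float = 0.05
    pls_components: int = 2
    pls_x_channels: tuple[str, ...] = HP_LABELS
    pls_y_channels: tuple[str, ...] = PET_LABELS
    write_outputs: bool = True

    def __post_init__(self) -> None:
        self.grid_shape = tuple(int(d) for d in self.grid_shape)
        if self.fwhm_grid is not None:
            self.fwhm_grid = tuple(float(f) for f in self.fwhm_grid)
        self.pls_x_channels = tuple(self.pls_x_channels)
        self.pls_y_channels = tuple(self.pls_y_channels)
        if self.n_perm < 100:
            raise ValueError("n_perm must be at least 100")
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must lie in (0, 1)")
        if self.fwhm_mm < 0:
            raise ValueError("fwhm_mm must be nonnegative")
        if self.smooth_block not in ("pet", "hp", "none"):
            raise ValueError("smooth_block must be 'pet', 'hp' or 'none'")
        if self.pls_components < 1:
            raise ValueError("pls_components must be positive")

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        data.update(overrides)
        return cls(**data)

    def to_dict(self) -> dict:
        d = asdict(self)
        d["grid_shape"] = list(self.grid_shape)
        d["fwhm_grid"] = list(self.fwhm_grid) if self.fwhm_grid is not None else None
        d["pls_x_channels"] = list(self.pls_x_channels)
        d["pls_y_channels"] = list(self.pls_y_channels)
        return d

    @property
    def config_hash(self) -> str:
        d = self.to_dict()
        d.pop("out_dir")  # where results land must not change what they are
        d.pop("write_outputs")
        payload = json.dumps(d, sort_keys=True).encode()
        return hashlib.sha256(payload).hexdigest()[:12]


@dataclass
class StudyResult:
    """In-memory bundle returned by :func:`run_study`."""

    config: RunConfig
    mask: np.ndarray
    analysis_mask: np.ndarray
    parcellation: Parcellation
    group_maps: dict[str, VolumeMap]
    smoothed_maps: dict[str, VolumeMap]
    fwhm_used: float
    correlations: pd.DataFrame
    pls: PLSModel
    pls_score_correlations: np.ndarray
    provenance: dict


def _subject_maps(
    config: RunConfig,
    latents: list[VolumeMap],
    mask: np.ndarray,
    mixing: MixingSpec,
    dyn: DynamicSpec,
) -> tuple[list[dict[str, VolumeMap]], np.ndarray]:
    """Per-subject normalized sum images plus derived maps.

    Returns the per-subject label->map dicts and the analysis mask (the
    brain mask intersected with every subject's valid ratio-map voxels).
    """
    subject_seeds = np.random.SeedSequence(config.seed).generate_state(config.n_subjects)
    window = IntegrationWindow.all_frames()
    subjects: list[dict[str, VolumeMap]] = []
    analysis_mask = mask.copy()
    for s in range(config.n_subjects):
        series = generate_subject_dataset(latents, mixing, dyn, int(subject_seeds[s]), mask)
        maps = {
            ch: normalize_global_mean(sum_image(ser, window), mask)
            for ch, ser in series.items()
        }
        maps["lbr"] = spatial_regress_out(maps["lactate"], maps["bicarbonate"], mask).values
        maps["lpr"] = spatial_regress_out(maps["lactate"], maps["pyruvate"], mask).values
        maps["bpr"] = spatial_regress_out(maps["bicarbonate"], maps["pyruvate"], mask).values
        maps["gi"] = compute_gi(maps["cmrglc"], maps["cmro2"], mask).values
        oef, valid = compute_oef(
            maps["cmro2"], maps["cbf"], maps["cbv"], mask, config.denom_floor
        )
        maps["oef"] = oef
        analysis_mask &= valid
        subjects.append(maps)
    return subjects, analysis_mask


def _correlation_family(
    pairs: list[tuple[str, str]],
    family: str,
    maps: dict[str, VolumeMap],
    parcel_vectors: dict[str, np.ndarray],
    analysis_mask: np.ndarray,
    parc: Parcellation,
    perm_idx: np.ndarray,
    alpha: float,
) -> pd.DataFrame:
    rows = []
    for a, b in pairs:
        rho_vox = spearman_rho(
            maps[a].values[analysis_mask], maps[b].values[analysis_mask]
        )
        rho_parcel, p_spin, _ = spin_test(
            parcel_vectors[a], parcel_vectors[b], parc, perm_idx=perm_idx
        )
        rows.append(
            {
                "family": family,
                "label_a": a,
                "label_b": b,
                "rho_voxel": rho_vox,
                "rho_parcel": rho_parcel,
                "p_spin": p_spin,
            }
        )
    df = pd.DataFrame(rows)
    df["q_flag"] = fdr_bh(df["p_spin"].to_numpy(), alpha)
    return df


def run_study(config: RunConfig) -> StudyResult:
    """Execute the full pipeline for one configuration.

    The run is a pure function of (config, seed): identical inputs yield
    byte-identical CSV outputs.
    """
    logger.info("run_study: seed=%d hash=%s", config.seed, config.config_hash)

    # --- synthetic inputs -------------------------------------------------
    lat_spec = LatentFieldSpec(
        grid_shape=config.grid_shape,
        voxel_size_mm=config.voxel_size_mm,
        n_latents=config.n_latents,
        smooth_fwhm_mm=config.latent_fwhm_mm,
        seed=config.seed,
    )
    latents = generate_latent_fields(lat_spec)
    mask = ellipsoid_mask(config.grid_shape)
    mixing = default_mixing_spec(
        n_subjects=config.n_subjects,
        subject_noise_sd=config.subject_noise_sd,
        voxel_noise_sd=config.voxel_noise_sd,
    )
    dyn = DynamicSpec(n_frames=config.n_frames, frame_interval_s=config.frame_interval_s)
    parc = generate_spherical_parcellation(
        config.grid_shape, mask, config.n_parcels, seed=config.seed + 1
    )

    # --- per-subject processing ------------------------------------------
    logger.info("stage: subject sum images, normalization, derived maps")
    subjects, analysis_mask = _subject_maps(config, latents, mask, mixing, dyn)

    # --- group medians ----------------------------------------------------
    logger.info("stage: group medians")
    labels = list(HP_LABELS) + list(PET_LABELS)
    group_maps = {
        lab: group_median([subj[lab] for subj in subjects]) for lab in labels
    }

    # --- smoothing --------------------------------------------------------
    smooth_labels: tuple[str, ...] = ()
    if config.smooth_block == "pet":
        smooth_labels = PET_LABELS
    elif config.smooth_block == "hp":
        smooth_labels = HP_LABELS
    if config.fwhm_grid is not None and smooth_labels:
        fixed = HP_LABELS if config.smooth_block == "pet" else PET_LABELS
        n_pairs = min(len(fixed), len(smooth_labels))
        fwhm_used = optimize_fwhm(
            [group_maps[lab] for lab in fixed[:n_pairs]],
            [group_maps[lab] for lab in smooth_labels[:n_pairs]],
            analysis_mask,
            config.fwhm_grid,
        )
    else:
        fwhm_used = config.fwhm_mm
    logger.info("stage: smoothing %s at %.1f mm FWHM", smooth_labels, fwhm_used)
    smoothed = dict(group_maps)
    for lab in smooth_labels:
        smoothed[lab] = gaussian_smooth(group_maps[lab], fwhm_used, analysis_mask)

    # --- correlation matrices --------------------------------------------
    logger.info("stage: correlations (%d permutations)", config.n_perm)
    parcel_vectors = {lab: parcel_medians(smoothed[lab], parc) for lab in labels}
    perm_idx, _ = spin_permutation_indices(parc, config.n_perm, seed=config.seed + 2)
    frames = [
        _correlation_family(
            list(combinations(HP_LABELS, 2)), "hp_within",
            smoothed, parcel_vectors, analysis_mask, parc, perm_idx, config.alpha,
        ),
        _correlation_family(
            list(combinations(PET_LABELS, 2)), "pet_within",
            smoothed, parcel_vectors, analysis_mask, parc, perm_idx, config.alpha,
        ),
        _correlation_family(
            list(product(HP_LABELS, PET_LABELS)), "between",
            smoothed, parcel_vectors, analysis_mask, parc, perm_idx, config.alpha,
        ),
    ]
    correlations = pd.concat(frames, ignore_index=True)
    correlations["n_perm"] = config.n_perm
    correlations["seed"] = config.seed
    correlations["config_hash"] = config.config_hash

    # --- PLS --------------------------------------------------------------
    logger.info("stage: PLS (%d components)", config.pls_components)
    X = np.column_stack(
        [smoothed[lab].values[analysis_mask] for lab in config.pls_x_channels]
    )
    Y = np.column_stack(
        [smoothed[lab].values[analysis_mask] for lab in config.pls_y_channels]
    )
    model = normalize_scores(fit_pls(X, Y, config.pls_components))
    score_corrs = score_correlations(model)

    provenance = {
        "config": config.to_dict(),
        "config_hash": config.config_hash,
        "seed": config.seed,
        "n_perm": config.n_perm,
        "alpha": config.alpha,
        "fwhm_used": fwhm_used,
        "crossmodal_version": __version__,
        "numpy_version": np.__version__,
    }

    result = StudyResult(
        config=config,
        mask=mask,
        analysis_mask=analysis_mask,
        parcellation=parc,
        group_maps=group_maps,
        smoothed_maps=smoothed,
        fwhm_used=fwhm_used,
        correlations=correlations,
        pls=model,
        pls_score_correlations=score_corrs,
        provenance=provenance,
    )
    if config.write_outputs:
        _write_outputs(result)
    return result


def _write_outputs(result: StudyResult) -> None:
    config = result.config
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    logger.info("stage: writing outputs to %s", out)

    result.correlations.to_csv(out / "correlations.csv", index=False)

    weight_rows = []
    for comp in range(result.pls.n_components):
        for block, channels, weights in (
            ("hp", config.pls_x_channels, result.pls.weights_x),
            ("pet", config.pls_y_channels, result.pls.weights_y),
        ):
            for ch, w in zip(channels, weights[comp]):
                weight_rows.append(
                    {
                        "component": comp + 1,
                        "block": block,
                        "channel": ch,
                        "weight": w,
                        "config_hash": config.config_hash,
                    }
                )
    pd.DataFrame(weight_rows).to_csv(out / "pls_weights.csv", index=False)

    pd.DataFrame(
        {
            "component": np.arange(1, result.pls.n_components + 1),
            "score_spearman_rho": result.pls_score_correlations,
            "config_hash": config.config_hash,
        }
    ).to_csv(out / "pls_score_correlations.csv", index=False)

    voxel = config.voxel_size_mm
    save_mask(out / "mask.nii.gz", result.mask, voxel)
    save_mask(out / "analysis_mask.nii.gz", result.analysis_mask, voxel)
    save_parcellation(
        out / "parcellation.nii.gz", out / "parcel_centroids.csv",
        result.parcellation, voxel,
    )
    for lab, vmap in result.smoothed_maps.items():
        save_volume(out / f"group_{lab}.nii.gz", vmap)
    for block, scores in (("hp", result.pls.scores_x), ("pet", result.pls.scores_y)):
        for comp in range(result.pls.n_components):
            vol = np.zeros(result.mask.shape)
            vol[result.analysis_mask] = scores[:, comp]
            save_volume(
                out / f"scores_{block}_component{comp + 1}.nii.gz",
                VolumeMap(vol, voxel),
            )
    with open(out / "provenance.json", "w") as fh:
        json.dump(result.provenance, fh, indent=2, sort_keys=True)
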