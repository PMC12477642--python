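"""Derived maps: spatial-regression residuals and the oxygen-extraction ratio.

Residual maps replace voxelwise division when normalizing one channel by
another: the dependent map is regressed on the independent map over the
within-mask voxels (each voxel is one observation), and the residuals form
a mean-zero map that is orthogonal to the regressor by construction.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .volume import VolumeMap, normalize_global_mean

__all__ = [
    "ResidualMap",
    "spatial_regress_out",
    "compute_gi",
    "remove_vascular_component",
    "compute_oef",
]


@dataclass
class ResidualMap:
    """Residuals of one map regressed on another, plus the fitted line."""

    values: VolumeMap
    dependent_label: str
    independent_label: str
    slope: float
    intercept: float


def _ols_1d(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Slope and intercept of ordinary least squares with intercept."""
    xm, ym = x.mean(), y.mean()
    dx = x - xm
    sxx = float(dx @ dx)
    if sxx == 0:
        raise ValueError("independent map is constant within the mask")
    slope = float(dx @ (y - ym)) / sxx
    return slope, float(ym - slope * xm)


def spatial_regress_out(
    dependent: VolumeMap,
    independent: VolumeMap,
    mask: np.ndarray,
    dependent_label: str = "dependent",
    independent_label: str = "independent",
) -> ResidualMap:
    """OLS residual map of ``dependent`` regressed on ``independent``.

    Within-mask voxels are the observations; the fit includes an
    intercept, so the residual map has within-mask mean 0 and is
    orthogonal to the regressor. Voxels outside the mask are set to 0.
    """
    mask = np.asarray(mask, dtype=bool)
    x = independent.values[mask]
    y = dependent.values[mask]
    slope, intercept = _ols_1d(x, y)
    out = np.zeros_like(dependent.values)
    out[mask] = y - (intercept + slope * x)
    return ResidualMap(
        values=dependent.with_values(out),
        dependent_label=dependent_label,
        independent_label=independent_label,
        slope=slope,
        intercept=intercept,
    )


def compute_gi(cmrglc: VolumeMap, cmro2: VolumeMap, mask: np.ndarray) -> ResidualMap:
    """Glycolytic-index residual: glucose-channel map regressed on oxygen.

    Positive values flag regions where glucose consumption exceeds what the
    oxygen-consumption map predicts; the map has whole-brain mean 0.
    """
    return spatial_regress_out(cmrglc, cmro2, mask, "cmrglc", "cmro2")


def remove_vascular_component(
    target: VolumeMap, cbv: VolumeMap, mask: np.ndarray
) -> VolumeMap:
    """Regress the blood-volume map out of ``target``, restoring the intercept.

    The residual alone would be mean-zero; adding the fitted intercept back
    keeps the corrected map positive so it can enter downstream ratios.
    The result is uncorrelated with ``cbv`` within the mask.
    """
    res = spatial_regress_out(target, cbv, mask, "target", "cbv")
    out = res.values.values.copy()
    out[np.asarray(mask, dtype=bool)] += res.intercept
    return target.with_values(out)


def compute_oef(
    o2_sum: VolumeMap,
    h2o_sum: VolumeMap,
    cbv: VolumeMap,
    mask: np.ndarray,
    denom_floor: float = 0.05,
) -> tuple[VolumeMap, np.ndarray]:
    """Oxygen-extraction ratio map with a denominator floor.

    The oxygen sum image is vascular-corrected against ``cbv``, divided
    voxelwise by the water sum image, and normalized to a within-mask mean
    of 1. Voxels whose denominator falls below ``denom_floor`` times the
    within-mask median of ``h2o_sum`` are excluded; the returned mask marks
    the voxels that survive.
    """
    mask = np.asarray(mask, dtype=bool)
    o2_corr = remove_vascular_component(o2_sum, cbv, mask)
    h2o = h2o_sum.values
    floor = denom_floor * float(np.median(h2o[mask]))
    valid = mask & (h2o > floor)
    if not valid.any():
        raise ValueError("all voxels excluded by the denominator floor")
    ratio = np.zeros_like(h2o)
    ratio[valid] = o2_corr.values[valid] / h2o[valid]
    oef = normalize_global_mean(o2_sum.with_values(ratio), valid)
    return oef, valid
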