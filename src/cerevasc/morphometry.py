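"""Deformation-based morphometry and ROI volumetry.

The Jacobian determinant of a subject-to-common-space deformation measures
local volume change per voxel (det > 1: the subject is locally larger).
Voxel-wise group differences are tested on log-Jacobians — the log
symmetrises expansion against contraction — with Benjamini–Hochberg FDR
control across voxels inside an analysis mask.  ROI volumetry is exact
integer voxel counting times the voxel volume.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats
from statsmodels.stats.multitest import multipletests

from cerevasc.grids import DisplacementField, LabelVolume, Volume
from cerevasc.acbv import percent_increase

__all__ = [
    "jacobian_map",
    "VoxelStatMap",
    "voxelwise_group_test",
    "fdr_mask",
    "VolumetryResult",
    "roi_volume",
    "group_mean_ci",
    "volume_summaries",
]


def jacobian_map(field: DisplacementField) -> Volume:
    """``det(I + grad u)`` with central differences in physical units.

    One-sided differences at the boundary faces; exact for affine fields in
    the interior.  Non-positive determinants are reported as-is (they mean
    the input field folds), not rejected.
    """
    if min(field.shape) < 3:
        raise ValueError("need at least 3 voxels per axis for differences")
    u = field.vectors
    h = field.spacing
    # grad[i][j] = d u_i / d x_j
    grad = [[np.gradient(u[..., i], h, axis=j) for j in range(3)] for i in range(3)]
    g = [[grad[i][j] + (1.0 if i == j else 0.0) for j in range(3)] for i in range(3)]
    det = (
        g[0][0] * (g[1][1] * g[2][2] - g[1][2] * g[2][1])
        - g[0][1] * (g[1][0] * g[2][2] - g[1][2] * g[2][0])
        + g[0][2] * (g[1][0] * g[2][1] - g[1][1] * g[2][0])
    )
    return Volume(values=det, spacing=field.spacing)


@dataclass
class VoxelStatMap:
    """Voxel-wise statistic/p maps with the FDR-significant mask."""

    statistic: np.ndarray
    p: np.ndarray
    significant: np.ndarray
    q: float
    direction: np.ndarray | None = None  # sign of old-vs-young mean log-J difference


def voxelwise_group_test(
    jacobians_by_group: dict[str, list[Volume]],
    analysis_mask: np.ndarray | None = None,
    q: float = 0.05,
    exclude_boundary: bool = True,
) -> VoxelStatMap:
    """Per-voxel two-sample t (2 groups) or one-way F (>= 3 groups) on log-Jacobians.

    Voxels with zero variance in every group get p = 1.  Boundary voxels
    use one-sided derivative stencils and are excluded from testing by
    default.  The FDR mask is computed over the analysis mask only.
    """
    groups = list(jacobians_by_group)
    if len(groups) < 2:
        raise ValueError("need at least two groups")
    data = []
    shape = None
    for gname in groups:
        vols = jacobians_by_group[gname]
        if len(vols) < 2:
            raise ValueError(f"group {gname!r} needs >= 2 subjects")
        arr = np.stack([v.values for v in vols])
        if shape is None:
            shape = arr.shape[1:]
        elif arr.shape[1:] != shape:
            raise ValueError("all Jacobian maps must share a grid")
        if np.any(arr <= 0):
            raise ValueError("non-positive Jacobians cannot be log-transformed")
        data.append(np.log(arr))

    if analysis_mask is None:
        analysis_mask = np.ones(shape, dtype=bool)
    else:
        analysis_mask = analysis_mask.copy()
    if exclude_boundary:
        interior = np.zeros(shape, dtype=bool)
        interior[1:-1, 1:-1, 1:-1] = True
        analysis_mask &= interior

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # zero-variance voxels produce nan
        if len(groups) == 2:
            res = stats.ttest_ind(data[0], data[1], axis=0)
            stat, p = np.asarray(res.statistic), np.asarray(res.pvalue)
        else:
            res = stats.f_oneway(*data, axis=0)
            stat, p = np.asarray(res.statistic), np.asarray(res.pvalue)

    degenerate = ~np.isfinite(p)
    p = np.where(degenerate, 1.0, p)
    stat = np.where(np.isfinite(stat), stat, 0.0)
    direction = np.sign(data[-1].mean(axis=0) - data[0].mean(axis=0))
    significant = fdr_mask(p, q=q, analysis_mask=analysis_mask)
    return VoxelStatMap(statistic=stat, p=p, significant=significant, q=q, direction=direction)


def fdr_mask(p: np.ndarray, q: float = 0.05, analysis_mask: np.ndarray | None = None) -> np.ndarray:
    """Benjamini–Hochberg step-up over the voxels inside the analysis mask.

    Rejects all p <= p_(k*) with ``k* = max{k : p_(k) <= k q / m}``; returns
    a boolean grid that is False everywhere outside the mask.
    """
    p = np.asarray(p, dtype=float)
    if analysis_mask is None:
        analysis_mask = np.ones(p.shape, dtype=bool)
    if not analysis_mask.any():
        raise ValueError("analysis mask is empty")
    pv = p[analysis_mask]
    if np.any((pv < 0) | (pv > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    reject, *_ = multipletests(pv, alpha=q, method="fdr_bh")
    out = np.zeros(p.shape, dtype=bool)
    out[analysis_mask] = reject
    return out


@dataclass(frozen=True)
class VolumetryResult:
    roi: str
    n_voxels: int
    volume_mm3: float


def roi_volume(labels: LabelVolume, roi: str | int | tuple[int, ...]) -> VolumetryResult:
    """Exact ROI volume: voxel count times spacing^3 (no tolerance)."""
    ids = labels.roi_ids(roi)
    n = int(np.isin(labels.labels, ids).sum())
    if n == 0:
        warnings.warn(f"ROI {roi!r} is empty; volume 0", stacklevel=2)
    return VolumetryResult(roi=str(roi), n_voxels=n, volume_mm3=n * labels.spacing**3)


def group_mean_ci(values, confidence: float = 0.95) -> tuple[float, float, float]:
    """t-based mean and confidence interval: (mean, lo, hi)."""
    v = np.asarray(values, dtype=float)
    m = float(v.mean())
    if v.size < 2:
        return m, m, m
    half = stats.t.ppf(0.5 + confidence / 2.0, df=v.size - 1) * v.std(ddof=1) / np.sqrt(v.size)
    return m, m - float(half), m + float(half)


def volume_summaries(volumes_by_group: dict[str, dict[str, float]]) -> dict[str, dict[str, float]]:
    """Derived volumetric summaries across age groups.

    Input: ``{group: {"whole_brain": mm3, "ventricular_system": mm3}}`` with
    groups ordered youngest first.  Output per group: percent change of each
    region relative to the youngest group and the ventricular fraction
    (ventricle volume as % of whole brain).
    """
    groups = list(volumes_by_group)
    ref = volumes_by_group[groups[0]]
    out: dict[str, dict[str, float]] = {}
    for g in groups:
        cur = volumes_by_group[g]
        entry: dict[str, float] = {}
        for region, vol in cur.items():
            if ref[region] == 0:
                raise ValueError(f"zero reference volume for {region!r}")
            entry[f"{region}_pct_change"] = percent_increase(ref[region], vol)
        if "whole_brain" in cur and "ventricular_system" in cur:
            if cur["whole_brain"] == 0:
                raise ValueError("zero whole-brain volume")
            entry["ventricular_fraction_pct"] = (
                100.0 * cur["ventricular_system"] / cur["whole_brain"]
            )
        out[g] = entry
    return out
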