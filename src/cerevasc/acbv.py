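"""Apparent cerebral blood volume quantification.

The aCBV of an ROI is the percentage of its voxels whose signal intensity
satisfies ``SI >= mean(SI_ROI) + k * SD(SI_ROI)`` with ``k = 2.5`` by
default.  The moments are computed over *all* ROI voxels (vessels
included) in a single pass — the threshold is chosen once, not iterated —
and the inequality is inclusive.  Because mean and SD transform together,
the statistic is invariant to affine intensity rescaling.

Also here: maximum-intensity projection rendering, the SNR measurement
(mean signal over background-noise SD, averaged across signal ROIs), and
the percent-change helpers used for the aging summaries.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from cerevasc.grids import LabelVolume, Volume, check_aligned

__all__ = [
    "AcbvParams",
    "AcbvResult",
    "roi_mask",
    "acbv_threshold",
    "compute_acbv",
    "mip",
    "measure_snr",
    "percent_change",
    "percent_increase",
]


@dataclass(frozen=True)
class AcbvParams:
    """Threshold multiplier ``k`` and inclusivity of the comparison."""

    k: float = 2.5
    inclusive: bool = True

    def __post_init__(self) -> None:
        if self.k < 0:
            raise ValueError("k must be >= 0")


@dataclass(frozen=True)
class AcbvResult:
    roi: str
    threshold: float
    n_voxels: int
    n_supra: int
    degenerate: bool = False

    @property
    def acbv(self) -> float:
        """Suprathreshold voxel percentage."""
        return 100.0 * self.n_supra / self.n_voxels


def roi_mask(labels: LabelVolume, roi: str | int | tuple[int, ...]) -> np.ndarray:
    """Binary mask of an ROI; union names resolve to all member labels."""
    ids = labels.roi_ids(roi)
    mask = np.isin(labels.labels, ids)
    if not mask.any():
        warnings.warn(f"ROI {roi!r} is empty on this grid", stacklevel=2)
    return mask


def acbv_threshold(volume: Volume, mask: np.ndarray, params: AcbvParams = AcbvParams()) -> float:
    """``mean + k * SD`` over the masked voxels (sample SD, n-1)."""
    vals = volume.values[mask]
    if vals.size == 0:
        raise ValueError("mask selects no voxels")
    sd = vals.std(ddof=1) if vals.size > 1 else 0.0
    return float(vals.mean() + params.k * sd)


def compute_acbv(
    volume: Volume,
    labels: LabelVolume,
    roi: str | int | tuple[int, ...],
    params: AcbvParams = AcbvParams(),
) -> AcbvResult:
    """Threshold an ROI and count its suprathreshold voxel percentage.

    A constant-intensity ROI yields 100% (every voxel satisfies the
    inclusive inequality at SD = 0); this is reported with
    ``degenerate=True`` rather than raised, since it is the formula's
    literal consequence.
    """
    check_aligned(volume, labels)
    mask = roi_mask(labels, roi)
    if not mask.any():
        raise ValueError(f"ROI {roi!r} is empty")
    thr = acbv_threshold(volume, mask, params)
    vals = volume.values[mask]
    if params.inclusive:
        n_supra = int(np.count_nonzero(vals >= thr))
    else:
        n_supra = int(np.count_nonzero(vals > thr))
    degenerate = bool(np.allclose(vals, vals.flat[0]))
    if degenerate:
        warnings.warn(
            f"ROI {roi!r} has constant intensity; aCBV is degenerate (100%)",
            stacklevel=2,
        )
    return AcbvResult(
        roi=str(roi),
        threshold=thr,
        n_voxels=int(mask.sum()),
        n_supra=n_supra,
        degenerate=degenerate,
    )


_AXES = {"x": 0, "y": 1, "z": 2}


def mip(volume: Volume, axis: str | int = "z", mask: np.ndarray | None = None) -> np.ndarray:
    """Maximum-intensity projection along an axis.

    With a mask, voxels outside it are treated as -inf, so rays that never
    touch the mask project to -inf.
    """
    ax = _AXES.get(axis, axis) if isinstance(axis, str) else int(axis)
    if ax not in (0, 1, 2):
        raise ValueError("axis must be one of x, y, z (or 0, 1, 2)")
    vals = volume.values
    if mask is not None:
        vals = np.where(mask, vals, -np.inf)
    return vals.max(axis=ax)


def measure_snr(
    volume: Volume,
    signal_masks: list[np.ndarray],
    noise_mask: np.ndarray,
) -> tuple[float, float]:
    """SNR per signal ROI = mean(ROI) / SD(noise ROI); returns (mean, SD) over ROIs.

    The noise ROI must lie outside anatomy; its *measured* SD is used
    directly, with no Rician correction.
    """
    if not noise_mask.any():
        raise ValueError("noise ROI is empty")
    noise_sd = float(volume.values[noise_mask].std(ddof=1))
    if noise_sd == 0:
        raise ValueError("noise ROI has zero SD")
    snrs = []
    for m in signal_masks:
        if not m.any():
            raise ValueError("a signal ROI is empty")
        snrs.append(float(volume.values[m].mean()) / noise_sd)
    return float(np.mean(snrs)), float(np.std(snrs, ddof=1)) if len(snrs) > 1 else 0.0


def percent_change(reference: float, later: float) -> float:
    """Percent *loss* relative to the reference: ``100 (ref - later)/ref``.

    Positive when the later value is smaller.  All aging losses are quoted
    relative to the youngest group.
    """
    if reference == 0:
        raise ValueError("reference must be nonzero")
    return 100.0 * (reference - later) / reference


def percent_increase(reference: float, later: float) -> float:
    """Percent gain relative to the reference: ``100 (later - ref)/ref``."""
    if reference == 0:
        raise ValueError("reference must be nonzero")
    return 100.0 * (later - reference) / reference
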