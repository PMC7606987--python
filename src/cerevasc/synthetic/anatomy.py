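"""Geometric mouse-brain-like label volumes.

Deliberately schematic: an ellipsoidal brain with shell and interior
compartments standing in for the atlas ROIs (cerebral cortex, cerebellar
cortex, entorhinal cortex, hippocampus, striatum) plus the four ventricular
labels.  No attempt is made at real neuroanatomy — the labels exist so the
ROI bookkeeping, thresholding, and volumetry code paths are exercised with
regions of realistic relative size.
"""

from __future__ import annotations

import numpy as np

from cerevasc.grids import LabelVolume

__all__ = ["LABEL_IDS", "ROI_NAME_MAP", "brain_labels", "volumetry_labels"]

LABEL_IDS = {
    "parenchyma": 1,
    "cerebral_cortex": 2,
    "cerebellar_cortex": 3,
    "entorhinal_cortex": 4,
    "hippocampus": 5,
    "striatum": 6,
    "lateral_ventricles": 10,
    "third_ventricle": 11,
    "cerebral_aqueduct": 12,
    "fourth_ventricle": 13,
}

_VENTRICLES = ("lateral_ventricles", "third_ventricle", "cerebral_aqueduct", "fourth_ventricle")

ROI_NAME_MAP: dict[str, tuple[int, ...]] = {
    **{name: (lid,) for name, lid in LABEL_IDS.items()},
    "ventricular_system": tuple(LABEL_IDS[v] for v in _VENTRICLES),
    "whole_brain": tuple(LABEL_IDS.values()),
}


def _normalized_coords(shape: tuple[int, int, int]) -> tuple[np.ndarray, ...]:
    """Per-axis coordinates scaled so the brain ellipsoid is the unit ball."""
    axes = []
    for n in shape:
        c = (n - 1) / 2.0
        a = 0.42 * n  # semi-axis in voxels
        axes.append((np.arange(n) - c) / a)
    ux = axes[0][:, None, None]
    uy = axes[1][None, :, None]
    uz = axes[2][None, None, :]
    rho = np.sqrt(ux**2 + uy**2 + uz**2)
    return ux, uy, uz, rho


def brain_labels(shape: tuple[int, int, int], spacing: float) -> LabelVolume:
    """Build the schematic atlas on the given grid.

    Shell compartments (both cortices, entorhinal cortex) occupy the outer
    ellipsoidal rind; hippocampus and striatum are interior; the four
    ventricular labels are small CSF pockets near the centre; everything
    else inside the brain is generic parenchyma.
    """
    ux, uy, uz, rho = _normalized_coords(shape)
    brain = rho <= 1.0
    labels = np.where(brain, LABEL_IDS["parenchyma"], 0).astype(np.int16)

    shell = (rho > 0.80) & brain
    cereb = shell & (ux > 0.62)
    labels[cereb] = LABEL_IDS["cerebellar_cortex"]
    ento = shell & (rho > 0.86) & (uz < -0.25) & (np.abs(ux) < 0.30) & ~cereb
    labels[ento] = LABEL_IDS["entorhinal_cortex"]
    cortex = (rho > 0.93) & brain & (uz > -0.25) & ~cereb
    labels[cortex] = LABEL_IDS["cerebral_cortex"]

    hipp = (rho > 0.45) & (rho < 0.62) & (np.abs(uz) < 0.25) & brain
    labels[hipp] = LABEL_IDS["hippocampus"]
    stri = (rho < 0.50) & (ux < -0.35) & brain
    labels[stri] = LABEL_IDS["striatum"]

    # small ventricular pockets: (centre offsets in normalized coords, semi-axes)
    pockets = {
        "lateral_ventricles": ((0.0, 0.28, 0.10), (0.18, 0.10, 0.10)),
        "third_ventricle": ((0.05, 0.0, -0.05), (0.06, 0.06, 0.12)),
        "cerebral_aqueduct": ((0.22, 0.0, -0.02), (0.12, 0.04, 0.04)),
        "fourth_ventricle": ((0.38, 0.0, -0.08), (0.08, 0.07, 0.07)),
    }
    for name, (centre, semi) in pockets.items():
        d = (
            ((ux - centre[0]) / semi[0]) ** 2
            + ((uy - centre[1]) / semi[1]) ** 2
            + ((uz - centre[2]) / semi[2]) ** 2
        )
        pocket = (d <= 1.0) & brain
        labels[pocket] = LABEL_IDS[name]
        mirror = (
            ((ux - centre[0]) / semi[0]) ** 2
            + ((uy + centre[1]) / semi[1]) ** 2
            + ((uz - centre[2]) / semi[2]) ** 2
        )
        if name == "lateral_ventricles":  # paired structure
            labels[(mirror <= 1.0) & brain] = LABEL_IDS[name]

    return LabelVolume(labels=labels, spacing=spacing, name_map=dict(ROI_NAME_MAP))


def volumetry_labels(
    brain_mm3: float,
    ventricle_mm3: dict[str, float] | float,
    spacing: float = 0.1,
    shape: tuple[int, int, int] | None = None,
) -> LabelVolume:
    """Label volume with *exact* voxel counts for volumetry fixtures.

    The brain is the ``round(brain_mm3 / spacing^3)`` voxels of smallest
    ellipsoidal radius, so ``count * spacing^3`` reproduces the requested
    volume to within half a voxel; ventricular pockets are carved the same
    way around interior centres.  ``ventricle_mm3`` may be a single total
    (split across the four labels 55/20/10/15 %) or a per-label dict.
    """
    n_brain = int(round(brain_mm3 / spacing**3))
    if shape is None:
        # ellipsoid with aspect 1 : 1.25 : 0.9 comfortably inside the grid
        vol_factor = 4.0 / 3.0 * np.pi * 0.42**3 * 1.25 * 0.9
        n_side = int(np.ceil((n_brain / vol_factor) ** (1 / 3)))
        shape = (n_side, int(np.ceil(1.25 * n_side)), int(np.ceil(0.9 * n_side)))
    ux, uy, uz, rho = _normalized_coords(shape)
    order = np.argsort(rho, axis=None, kind="stable")
    if n_brain > order.size:
        raise ValueError("grid too small for requested brain volume")
    labels = np.zeros(shape, dtype=np.int16)
    labels.ravel()[order[:n_brain]] = LABEL_IDS["parenchyma"]

    if not isinstance(ventricle_mm3, dict):
        split = {"lateral_ventricles": 0.55, "third_ventricle": 0.20,
                 "cerebral_aqueduct": 0.10, "fourth_ventricle": 0.15}
        ventricle_mm3 = {k: ventricle_mm3 * w for k, w in split.items()}
    centres = {
        "lateral_ventricles": (0.0, 0.25, 0.10),
        "third_ventricle": (0.05, 0.0, -0.05),
        "cerebral_aqueduct": (0.25, 0.0, -0.02),
        "fourth_ventricle": (0.40, 0.0, -0.08),
    }
    brain_mask = labels.ravel() == LABEL_IDS["parenchyma"]
    for name, target in ventricle_mm3.items():
        n_v = int(round(target / spacing**3))
        if n_v == 0:
            continue
        c = centres[name]
        d = ((ux - c[0]) ** 2 + (uy - c[1]) ** 2 + (uz - c[2]) ** 2).ravel()
        d = np.where(brain_mask, d, np.inf)
        pick = np.argpartition(d, n_v)[:n_v]
        labels.ravel()[pick] = LABEL_IDS[name]
        brain_mask[pick] = False

    return LabelVolume(labels=labels, spacing=spacing, name_map=dict(ROI_NAME_MAP))
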