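"""In-memory containers for volumetric and sectional image data.

All physical lengths are millimetres unless a name says otherwise
(histology pixel sizes are micrometres, matching how they are reported).
Voxel ``i`` of an axis covers the physical interval ``[i*s, (i+1)*s)`` and
its centre sits at ``(i + 0.5)*s`` for spacing ``s``; the affine maps index
coordinates to those centres.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

__all__ = [
    "Volume",
    "LabelVolume",
    "DisplacementField",
    "SectionImage",
    "check_aligned",
]


def _default_affine(spacing: float) -> np.ndarray:
    aff = np.diag([spacing, spacing, spacing, 1.0])
    aff[:3, 3] = 0.5 * spacing
    return aff


@dataclass
class Volume:
    """A 3D scalar grid with isotropic spacing (mm) and an index->mm affine."""

    values: np.ndarray
    spacing: float
    affine: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        if self.values.ndim != 3:
            raise ValueError(f"Volume requires a 3D array, got shape {self.values.shape}")
        if not np.isfinite(self.values).all():
            raise ValueError("Volume values must be finite")
        if not (self.spacing > 0):
            raise ValueError(f"spacing must be positive, got {self.spacing}")
        if self.affine is None:
            self.affine = _default_affine(self.spacing)
        else:
            self.affine = np.asarray(self.affine, dtype=float)
            if self.affine.shape != (4, 4):
                raise ValueError("affine must be 4x4")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.values.shape  # type: ignore[return-value]

    @property
    def voxel_volume(self) -> float:
        """Volume of one voxel in mm^3."""
        return float(self.spacing) ** 3


@dataclass
class LabelVolume:
    """Integer ROI atlas aligned to a :class:`Volume`.

    ``name_map`` maps ROI names to one or more label ids; union ROIs (such
    as a ventricular system compiled from its four components) are simply
    names mapping to several ids.  Label 0 is background.
    """

    labels: np.ndarray
    spacing: float
    name_map: Mapping[str, tuple[int, ...]] = field(default_factory=dict)
    affine: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        if self.labels.ndim != 3:
            raise ValueError("LabelVolume requires a 3D array")
        if not np.issubdtype(self.labels.dtype, np.integer):
            raise ValueError("labels must be an integer array")
        if self.labels.min() < 0:
            raise ValueError("label ids must be >= 0 (0 = background)")
        if not (self.spacing > 0):
            raise ValueError("spacing must be positive")
        if self.affine is None:
            self.affine = _default_affine(self.spacing)
        self.name_map = {k: tuple(int(i) for i in np.atleast_1d(v)) for k, v in self.name_map.items()}

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.labels.shape  # type: ignore[return-value]

    def roi_ids(self, roi: str | int | Sequence[int]) -> tuple[int, ...]:
        """Resolve an ROI name, id, or id collection to a tuple of label ids."""
        if isinstance(roi, str):
            if roi not in self.name_map:
                raise KeyError(
                    f"unknown ROI {roi!r}; available: {sorted(self.name_map)}"
                )
            return self.name_map[roi]
        if isinstance(roi, (int, np.integer)):
            return (int(roi),)
        return tuple(int(i) for i in roi)


@dataclass
class DisplacementField:
    """Per-voxel displacement 3-vectors (mm) on a regular grid.

    The convention is forward: ``x_common = x_subject + u(x_subject)``, so a
    Jacobian determinant of ``det(I + grad u) > 1`` means the subject is
    locally larger than the common space (local expansion).
    """

    vectors: np.ndarray
    spacing: float
    affine: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.vectors = np.asarray(self.vectors, dtype=float)
        if self.vectors.ndim != 4 or self.vectors.shape[-1] != 3:
            raise ValueError(
                f"DisplacementField requires shape (nx, ny, nz, 3), got {self.vectors.shape}"
            )
        if not np.isfinite(self.vectors).all():
            raise ValueError("displacement vectors must be finite")
        if not (self.spacing > 0):
            raise ValueError("spacing must be positive")
        if self.affine is None:
            self.affine = _default_affine(self.spacing)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.vectors.shape[:3]  # type: ignore[return-value]


@dataclass
class SectionImage:
    """2D multi-channel fluorescence section with a physical pixel size (µm)."""

    channels: np.ndarray  # (H, W, C) or (H, W)
    pixel_size_um: float
    tissue_mask: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.channels = np.asarray(self.channels)
        if self.channels.ndim == 2:
            self.channels = self.channels[:, :, None]
        if self.channels.ndim != 3:
            raise ValueError("channels must be (H, W) or (H, W, C)")
        if not (self.pixel_size_um > 0):
            raise ValueError("pixel_size_um must be positive")
        if self.tissue_mask is not None:
            self.tissue_mask = np.asarray(self.tissue_mask, dtype=bool)
            if self.tissue_mask.shape != self.channels.shape[:2]:
                raise ValueError("tissue_mask must match the image grid")

    @property
    def shape(self) -> tuple[int, int]:
        return self.channels.shape[:2]  # type: ignore[return-value]

    def channel(self, index: int) -> np.ndarray:
        return self.channels[:, :, index]

    @property
    def area_mm2(self) -> float:
        """Physical area of the full image frame in mm^2."""
        h, w = self.shape
        return h * w * (self.pixel_size_um / 1000.0) ** 2


def check_aligned(*grids: Volume | LabelVolume | DisplacementField) -> None:
    """Raise if the given grids do not share shape and spacing."""
    ref = grids[0]
    for g in grids[1:]:
        if g.shape != ref.shape:
            raise ValueError(f"grid shapes differ: {g.shape} vs {ref.shape}")
        if not np.isclose(g.spacing, ref.spacing):
            raise ValueError(f"grid spacings differ: {g.spacing} vs {ref.spacing}")
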