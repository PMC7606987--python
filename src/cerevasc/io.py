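"""File interchange: NIfTI volumes and fields, TIFF sections, YAML configs.

Volumes and label volumes round-trip bitwise through NIfTI (.nii or
.nii.gz); displacement fields are stored as 4D NIfTI with the vector
component last, in mm.  Section images go to RGB TIFF with the pixel size
in the resolution tags and a YAML sidecar.  ROI name maps and pipeline
configs are YAML.
"""

from __future__ import annotations

from pathlib import Path

import nibabel as nib
import numpy as np
import tifffile
import yaml

from cerevasc.grids import DisplacementField, LabelVolume, SectionImage, Volume

__all__ = [
    "load_volume",
    "save_volume",
    "load_labels",
    "save_labels",
    "load_displacement",
    "save_displacement",
    "load_section",
    "save_section",
    "load_config",
    "save_config",
    "save_mip_png",
    "require_isotropic",
]


def _spacing_from_nifti(img: nib.Nifti1Image) -> tuple[float, np.ndarray]:
    zooms = img.header.get_zooms()[:3]
    return float(zooms[0]), np.asarray(img.affine)


def require_isotropic(path_or_img, tol: float = 1e-4) -> None:
    """Reject anisotropic voxel grids (the aCBV statistic assumes cubes)."""
    img = nib.load(str(path_or_img)) if not isinstance(path_or_img, nib.Nifti1Image) else path_or_img
    zooms = np.asarray(img.header.get_zooms()[:3], dtype=float)
    if np.ptp(zooms) > tol * zooms.mean():
        raise ValueError(f"anisotropic voxels {tuple(zooms)}; isotropic spacing required")


def load_volume(path: str | Path) -> Volume:
    img = nib.load(str(path))
    require_isotropic(img)
    spacing, affine = _spacing_from_nifti(img)
    return Volume(values=np.asarray(img.dataobj, dtype=float), spacing=spacing, affine=affine)


def save_volume(volume: Volume, path: str | Path) -> None:
    affine = volume.affine if volume.affine is not None else np.diag([volume.spacing] * 3 + [1.0])
    img = nib.Nifti1Image(np.asarray(volume.values, dtype=np.float64), affine)
    img.header.set_zooms((volume.spacing,) * 3)
    nib.save(img, str(path))


def load_labels(path: str | Path, name_map_path: str | Path | None = None) -> LabelVolume:
    img = nib.load(str(path))
    require_isotropic(img)
    spacing, affine = _spacing_from_nifti(img)
    name_map = {}
    if name_map_path is not None:
        with open(name_map_path) as fh:
            raw = yaml.safe_load(fh)
        name_map = {str(k): tuple(np.atleast_1d(v).astype(int)) for k, v in raw.items()}
    return LabelVolume(
        labels=np.asarray(img.dataobj).astype(np.int32),
        spacing=spacing,
        name_map=name_map,
        affine=affine,
    )


def save_labels(labels: LabelVolume, path: str | Path, name_map_path: str | Path | None = None) -> None:
    affine = labels.affine if labels.affine is not None else np.diag([labels.spacing] * 3 + [1.0])
    img = nib.Nifti1Image(np.asarray(labels.labels, dtype=np.int32), affine)
    img.header.set_zooms((labels.spacing,) * 3)
    nib.save(img, str(path))
    if name_map_path is not None:
        with open(name_map_path, "w") as fh:
            yaml.safe_dump({k: list(v) for k, v in labels.name_map.items()}, fh)


def load_displacement(path: str | Path) -> DisplacementField:
    img = nib.load(str(path))
    data = np.asarray(img.dataobj, dtype=float)
    if data.ndim == 5:  # NIfTI vector convention (x, y, z, 1, 3)
        data = data[:, :, :, 0, :]
    spacing = float(img.header.get_zooms()[0])
    return DisplacementField(vectors=data, spacing=spacing, affine=np.asarray(img.affine))


def save_displacement(field: DisplacementField, path: str | Path) -> None:
    affine = field.affine if field.affine is not None else np.diag([field.spacing] * 3 + [1.0])
    img = nib.Nifti1Image(np.asarray(field.vectors, dtype=np.float64), affine)
    img.header.set_zooms((field.spacing,) * 3 + (1.0,))
    img.header["intent_code"] = 1007  # NIFTI_INTENT_VECTOR, components in mm
    nib.save(img, str(path))


def save_section(section: SectionImage, path: str | Path) -> None:
    """Write an RGB TIFF with the pixel size in the resolution tags + sidecar."""
    path = Path(path)
    px_per_cm = 10000.0 / section.pixel_size_um
    tifffile.imwrite(
        path,
        np.asarray(section.channels, dtype=np.float32),
        photometric="rgb" if section.channels.shape[-1] == 3 else "minisblack",
        resolution=(px_per_cm, px_per_cm),
        resolutionunit="CENTIMETER",
    )
    with open(path.with_suffix(path.suffix + ".yaml"), "w") as fh:
        yaml.safe_dump({"pixel_size_um": float(section.pixel_size_um)}, fh)


def load_section(path: str | Path, pixel_size_um: float | None = None) -> SectionImage:
    """Read a TIFF section; pixel size from the sidecar, tags, or argument."""
    path = Path(path)
    data = tifffile.imread(path)
    if pixel_size_um is None:
        sidecar = path.with_suffix(path.suffix + ".yaml")
        if sidecar.exists():
            with open(sidecar) as fh:
                pixel_size_um = float(yaml.safe_load(fh)["pixel_size_um"])
        else:
            with tifffile.TiffFile(path) as tf:
                page = tf.pages[0]
                res = page.tags.get("XResolution")
                unit = page.tags.get("ResolutionUnit")
                if res is not None and unit is not None and unit.value == 3:
                    num, den = res.value
                    pixel_size_um = 10000.0 / (num / den)
    if pixel_size_um is None:
        raise ValueError("pixel size not recoverable; pass pixel_size_um explicitly")
    return SectionImage(channels=np.asarray(data, dtype=float), pixel_size_um=pixel_size_um)


def save_mip_png(mip_image, path: str | Path, cmap: str = "gray") -> None:
    """Render a 2D maximum-intensity projection to PNG."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    arr = np.asarray(mip_image, dtype=float)
    finite = np.isfinite(arr)
    vmin = arr[finite].min() if finite.any() else 0.0
    arr = np.where(finite, arr, vmin)
    fig, ax = plt.subplots(figsize=(4, 4), dpi=150)
    ax.imshow(arr.T, cmap=cmap, origin="lower")
    ax.set_axis_off()
    fig.savefig(path, bbox_inches="tight", pad_inches=0)
    plt.close(fig)


def load_config(path: str | Path) -> dict:
    with open(path) as fh:
        return yaml.safe_load(fh)


def save_config(config: dict, path: str | Path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(config, fh, sort_keys=True)
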