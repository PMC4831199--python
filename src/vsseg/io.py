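"""Volume and label-map containers plus NIfTI / NRRD round-tripping.

A :class:`VolumeImage` is a plain 3-D scalar grid with voxel spacing in mm
and opaque orientation metadata (a NIfTI affine, or the SimpleITK
origin/direction pair for NRRD) that is carried from input to output
untouched.  All internal computation is 0-based voxel-index space; spacing
only enters physically meaningful outputs (Hausdorff distances).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .errors import FormatError, GeometryError

__all__ = ["VolumeImage", "SeedLabelMap", "read_volume", "write_volume",
           "read_seed_map"]


@dataclass
class VolumeImage:
    """3-D scalar image with physical voxel spacing.

    Parameters
    ----------
    data : (nx, ny, nz) float array
    spacing : 3-vector of positive voxel sizes in mm
    meta : opaque geometry metadata (kept for writing)
    """

    data: np.ndarray
    spacing: np.ndarray = field(default_factory=lambda: np.ones(3))
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=np.float64)
        if self.data.ndim != 3 or self.data.size == 0:
            raise GeometryError("VolumeImage requires a non-empty 3-D grid")
        self.spacing = np.asarray(self.spacing, dtype=np.float64)
        if self.spacing.shape != (3,) or np.any(self.spacing <= 0):
            raise GeometryError("spacing must be three positive values")

    @property
    def shape(self):
        return self.data.shape


@dataclass
class SeedLabelMap:
    """Integer label grid aligned with an image: 0 unlabeled, 1 fg, 2 bg."""

    labels: np.ndarray

    def __post_init__(self):
        self.labels = np.asarray(self.labels)
        if self.labels.ndim != 3:
            raise GeometryError("seed label map must be 3-D")
        codes = np.unique(self.labels)
        if not np.isin(codes, (0, 1, 2)).all():
            raise GeometryError(f"seed codes must be in {{0,1,2}}, got {codes}")
        self.labels = self.labels.astype(np.uint8)

    def check_geometry(self, image: VolumeImage) -> None:
        if self.labels.shape != image.data.shape:
            raise GeometryError(
                f"seed map shape {self.labels.shape} does not match image "
                f"shape {image.data.shape}")

    @property
    def foreground(self) -> np.ndarray:
        return self.labels == 1

    @property
    def background(self) -> np.ndarray:
        return self.labels == 2


def _is_nifti(path: str) -> bool:
    return path.endswith(".nii") or path.endswith(".nii.gz")


def read_volume(path) -> VolumeImage:
    """Read a 3-D NIfTI (.nii/.nii.gz) or NRRD (.nrrd) volume."""
    path = str(path)
    if not Path(path).exists():
        raise FormatError(f"no such file: {path}")
    if _is_nifti(path):
        import nibabel as nib
        try:
            img = nib.load(path)
            data = np.asanyarray(img.dataobj)
        except Exception as exc:  # corrupt header etc.
            raise FormatError(f"cannot read NIfTI file {path}: {exc}") from exc
        if data.ndim == 4 and data.shape[3] == 1:
            data = data[..., 0]
        if data.ndim != 3:
            raise FormatError(
                f"{path}: only 3-D volumes are supported, got {data.ndim}-D")
        spacing = np.asarray(img.header.get_zooms()[:3], dtype=np.float64)
        return VolumeImage(data=np.asarray(data, dtype=np.float64),
                           spacing=spacing,
                           meta={"format": "nifti", "affine": img.affine.copy()})
    if path.endswith(".nrrd"):
        import SimpleITK as sitk
        try:
            img = sitk.ReadImage(path)
        except Exception as exc:
            raise FormatError(f"cannot read NRRD file {path}: {exc}") from exc
        if img.GetDimension() != 3:
            raise FormatError(
                f"{path}: only 3-D volumes are supported, "
                f"got {img.GetDimension()}-D")
        # SimpleITK arrays come back (z, y, x); transpose to (x, y, z)
        data = sitk.GetArrayFromImage(img).transpose(2, 1, 0)
        return VolumeImage(
            data=np.asarray(data, dtype=np.float64),
            spacing=np.asarray(img.GetSpacing(), dtype=np.float64),
            meta={"format": "nrrd", "origin": img.GetOrigin(),
                  "direction": img.GetDirection()})
    raise FormatError(f"unsupported volume format: {path}")


def write_volume(image: VolumeImage, path, dtype=None) -> None:
    """Write a VolumeImage, preserving the metadata it was read with."""
    path = str(path)
    data = image.data if dtype is None else image.data.astype(dtype)
    if _is_nifti(path):
        import nibabel as nib
        affine = image.meta.get("affine")
        if affine is None:
            affine = np.diag(list(image.spacing) + [1.0])
        out = nib.Nifti1Image(data, affine)
        out.header.set_zooms(tuple(image.spacing))
        nib.save(out, path)
        return
    if path.endswith(".nrrd"):
        import SimpleITK as sitk
        img = sitk.GetImageFromArray(np.ascontiguousarray(data.transpose(2, 1, 0)))
        img.SetSpacing(tuple(float(s) for s in image.spacing))
        if "origin" in image.meta:
            img.SetOrigin(image.meta["origin"])
        if "direction" in image.meta:
            img.SetDirection(image.meta["direction"])
        sitk.WriteImage(img, path)
        return
    raise FormatError(f"unsupported volume format: {path}")


def read_seed_map(path, image: VolumeImage) -> SeedLabelMap:
    """Read a seed label volume and check it against the image geometry."""
    vol = read_volume(path)
    seeds = SeedLabelMap(np.rint(vol.data).astype(np.int64))
    seeds.check_geometry(image)
    return seeds
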