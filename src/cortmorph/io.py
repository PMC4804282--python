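"""Volume containers and file I/O.

The pipeline's unit of data is a 3D grey-value volume with isotropic voxels.
Arrays are indexed ``(z, y, x)`` with z the anatomical (bone) axis; physical
coordinates are ``(x, y, z)`` in micrometres with the origin at voxel
``(0, 0, 0)`` (position = index * voxel_size_um).

Supported formats: TIFF stacks (via tifffile), NIfTI (via nibabel, zooms
stored in mm per the format convention) and MHD/RAW (via SimpleITK).
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import numpy as np


@dataclass
class ImageVolume:
    """A 3D scalar volume with isotropic voxel size in micrometres."""

    data: np.ndarray
    voxel_size_um: float

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise ValueError(f"expected a 3D volume, got ndim={self.data.ndim}")
        if self.voxel_size_um <= 0:
            raise ValueError("voxel_size_um must be positive")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape  # type: ignore[return-value]

    def physical_center_um(self) -> np.ndarray:
        """Physical (x, y, z) coordinate of the grid centre in micrometres."""
        nz, ny, nx = self.data.shape
        return np.array([nx - 1, ny - 1, nz - 1], dtype=float) / 2.0 * self.voxel_size_um

    def copy(self) -> "ImageVolume":
        return ImageVolume(self.data.copy(), self.voxel_size_um)


@dataclass
class RegionLabelVolume:
    """Voxel labels: 0 background, 1 endocortical bone, 2 periosteal bone."""

    labels: np.ndarray
    voxel_size_um: float
    provenance: dict = field(default_factory=dict)

    BACKGROUND = 0
    ENDOCORTICAL = 1
    PERIOSTEAL = 2

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=np.uint8)
        if self.labels.ndim != 3:
            raise ValueError("labels must be a 3D volume")

    @property
    def bone_mask(self) -> np.ndarray:
        return self.labels > 0

    @property
    def endocortical(self) -> np.ndarray:
        return self.labels == self.ENDOCORTICAL

    @property
    def periosteal(self) -> np.ndarray:
        return self.labels == self.PERIOSTEAL


def read_volume(path: str, voxel_size_um: float | None = None) -> ImageVolume:
    """Read a volume from TIFF stack, NIfTI, or MHD/RAW.

    ``voxel_size_um`` overrides (TIFF) or cross-checks (NIfTI/MHD) the voxel
    size stored in the file; TIFF carries no reliable spacing so it is
    required there.
    """
    lower = path.lower()
    if lower.endswith((".tif", ".tiff")):
        import tifffile

        data = tifffile.imread(path)
        if voxel_size_um is None:
            raise ValueError("voxel_size_um is required when reading TIFF")
        return ImageVolume(np.asarray(data), voxel_size_um)
    if lower.endswith((".nii", ".nii.gz")):
        import nibabel as nib

        img = nib.load(path)
        data = np.asarray(img.dataobj)
        # nibabel stores (x, y, z); convert to (z, y, x) and zooms from mm.
        data = np.transpose(data, (2, 1, 0))
        vs = float(img.header.get_zooms()[0]) * 1000.0
        if voxel_size_um is not None:
            vs = voxel_size_um
        return ImageVolume(data, vs)
    if lower.endswith(".mhd"):
        import SimpleITK as sitk

        img = sitk.ReadImage(path)
        data = sitk.GetArrayFromImage(img)  # (z, y, x)
        vs = float(img.GetSpacing()[0])
        if voxel_size_um is not None:
            vs = voxel_size_um
        return ImageVolume(data, vs)
    raise ValueError(f"unsupported volume format: {path}")


def write_volume(volume: ImageVolume, path: str) -> None:
    """Write a volume as TIFF stack, NIfTI, or MHD/RAW (by extension)."""
    lower = path.lower()
    os.makedirs(os.path.dirname(os.path.abspath(path)), exist_ok=True)
    if lower.endswith((".tif", ".tiff")):
        import tifffile

        tifffile.imwrite(path, np.asarray(volume.data))
        return
    if lower.endswith((".nii", ".nii.gz")):
        import nibabel as nib

        vs_mm = volume.voxel_size_um / 1000.0
        affine = np.diag([vs_mm, vs_mm, vs_mm, 1.0])
        img = nib.Nifti1Image(np.transpose(volume.data, (2, 1, 0)), affine)
        img.header.set_zooms((vs_mm, vs_mm, vs_mm))
        nib.save(img, path)
        return
    if lower.endswith(".mhd"):
        import SimpleITK as sitk

        img = sitk.GetImageFromArray(np.asarray(volume.data))
        img.SetSpacing((volume.voxel_size_um,) * 3)
        sitk.WriteImage(img, path)
        return
    raise ValueError(f"unsupported volume format: {path}")


def write_label_volume(labels: np.ndarray, voxel_size_um: float, path: str,
                       sidecar: dict | None = None) -> None:
    """Write an 8-bit label volume plus an optional plain-text sidecar."""
    write_volume(ImageVolume(np.asarray(labels, dtype=np.uint8), voxel_size_um), path)
    if sidecar:
        base, _ = os.path.splitext(path)
        with open(base + ".txt", "w") as fh:
            for key, value in sidecar.items():
                fh.write(f"{key} = {value}\n")
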