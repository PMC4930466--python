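"""3D binary organ masks with physical voxel spacing, and their file formats.

Array convention (stated once, used everywhere): masks are indexed
``(slice, row, col)`` with axis 0 running inferior -> superior through the
axial stack, axis 1 anterior -> posterior and axis 2 left -> right.
``voxel_spacing[i]`` is the physical extent in mm of one voxel along array
axis ``i`` (so ``voxel_spacing[0]`` is the slice thickness). Pixel indices are
0-based.
"""

from __future__ import annotations

from dataclasses import dataclass

import nibabel as nib
import numpy as np
import tifffile

from .errors import EmptySegmentationError, ParameterError

__all__ = ["VolumetricMask", "load_mask", "save_mask"]


@dataclass
class VolumetricMask:
    """A 3D binary segmentation with anisotropic voxel spacing in mm."""

    voxels: np.ndarray
    voxel_spacing: tuple[float, float, float]

    def __post_init__(self) -> None:
        self.voxels = np.asarray(self.voxels).astype(bool)
        if self.voxels.ndim != 3:
            raise ParameterError(f"mask must be 3D, got {self.voxels.ndim}D")
        self.voxel_spacing = tuple(float(s) for s in self.voxel_spacing)
        if len(self.voxel_spacing) != 3 or any(s <= 0 for s in self.voxel_spacing):
            raise ParameterError(
                f"voxel_spacing must be 3 positive mm values, got {self.voxel_spacing}"
            )

    @property
    def voxel_volume_mm3(self) -> float:
        s = self.voxel_spacing
        return s[0] * s[1] * s[2]

    @property
    def n_foreground(self) -> int:
        return int(self.voxels.sum())

    def require_nonempty(self) -> None:
        if not self.voxels.any():
            raise EmptySegmentationError("mask has no foreground voxels")


def save_mask(mask: VolumetricMask, path: str) -> None:
    """Write a mask as NIfTI (.nii/.nii.gz) or multi-page TIFF (.tif/.tiff).

    NIfTI stores the spacing in the affine/zooms; TIFF uses ImageJ-style
    metadata (page resolution for in-plane spacing, ``spacing`` for slice
    thickness).
    """
    path = str(path)
    if path.endswith((".nii", ".nii.gz")):
        # nibabel expects (x, y, z) fastest-varying first; store array axes
        # as-is and record per-axis spacing in the affine diagonal.
        affine = np.diag([*mask.voxel_spacing, 1.0])
        img = nib.Nifti1Image(mask.voxels.astype(np.uint8), affine)
        img.header.set_zooms(mask.voxel_spacing)
        nib.save(img, path)
    elif path.endswith((".tif", ".tiff")):
        s0, s1, s2 = mask.voxel_spacing
        tifffile.imwrite(
            path,
            mask.voxels.astype(np.uint8),
            imagej=True,
            resolution=(1.0 / s2, 1.0 / s1),
            metadata={"spacing": s0, "unit": "mm", "axes": "ZYX"},
        )
    else:
        raise ParameterError(f"unsupported mask format: {path}")


def load_mask(path: str) -> VolumetricMask:
    """Read a mask written by :func:`save_mask` (NIfTI or ImageJ TIFF)."""
    path = str(path)
    if path.endswith((".nii", ".nii.gz")):
        img = nib.load(path)
        data = np.asanyarray(img.dataobj)
        zooms = img.header.get_zooms()[:3]
        return VolumetricMask(data > 0, tuple(float(z) for z in zooms))
    if path.endswith((".tif", ".tiff")):
        with tifffile.TiffFile(path) as tf:
            data = tf.asarray()
            meta = tf.imagej_metadata or {}
            s0 = float(meta.get("spacing", 1.0))
            page = tf.pages[0]
            res = page.tags.get("XResolution")
            s2 = float(res.value[1]) / float(res.value[0]) if res else 1.0
            res = page.tags.get("YResolution")
            s1 = float(res.value[1]) / float(res.value[0]) if res else 1.0
        if data.ndim == 2:
            data = data[None]
        return VolumetricMask(data > 0, (s0, s1, s2))
    raise ParameterError(f"unsupported mask format: {path}")
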