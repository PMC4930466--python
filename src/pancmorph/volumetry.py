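"""Organ volume from per-slice ROIs or 3D masks, and the BMI-normalised volume index.

Volume follows the slice-summation rule used for manual MRI planimetry: the
delineated area on each axial slice is multiplied by the slice thickness and
the products summed. With a voxelised mask this is exactly
(foreground-voxel count) x (voxel volume).

Polygon ROIs live in continuous pixel coordinates, ``(row, col)`` order, where
pixel ``(r, c)`` occupies the unit square ``[r, r+1) x [c, c+1)`` and has its
center at ``(r + 0.5, c + 0.5)``. A pixel belongs to an ROI iff its center
lies strictly inside the polygon; several polygons on one slice are unioned.
This center-inclusion rule makes ROI fixtures bit-reproducible: an
axis-aligned square with vertices (0,0)...(10,10) rasterises to exactly
10 x 10 pixels.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np
import shapely

from .errors import EmptySegmentationError, GeometryError, ParameterError
from .mask import VolumetricMask

__all__ = [
    "SliceROISet",
    "VolumeResult",
    "mask_from_rois",
    "compute_volume",
    "pancreas_volume_index",
    "load_roi_json",
]


def _as_closed_polygon(vertices) -> np.ndarray:
    """Validate one polygon: >= 3 distinct vertices, closure implied, simple."""
    v = np.asarray(vertices, dtype=float)
    if v.ndim != 2 or v.shape[1] != 2:
        raise GeometryError("polygon vertices must be an (n, 2) array of (row, col)")
    if len(v) >= 2 and np.allclose(v[0], v[-1]):
        v = v[:-1]  # explicit closure -> drop duplicate
    if len(v) < 3:
        raise GeometryError("polygon needs at least 3 distinct vertices")
    poly = shapely.Polygon(v)
    if not poly.is_valid:
        raise GeometryError(f"invalid (self-intersecting?) polygon: {shapely.is_valid_reason(poly)}")
    return v


@dataclass
class SliceROISet:
    """Per-slice polygon ROIs, the file-level stand-in for manual delineation.

    ``slices`` maps strictly increasing slice indices to lists of closed
    polygons (closure may be explicit or implied).
    """

    slices: list[tuple[int, list[np.ndarray]]]
    pixel_spacing: tuple[float, float]
    slice_thickness: float

    def __post_init__(self) -> None:
        self.pixel_spacing = tuple(float(s) for s in self.pixel_spacing)
        if len(self.pixel_spacing) != 2 or any(s <= 0 for s in self.pixel_spacing):
            raise ParameterError("pixel_spacing must be 2 positive mm values")
        if self.slice_thickness <= 0:
            raise ParameterError("slice_thickness must be positive")
        idx = [int(i) for i, _ in self.slices]
        if any(b <= a for a, b in zip(idx, idx[1:])):
            raise GeometryError("slice indices must be strictly increasing")
        if any(i < 0 for i in idx):
            raise GeometryError("slice indices must be non-negative")
        self.slices = [
            (int(i), [_as_closed_polygon(p) for p in polys]) for i, polys in self.slices
        ]


def load_roi_json(path: str) -> SliceROISet:
    """Read the documented ROI JSON schema::

        {"pixel_spacing_mm": [r, c], "slice_thickness_mm": t,
         "slices": [{"index": 0, "polygons": [[[r0,c0],[r1,c1],...], ...]}, ...]}
    """
    with open(path) as fh:
        doc = json.load(fh)
    return SliceROISet(
        slices=[(s["index"], [np.asarray(p) for p in s["polygons"]]) for s in doc["slices"]],
        pixel_spacing=tuple(doc["pixel_spacing_mm"]),
        slice_thickness=doc["slice_thickness_mm"],
    )


def rasterize_polygons(polygons, grid_shape: tuple[int, int]) -> np.ndarray:
    """Union of polygon interiors on a pixel grid by the center-inclusion rule."""
    out = np.zeros(grid_shape, dtype=bool)
    if not polygons:
        return out
    rr, cc = np.mgrid[0 : grid_shape[0], 0 : grid_shape[1]]
    centers_r = rr.ravel() + 0.5
    centers_c = cc.ravel() + 0.5
    for v in polygons:
        poly = shapely.Polygon(v)
        inside = shapely.contains_xy(poly, centers_r, centers_c)
        out |= inside.reshape(grid_shape)
    return out


def mask_from_rois(rois: SliceROISet, grid_shape: tuple[int, int]) -> VolumetricMask:
    """Rasterise per-slice polygon ROIs into a :class:`VolumetricMask`.

    The stack spans slices 0..max(index); slices without ROIs are background.
    """
    grid_shape = tuple(int(g) for g in grid_shape)
    if len(grid_shape) != 2 or any(g <= 0 for g in grid_shape):
        raise ParameterError("grid_shape must be 2 positive integers")
    for idx, polys in rois.slices:
        for v in polys:
            if (v < 0).any() or (v[:, 0] > grid_shape[0]).any() or (v[:, 1] > grid_shape[1]).any():
                raise GeometryError(f"polygon vertex outside grid bounds on slice {idx}")
    n_slices = max((i for i, _ in rois.slices), default=-1) + 1
    vox = np.zeros((max(n_slices, 1), *grid_shape), dtype=bool)
    for idx, polys in rois.slices:
        vox[idx] = rasterize_polygons(polys, grid_shape)
    return VolumetricMask(vox, (rois.slice_thickness, *rois.pixel_spacing))


@dataclass
class VolumeResult:
    """Slice-summation volume with per-slice provenance."""

    volume_cm3: float
    per_slice_areas_mm2: list[float]
    n_slices_with_roi: int


def compute_volume(mask: VolumetricMask) -> VolumeResult:
    """Slice-summation volumetry: per-slice area x slice thickness, summed.

    Raises :class:`EmptySegmentationError` on an all-background mask — an
    absent organ is a data problem, not a 0 cm^3 measurement.
    """
    mask.require_nonempty()
    thickness, sr, sc = mask.voxel_spacing
    pixel_area = sr * sc
    counts = mask.voxels.sum(axis=(1, 2))
    areas = counts * pixel_area
    volume_mm3 = float(areas.sum() * thickness)
    return VolumeResult(
        volume_cm3=volume_mm3 / 1000.0,
        per_slice_areas_mm2=[float(a) for a in areas],
        n_slices_with_roi=int((counts > 0).sum()),
    )


def pancreas_volume_index(volume_cm3: float, bmi: float) -> float:
    """Pancreas volume normalised by BMI, in cm^3 m^2 kg^-1.

    Computed per individual; group aggregation of the per-individual ratios is
    the cohort-statistics layer's job.
    """
    if volume_cm3 <= 0:
        raise ParameterError(f"volume must be positive, got {volume_cm3}")
    if bmi <= 0:
        raise ParameterError(f"BMI must be positive, got {bmi}")
    return volume_cm3 / bmi
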