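"""Three-point Dixon water/fat separation and ROI-based fat percentages.

The forward model assumed for the echo triplet, with real non-negative water
(W) and fat (F) magnetisations and an off-resonance phase error phi accrued
per echo interval:

    echo1 (in-phase)      S1 = (W + F)
    echo2 (opposed-phase) S2 = (W - F) * exp(i*phi)
    echo3 (in-phase)      S3 = (W + F) * exp(2i*phi)

Separation estimates phi as half the phase of ``S3 * conj(S1)``, demodulates
the opposed-phase echo, averages the two in-phase echoes symmetrically, and
solves for W and F from the real parts. The fat fraction is
``FF = 100 * F / (W + F)``; negative W or F from noise are clamped to zero
and the clamp count reported. On magnitude-only input (real arrays) the phase
error is assumed zero and a warning is issued.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import shapely

from .errors import GeometryError, InputError, ParameterError

__all__ = [
    "DixonTriplet",
    "FatFractionMap",
    "CircularROI",
    "SubcutaneousBoundaryPair",
    "dixon_separate",
    "mean_ff_in_rois",
    "pancreas_fat_percent",
    "visceral_fat_percent",
    "suggest_uniform_rois",
]


@dataclass
class DixonTriplet:
    """Co-registered echo images; complex preferred, magnitude accepted."""

    in_phase: np.ndarray
    opposed_phase: np.ndarray
    third_echo: np.ndarray
    pixel_spacing: tuple[float, float] = (1.0, 1.0)

    def __post_init__(self) -> None:
        self.in_phase = np.asarray(self.in_phase)
        self.opposed_phase = np.asarray(self.opposed_phase)
        self.third_echo = np.asarray(self.third_echo)
        shapes = {self.in_phase.shape, self.opposed_phase.shape, self.third_echo.shape}
        if len(shapes) != 1:
            raise InputError(f"echo images must share dimensions, got {shapes}")
        if self.in_phase.ndim != 2:
            raise InputError("echo images must be 2D")
        self.pixel_spacing = tuple(float(s) for s in self.pixel_spacing)
        if any(s <= 0 for s in self.pixel_spacing):
            raise ParameterError("pixel_spacing must be positive")

    @property
    def is_magnitude_only(self) -> bool:
        return not any(
            np.iscomplexobj(e) for e in (self.in_phase, self.opposed_phase, self.third_echo)
        )


@dataclass
class FatFractionMap:
    """Per-pixel fat percentage in [0, 100]."""

    ff_percent: np.ndarray
    pixel_spacing: tuple[float, float] = (1.0, 1.0)
    n_clamped: int = 0


def dixon_separate(triplet: DixonTriplet) -> FatFractionMap:
    """Water/fat separation under the three-echo model in the module docstring.

    The phase-error map is recovered pixelwise from ``S3 * conj(S1)`` (valid
    for |phi| < pi/2 per echo interval, i.e. no unwrapping across that range);
    the estimator is invariant to a global intensity rescaling of all echoes.
    """
    if triplet.is_magnitude_only:
        warnings.warn(
            "magnitude-only echoes: assuming zero phase error", UserWarning, stacklevel=2
        )
        s1 = triplet.in_phase.astype(float)
        s2 = triplet.opposed_phase.astype(float)
        s3 = triplet.third_echo.astype(float)
        phasor = np.ones_like(s1, dtype=complex)
    else:
        s1 = triplet.in_phase.astype(complex)
        s2 = triplet.opposed_phase.astype(complex)
        s3 = triplet.third_echo.astype(complex)
        z = s3 * np.conj(s1)
        # half-angle via principal root; avoids explicit unwrapping
        phasor = np.exp(0.5j * np.angle(z))
    op_corr = s2 * np.conj(phasor)
    ip_avg = 0.5 * (s1 + s3 * np.conj(phasor) ** 2)
    water = 0.5 * np.real(ip_avg + op_corr)
    fat = 0.5 * np.real(ip_avg - op_corr)
    n_clamped = int((water < 0).sum() + (fat < 0).sum())
    water = np.maximum(water, 0.0)
    fat = np.maximum(fat, 0.0)
    total = water + fat
    with np.errstate(invalid="ignore", divide="ignore"):
        ff = np.where(total > 0, 100.0 * fat / np.where(total > 0, total, 1.0), 0.0)
    ff = np.clip(ff, 0.0, 100.0)
    return FatFractionMap(ff, triplet.pixel_spacing, n_clamped)


@dataclass
class CircularROI:
    """Disc ROI in continuous pixel coordinates (row, col), area in mm^2.

    The conventional sampling area for uniform-tissue fat readings is
    100 mm^2 (radius ~5.64 mm).
    """

    center: tuple[float, float]
    area_mm2: float = 100.0

    def __post_init__(self) -> None:
        if self.area_mm2 <= 0:
            raise ParameterError("ROI area must be positive")
        self.center = (float(self.center[0]), float(self.center[1]))

    @property
    def radius_mm(self) -> float:
        return float(np.sqrt(self.area_mm2 / np.pi))


def _roi_pixel_mask(roi: CircularROI, shape, spacing) -> np.ndarray:
    """Pixels whose centers fall inside the disc, distances in mm."""
    sr, sc = spacing
    r_mm = roi.radius_mm
    rr, cc = np.mgrid[0 : shape[0], 0 : shape[1]]
    dr = (rr + 0.5 - roi.center[0]) * sr
    dc = (cc + 0.5 - roi.center[1]) * sc
    return dr * dr + dc * dc <= r_mm * r_mm


def mean_ff_in_rois(ff: FatFractionMap, rois: list[CircularROI]) -> float:
    """Mean of per-ROI mean fat fractions (each ROI a pixel-center-in-disc set).

    Every ROI must lie fully inside the image and contain at least one pixel.
    """
    if not rois:
        raise ParameterError("need at least one ROI")
    img = np.asarray(ff.ff_percent, dtype=float)
    sr, sc = ff.pixel_spacing
    means = []
    for roi in rois:
        r_px_r = roi.radius_mm / sr
        r_px_c = roi.radius_mm / sc
        r0, c0 = roi.center
        if (
            r0 - r_px_r < 0
            or r0 + r_px_r > img.shape[0]
            or c0 - r_px_c < 0
            or c0 + r_px_c > img.shape[1]
        ):
            raise GeometryError(f"ROI at {roi.center} extends outside the image")
        sel = _roi_pixel_mask(roi, img.shape, ff.pixel_spacing)
        if not sel.any():
            raise GeometryError(f"ROI at {roi.center} contains no pixel centers")
        means.append(float(img[sel].mean()))
    return float(np.mean(means))


def pancreas_fat_percent(slice_means) -> float:
    """Average the two per-slice ROI means into the participant-level value.

    Exactly two slice means are required; a missing slice is an error, never a
    silent single-slice fallback.
    """
    vals = list(slice_means)
    if len(vals) != 2 or any(v is None or not np.isfinite(v) for v in vals):
        raise InputError(f"exactly 2 finite slice means required, got {vals}")
    return float(np.mean(vals))


@dataclass
class SubcutaneousBoundaryPair:
    """Outer and inner subcutaneous fat boundaries; inner strictly inside outer."""

    outer_polygon: np.ndarray
    inner_polygon: np.ndarray

    def __post_init__(self) -> None:
        self.outer_polygon = np.asarray(self.outer_polygon, dtype=float)
        self.inner_polygon = np.asarray(self.inner_polygon, dtype=float)
        outer = shapely.Polygon(self.outer_polygon)
        inner = shapely.Polygon(self.inner_polygon)
        if not (outer.is_valid and inner.is_valid):
            raise GeometryError("boundary polygons must be simple and valid")
        if not outer.contains(inner):
            raise GeometryError("inner boundary must lie strictly inside the outer boundary")


def visceral_fat_percent(fat_mask: np.ndarray, boundaries: SubcutaneousBoundaryPair) -> float:
    """Visceral fat share at L2-L3: fat inside the inner boundary over that
    plus fat between the boundaries (subcutaneous), as a percentage."""
    from .volumetry import rasterize_polygons

    fat = np.asarray(fat_mask, dtype=bool)
    outer = rasterize_polygons([boundaries.outer_polygon], fat.shape)
    inner = rasterize_polygons([boundaries.inner_polygon], fat.shape)
    visceral = int((fat & inner).sum())
    subcutaneous = int((fat & outer & ~inner).sum())
    if visceral + subcutaneous == 0:
        raise InputError("no fat pixels within the outer boundary")
    return 100.0 * visceral / (visceral + subcutaneous)


def suggest_uniform_rois(
    ff: FatFractionMap,
    organ_mask: np.ndarray,
    n_rois: int = 3,
    area_mm2: float = 100.0,
    min_separation_mm: float = 10.0,
) -> list[CircularROI]:
    """Convenience helper (beyond the manual workflow it stands in for):
    propose the lowest-variance discs of the given area inside an organ mask.

    ROI placement on real data is observer-driven; this helper exists only to
    automate tests and demos, scanning disc centers on the pixel grid and
    greedily picking minimal-variance discs separated by ``min_separation_mm``.
    """
    img = np.asarray(ff.ff_percent, dtype=float)
    organ = np.asarray(organ_mask, dtype=bool)
    sr, sc = ff.pixel_spacing
    radius_mm = float(np.sqrt(area_mm2 / np.pi))
    rk = max(int(np.ceil(radius_mm / sr)), 1)
    ck = max(int(np.ceil(radius_mm / sc)), 1)
    rr, cc = np.mgrid[-rk : rk + 1, -ck : ck + 1]
    disc = (rr * sr) ** 2 + (cc * sc) ** 2 <= radius_mm**2
    from scipy import ndimage

    npix = int(disc.sum())
    valid = ndimage.minimum_filter(organ.astype(np.uint8), footprint=disc, mode="constant") > 0
    if not valid.any():
        raise GeometryError("organ mask admits no disc of the requested area")
    mean = ndimage.convolve(img, disc / npix, mode="nearest")
    var = ndimage.convolve(img * img, disc / npix, mode="nearest") - mean**2
    var[~valid] = np.inf
    chosen: list[CircularROI] = []
    flat = np.argsort(var, axis=None)
    for idx in flat:
        if len(chosen) == n_rois:
            break
        r, c = np.unravel_index(idx, var.shape)
        if not np.isfinite(var[r, c]):
            break
        center = (r + 0.5, c + 0.5)
        far = all(
            np.hypot((center[0] - o.center[0]) * sr, (center[1] - o.center[1]) * sc)
            >= min_separation_mm
            for o in chosen
        )
        if far:
            chosen.append(CircularROI(center, area_mm2))
    if len(chosen) < n_rois:
        raise GeometryError(f"could only place {len(chosen)} of {n_rois} ROIs")
    return chosen
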