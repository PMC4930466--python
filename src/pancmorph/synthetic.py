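"""Synthetic inputs for every pipeline stage.

No imaging data ships with the package; instead this module generates

* serrated ellipsoid phantoms — a pancreas-sized organ whose border
  irregularity is controlled by a single amplitude knob, standing in for the
  serrated borders seen in disease;
* analytic fractal fixtures (line, circle, filled square, Koch curve) whose
  dimensions are known exactly, used to calibrate the box-counting estimator;
* three-point Dixon echo triplets with a known fat-fraction map;
* two-group / three-timepoint cohorts whose group moments reproduce the
  published summary table.

Everything is deterministic given its seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.interpolate import RegularGridInterpolator
from scipy.special import sph_harm_y_all
from scipy.stats import gamma as gamma_dist
from skimage.draw import circle_perimeter, line as draw_line

from .dixon import DixonTriplet, FatFractionMap
from .errors import ConstraintError, ParameterError, SizingError
from .fractal import BoundaryImage
from .mask import VolumetricMask
from .stats import GROUPS, TIMEPOINTS, ParticipantRecord

__all__ = [
    "PhantomSpec",
    "DixonPhantomSpec",
    "CohortSpec",
    "generate_organ_phantom",
    "generate_fractal_fixture",
    "koch_vertices",
    "generate_dixon_phantom",
    "generate_cohort",
    "table1_cohort_spec",
]


# --------------------------------------------------------------------------
# serrated organ phantom
# --------------------------------------------------------------------------


@dataclass
class PhantomSpec:
    """Ellipsoid organ phantom with a band-limited angular serration field.

    The surface is r(theta, phi) = r0(theta, phi) * (1 + a * s(theta, phi))
    where r0 is the ellipsoid radius along that direction, ``a`` the
    serration amplitude (fraction of local radius, < 1) and ``s`` a seeded
    zero-mean spherical-harmonic field of the requested dominant angular
    frequency, normalised to unit maximum amplitude. ``a = 0`` gives the
    exact digitised ellipsoid.
    """

    base_radii: tuple[float, float, float] = (30.0, 20.0, 15.0)  # mm, per array axis
    serration_amplitude: float = 0.2
    serration_frequency: int = 12
    voxel_spacing: tuple[float, float, float] = (0.25, 0.25, 0.25)  # mm
    grid_shape: tuple[int, int, int] = (344, 232, 176)
    seed: int = 0

    def __post_init__(self) -> None:
        self.base_radii = tuple(float(r) for r in self.base_radii)
        self.voxel_spacing = tuple(float(s) for s in self.voxel_spacing)
        self.grid_shape = tuple(int(g) for g in self.grid_shape)
        if any(r <= 0 for r in self.base_radii):
            raise ParameterError("base_radii must be positive")
        if any(s <= 0 for s in self.voxel_spacing):
            raise ParameterError("voxel_spacing must be positive")
        if any(g < 2 for g in self.grid_shape):
            raise ParameterError("grid_shape must be >= 2 along every axis")
        if not 0 <= self.serration_amplitude < 1:
            raise ParameterError("serration_amplitude must be in [0, 1)")
        if self.serration_frequency < 1:
            raise ParameterError("serration_frequency must be a positive integer")


_FIELD_MAX_DEGREE = 48  # resolvable on the lookup grid below


def _serration_field(frequency: int, seed: int) -> RegularGridInterpolator:
    """Seeded band-limited spherical-harmonic field on a (theta, phi) lookup
    grid, standardised to zero mean and unit max amplitude.

    Degrees span ``frequency`` to ``3 * frequency`` (capped) with power
    decaying as 1/degree, so the requested frequency dominates but the
    serrations carry structure across a range of scales — a narrow single
    degree produces scallops at one wavelength only, which the silhouette
    projection largely averages away.
    """
    rng = np.random.default_rng(seed)
    ell_min = int(frequency)
    ell_max = min(3 * ell_min, _FIELD_MAX_DEGREE)
    theta = np.linspace(0.0, np.pi, 181)
    phi = np.linspace(-np.pi, np.pi, 361)
    # Y_lm(theta, phi) = Y_lm(theta, 0) * exp(i m phi): evaluate the theta
    # part once per (l, m) and synthesise the azimuthal factor analytically.
    leg = sph_harm_y_all(ell_max, ell_max, theta, 0.0).real  # (l, m, theta)
    s = np.zeros((theta.size, phi.size))
    for m in range(ell_max + 1):
        c_cos = np.zeros(theta.size)
        c_sin = np.zeros(theta.size)
        for ell in range(max(ell_min, m), ell_max + 1):
            weight = ell_min / ell
            c_cos += weight * rng.standard_normal() * leg[ell, m]
            if m > 0:
                c_sin += weight * rng.standard_normal() * leg[ell, m]
        s += np.outer(c_cos, np.cos(m * phi)) - np.outer(c_sin, np.sin(m * phi))
    # area-weighted mean is analytically zero for l >= 1; remove residual
    w = np.sin(theta)[:, None] * np.ones_like(s)
    s -= (s * w).sum() / w.sum()
    # standardise to ~unit depth: 2.5-sigma clip then scale, so |s| <= 1 exactly
    # (containment bound) while typical serrations keep an O(1) fraction of
    # the amplitude knob rather than being diluted by a rare extreme
    rms = np.sqrt((s * s * w).sum() / w.sum())
    s = np.clip(s / (2.5 * rms), -1.0, 1.0)
    return RegularGridInterpolator((theta, phi), s, bounds_error=False, fill_value=None)


def generate_organ_phantom(spec: PhantomSpec) -> VolumetricMask:
    """Rasterise the perturbed ellipsoid: a voxel is foreground iff its center
    lies inside the surface. Deterministic given ``spec.seed``."""
    a = spec.serration_amplitude
    for i in range(3):
        half_extent = (spec.grid_shape[i] - 1) / 2.0 * spec.voxel_spacing[i]
        needed = spec.base_radii[i] * (1.0 + a)
        if needed > half_extent:
            raise SizingError(
                f"axis {i}: phantom extends to {needed:.1f} mm but grid half-extent "
                f"is {half_extent:.1f} mm"
            )
    coords = [
        ((np.arange(n) - (n - 1) / 2.0) * sp).astype(np.float32)
        for n, sp in zip(spec.grid_shape, spec.voxel_spacing)
    ]
    x0 = coords[0][:, None, None]
    x1 = coords[1][None, :, None]
    x2 = coords[2][None, None, :]
    # rho = r / r0(theta, phi): the ellipsoidal radial coordinate
    rho = np.sqrt(
        (x0 / spec.base_radii[0]) ** 2
        + (x1 / spec.base_radii[1]) ** 2
        + (x2 / spec.base_radii[2]) ** 2
    )
    if a == 0:
        return VolumetricMask(rho <= 1.0, spec.voxel_spacing)
    field = _serration_field(spec.serration_frequency, spec.seed)
    # |s| <= 1, so only the shell 1 - a < rho < 1 + a needs the angular field
    inside = rho <= 1.0 - a
    shell = (rho < 1.0 + a) & ~inside
    i0, i1, i2 = np.nonzero(shell)
    y0 = coords[0][i0]
    y1 = coords[1][i1]
    y2 = coords[2][i2]
    r = np.sqrt(y0**2 + y1**2 + y2**2)
    theta = np.arccos(np.clip(y0 / np.maximum(r, np.float32(1e-12)), -1.0, 1.0))
    phi = np.arctan2(y2, y1)
    s = field(np.stack([theta, phi], axis=-1))
    inside[i0, i1, i2] = rho[i0, i1, i2] <= 1.0 + a * s
    return VolumetricMask(inside, spec.voxel_spacing)


# --------------------------------------------------------------------------
# analytic fractal fixtures
# --------------------------------------------------------------------------


def koch_vertices(iterations: int) -> np.ndarray:
    """Vertices of the standard triadic Koch curve with unit-pixel smallest
    segments: base length 3**iterations, 4**iterations segments, returned as
    (n, 2) ``(x, y)`` with y >= 0 the peak direction."""
    if not 1 <= iterations <= 6:
        raise ParameterError("koch iterations must be in [1, 6]")
    pts = np.array([0.0 + 0.0j, float(3**iterations) + 0.0j])
    rot = np.exp(-1j * np.pi / 3.0)
    for _ in range(iterations):
        a = pts[:-1]
        b = pts[1:]
        d = (b - a) / 3.0
        new = np.empty(4 * a.size + 1, dtype=complex)
        new[0::4] = np.append(a, b[-1])
        new[1::4] = a + d
        new[2::4] = a + d + d * rot
        new[3::4] = a + 2 * d
        pts = new
    return np.column_stack([pts.real, -pts.imag])


def generate_fractal_fixture(kind: str, size: int = 512, iterations: int = 5) -> BoundaryImage:
    """Exact rasterisations of calibration standards with known dimension.

    ``line`` and ``circle`` have dimension 1, ``filled_square`` (analysed as
    a filled set) has dimension 2, and the Koch curve has Hausdorff dimension
    log 4 / log 3 ~ 1.2619. The canvas is ``size`` x ``size`` (the Koch
    canvas grows if the curve needs more room).
    """
    if size < 64:
        raise ParameterError("fixture size must be >= 64 pixels")
    if kind == "line":
        img = np.zeros((size, size), dtype=bool)
        img[size // 2, :] = True
    elif kind == "circle":
        img = np.zeros((size, size), dtype=bool)
        radius = size // 2 - 2
        rr, cc = circle_perimeter(size // 2, size // 2, radius)
        img[rr, cc] = True
    elif kind == "filled_square":
        img = np.ones((size, size), dtype=bool)
    elif kind == "koch":
        verts = koch_vertices(iterations)
        length = 3**iterations
        margin = 4
        height = int(np.ceil(verts[:, 1].max())) + 2 * margin
        canvas = max(size, length + 2 * margin, height)
        img = np.zeros((canvas, canvas), dtype=bool)
        row0 = canvas // 2 + int(verts[:, 1].max() // 2)
        col0 = (canvas - length) // 2
        rows = np.round(row0 - verts[:, 1]).astype(int)
        cols = np.round(col0 + verts[:, 0]).astype(int)
        for i in range(len(verts) - 1):
            rr, cc = draw_line(rows[i], cols[i], rows[i + 1], cols[i + 1])
            img[rr, cc] = True
    else:
        raise ParameterError(
            f"kind must be line, circle, filled_square or koch, got {kind!r}"
        )
    return BoundaryImage(img, source=f"fixture:{kind}")


# --------------------------------------------------------------------------
# Dixon phantom
# --------------------------------------------------------------------------


@dataclass
class DixonPhantomSpec:
    """Forward model for a three-echo Dixon acquisition with known truth.

    ``signal_intensity`` is the total (water + fat) magnetisation per pixel;
    the fat-fraction map partitions it. ``phase_error_map`` is the B0
    off-resonance phase (radians) accrued per echo interval; Gaussian noise
    of sd ``noise_sd`` is added independently to the real and imaginary
    channel of every echo.
    """

    fat_fraction_map: np.ndarray
    signal_intensity: float = 100.0
    phase_error_map: np.ndarray | float = 0.0
    noise_sd: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        self.fat_fraction_map = np.asarray(self.fat_fraction_map, dtype=float)
        if self.fat_fraction_map.ndim != 2:
            raise ParameterError("fat_fraction_map must be 2D")
        if (self.fat_fraction_map < 0).any() or (self.fat_fraction_map > 100).any():
            raise ParameterError("fat_fraction_map values must lie in [0, 100] %")
        if self.signal_intensity <= 0:
            raise ParameterError("signal_intensity must be positive")
        if self.noise_sd < 0:
            raise ParameterError("noise_sd must be >= 0")
        self.phase_error_map = np.broadcast_to(
            np.asarray(self.phase_error_map, dtype=float), self.fat_fraction_map.shape
        ).copy()


def generate_dixon_phantom(spec: DixonPhantomSpec) -> tuple[DixonTriplet, FatFractionMap]:
    """Simulate the echo triplet and return it with the ground-truth map."""
    ff = spec.fat_fraction_map / 100.0
    water = spec.signal_intensity * (1.0 - ff)
    fat = spec.signal_intensity * ff
    phase = np.exp(1j * spec.phase_error_map)
    e1 = (water + fat).astype(complex)
    e2 = (water - fat) * phase
    e3 = (water + fat) * phase**2
    if spec.noise_sd > 0:
        rng = np.random.default_rng(spec.seed)
        for e in (e1, e2, e3):
            e += rng.normal(0.0, spec.noise_sd, e.shape)
            e += 1j * rng.normal(0.0, spec.noise_sd, e.shape)
    triplet = DixonTriplet(e1, e2, e3)
    return triplet, FatFractionMap(spec.fat_fraction_map.copy(), triplet.pixel_spacing)


# --------------------------------------------------------------------------
# cohort generator
# --------------------------------------------------------------------------

# Published group summaries (mean, SEM) per (variable, group, timepoint);
# per-participant SDs are SEM * sqrt(n) with n = 12 responders / 17
# non-responders.
_TABLE1_SEM = {
    "weight_kg": {
        "responder": [(99.8, 3.2), (84.1, 3.1), (84.4, 3.2)],
        "non_responder": [(96.7, 3.9), (83.8, 3.4), (84.8, 3.7)],
    },
    "bmi": {
        "responder": [(34.0, 0.8), (28.6, 0.8), (28.7, 0.7)],
        "non_responder": [(34.4, 1.1), (29.8, 1.1), (30.2, 1.1)],
    },
    "fpg_mmol_l": {
        "responder": [(8.9, 0.7), (5.1, 0.2), (6.2, 0.3)],
        "non_responder": [(13.2, 0.6), (8.5, 0.8), (9.4, 0.7)],
    },
    "insulin_pmol_l": {
        "responder": [(143.8, 23.6), (63.2, 7.6), (68.8, 16.0)],
        "non_responder": [(78.5, 18.1), (47.9, 8.3), (49.3, 7.0)],
    },
    "total_body_fat_pct": {
        "responder": [(36.2, 1.9), (30.1, 2.0), (31.5, 1.9)],
        "non_responder": [(42.6, 2.2), (37.2, 2.0), (40.8, 2.5)],
    },
    "pancreas_fat_pct": {
        "responder": [(4.5, 0.3), (4.0, 0.3), (3.7, 0.3)],
        "non_responder": [(5.5, 0.8), (5.5, 0.7), (4.9, 0.6)],
    },
    "hba1c_mmol_mol": {
        "responder": [(54.5, 3.7), (39.8, 2.2), (41.4, 1.6)],
        "non_responder": [(68.1, 3.2), (62.8, 4.3), (61.7, 3.3)],
    },
    "triacylglycerol_mmol_l": {
        "responder": [(2.0, 0.3), (1.0, 0.1), (1.2, 0.1)],
        "non_responder": [(1.8, 0.4), (1.0, 0.1), (1.2, 0.2)],
    },
    "pancreas_volume_cm3": {
        "responder": [(52.0, 4.9), (51.9, 5.3), (51.4, 4.5)],
        "non_responder": [(39.7, 2.7), (41.4, 2.6), (41.3, 2.8)],
    },
    "fd": {
        "responder": [(1.143, 0.013), (1.169, 0.006), (1.130, 0.012)],
        "non_responder": [(1.175, 0.006), (1.176, 0.005), (1.167, 0.007)],
    },
}
_TABLE1_ATTR_SEM = {
    "age_years": {"responder": (52.0, 2.9), "non_responder": (59.9, 2.1)},
    "duration_years": {"responder": (3.8, 1.0), "non_responder": (9.8, 1.6)},
}
_TABLE1_SEX = {"responder": (8, 4), "non_responder": (7, 10)}  # (male, female)

FPG_CONSTRAINT_MMOL_L = 7.0
_RESAMPLE_CAP = 1000


@dataclass
class CohortSpec:
    """Two-group / three-timepoint cohort parameters as (mean, SD) per cell.

    ``variables[name][group]`` holds three ``(mean, sd)`` pairs, ordered
    baseline / week 8 / month 6; ``attributes`` are participant-constant.
    The week-8 fasting glucose carries the responder constraint (< 7 mmol/l
    for responders, >= 7 for non-responders).
    """

    n_responders: int = 12
    n_non_responders: int = 17
    variables: dict = field(default_factory=dict)
    attributes: dict = field(default_factory=dict)
    sex_counts: dict = field(default_factory=lambda: dict(_TABLE1_SEX))
    seed: int = 0
    exact_moments: bool = True

    def __post_init__(self) -> None:
        if self.n_responders < 2 or self.n_non_responders < 2:
            raise ParameterError("need at least 2 participants per group")
        for name, per_group in self.variables.items():
            for group, cells in per_group.items():
                for mean, sd in cells:
                    if sd < 0:
                        raise ParameterError(f"negative SD for {name}/{group}")
        for name, per_group in self.attributes.items():
            for group, (mean, sd) in per_group.items():
                if sd < 0:
                    raise ParameterError(f"negative SD for {name}/{group}")

    def group_n(self, group: str) -> int:
        return self.n_responders if group == "responder" else self.n_non_responders


def table1_cohort_spec(seed: int = 0, n_responders: int = 12, n_non_responders: int = 17,
                       exact_moments: bool = True) -> CohortSpec:
    """The default study conditions: published group means with SDs rescaled
    from the printed SEMs to the requested group sizes' per-participant SDs
    (SD = SEM * sqrt(n) at the published n of 12/17)."""
    pub_n = {"responder": 12, "non_responder": 17}
    variables = {
        name: {
            g: [(m, sem * math.sqrt(pub_n[g])) for m, sem in cells]
            for g, cells in per_group.items()
        }
        for name, per_group in _TABLE1_SEM.items()
    }
    attributes = {
        name: {g: (m, sem * math.sqrt(pub_n[g])) for g, (m, sem) in per_group.items()}
        for name, per_group in _TABLE1_ATTR_SEM.items()
    }
    return CohortSpec(
        n_responders=n_responders,
        n_non_responders=n_non_responders,
        variables=variables,
        attributes=attributes,
        seed=seed,
        exact_moments=exact_moments,
    )


def _exact_normal(rng: np.random.Generator, n: int, mean: float, sd: float) -> np.ndarray:
    """Normal draw standardised to the exact sample mean and (n-1) SD, in the
    style of mvrnorm(empirical=TRUE)."""
    if sd == 0 or n < 2:
        return np.full(n, mean)
    z = rng.standard_normal(n)
    zs = z.std(ddof=1)
    if zs == 0:  # pragma: no cover - measure-zero degenerate draw
        return np.full(n, mean)
    z = (z - z.mean()) / zs
    return mean + sd * z


def _constrained_fpg(
    rng: np.random.Generator, n: int, mean: float, sd: float, group: str, exact: bool
) -> np.ndarray:
    """Week-8 fasting glucose honouring the responder rule.

    Default: a gamma distribution on the distance from the 7 mmol/l threshold,
    moment-matched to the requested mean and SD and drawn by shuffled
    stratified quantiles, so the constraint holds by construction and the
    sample mean tracks the target to O(1/n). ``exact=False`` falls back to
    iid normal draws resampled against the constraint (cap 1000 per
    participant).
    """
    thr = FPG_CONSTRAINT_MMOL_L
    sign = -1.0 if group == "responder" else 1.0  # responders sit below 7
    dist_mean = sign * (mean - thr)
    if dist_mean <= 0:
        raise ConstraintError(
            f"infeasible responder constraint: {group} week-8 FPG mean {mean} is on the "
            f"wrong side of {thr} mmol/l"
        )
    if sd == 0:
        return np.full(n, mean)
    if exact:
        shape = (dist_mean / sd) ** 2
        scale = sd**2 / dist_mean
        u = (np.arange(n) + 0.5) / n
        dist = gamma_dist.ppf(u, shape, scale=scale)
        rng.shuffle(dist)
        return thr + sign * dist
    out = np.empty(n)
    for i in range(n):
        for _ in range(_RESAMPLE_CAP):
            v = rng.normal(mean, sd)
            if (v < thr) if group == "responder" else (v >= thr):
                out[i] = v
                break
        else:
            raise ConstraintError(
                f"could not draw {group} week-8 FPG respecting the {thr} mmol/l rule in "
                f"{_RESAMPLE_CAP} attempts (mean {mean}, sd {sd})"
            )
    return out


def generate_cohort(spec: CohortSpec | None = None) -> list[ParticipantRecord]:
    """Simulate the cohort: one record per participant-timepoint.

    Deterministic given ``spec.seed``. Responder records always satisfy the
    strict week-8 glucose rule.
    """
    spec = spec if spec is not None else table1_cohort_spec()
    rng = np.random.default_rng(spec.seed)
    records: list[ParticipantRecord] = []
    for group, prefix in zip(GROUPS, ("R", "N")):
        n = spec.group_n(group)
        ids = [f"{prefix}{i + 1:02d}" for i in range(n)]
        draws: dict[tuple[str, str], np.ndarray] = {}
        for name, per_group in spec.variables.items():
            if group not in per_group:
                continue
            for tp, (mean, sd) in zip(TIMEPOINTS, per_group[group]):
                if name == "fpg_mmol_l" and tp == "week8":
                    draws[(name, tp)] = _constrained_fpg(
                        rng, n, mean, sd, group, spec.exact_moments
                    )
                elif spec.exact_moments:
                    draws[(name, tp)] = _exact_normal(rng, n, mean, sd)
                else:
                    draws[(name, tp)] = rng.normal(mean, sd, n)
        attrs: dict[str, np.ndarray] = {}
        for name, per_group in spec.attributes.items():
            if group in per_group:
                mean, sd = per_group[group]
                attrs[name] = (
                    _exact_normal(rng, n, mean, sd)
                    if spec.exact_moments
                    else rng.normal(mean, sd, n)
                )
        n_male = spec.sex_counts.get(group, (0, 0))[0]
        sexes = ["M" if i < n_male else "F" for i in range(n)]
        for i, pid in enumerate(ids):
            for tp in TIMEPOINTS:
                record = ParticipantRecord(
                    id=pid,
                    timepoint=tp,
                    group=group,
                    sex=sexes[i],
                    **{name: float(vec[i]) for (name, tp2), vec in draws.items() if tp2 == tp},
                    **{name: float(vec[i]) for name, vec in attrs.items()},
                )
                records.append(record)
    return records
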