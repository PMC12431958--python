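"""Synthetic bilateral breast phantoms for transmission microwave imaging.

Generates 2D relative-permittivity maps of compressed breasts in the four
mammographic-style views (LCC, RCC, LMLO, RMLO), with mammographic density
categories A-D (fatty to extremely dense), a small left/right asymmetry for
healthy subjects, and optional unilateral ellipsoidal tumor inclusions.

The model is deliberately simple: a semi-elliptical breast abutting the
chest-wall edge of the image, a homogeneous fat background in the 4-7
permittivity band, and glandular tissue laid down as a Gaussian-smoothed
random field thresholded to a target areal fraction, with per-pixel values
drawn from a density-dependent band.  Through-thickness homogeneity is
assumed, so the mid-plane map fully determines propagation delays.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np
from scipy import ndimage

from .grid import GridSpec

VIEWS = ("LCC", "RCC", "LMLO", "RMLO")
SIDES = ("L", "R")
DENSITY_CATEGORIES = ("A", "B", "C", "D")

#: fat background permittivity band (low end of region R1)
FAT_BAND = (4.0, 7.0)

#: glandular permittivity bands per mammographic density category, chosen so
#: the category modes fall in threshold regions R2 (B), R3 (C) and R4 (D)
DENSITY_BANDS = {
    "A": (8.0, 11.0),
    "B": (10.0, 14.0),
    "C": (13.0, 18.0),
    "D": (17.0, 23.0),
}

#: default glandular areal fraction per density category
DENSITY_GLANDULAR_FRACTION = {"A": 0.20, "B": 0.35, "C": 0.50, "D": 0.65}

#: MLO views image a smaller portion of the breast than CC views
MLO_AREA_SCALE = 0.8

#: correlation length of the glandular texture field, mm
GLANDULAR_SMOOTHING_MM = 15.0

#: tumor permittivity = (1 + contrast) * expected average of the tissue the
#: inclusion replaces; 0 contrast means the inclusion is a no-op in expectation
DEFAULT_TUMOR_CONTRAST = 0.90

#: default tumor ellipse semi-axes, mm; calibrated so that the default cancer
#: cohort's true CC-view contralateral ratio averages ~1.15
DEFAULT_TUMOR_SEMI_AXES = (27.0, 22.0)


@dataclass(frozen=True)
class TumorSpec:
    """Elliptical tumor inclusion on the imaging plane."""

    center_mm: tuple[float, float]
    semi_axes_mm: tuple[float, float]
    permittivity: float

    def __post_init__(self) -> None:
        if min(self.semi_axes_mm) <= 0:
            raise ValueError("tumor semi-axes must be positive")
        if self.permittivity <= 0:
            raise ValueError("tumor permittivity must be positive")


@dataclass
class BreastPhantom:
    """Ground-truth permittivity map for one breast in one view."""

    grid: GridSpec
    epsilon_map: np.ndarray  # (ny, nx) relative permittivity, >= 1
    breast_mask_true: np.ndarray  # (ny, nx) bool
    view: str
    density_category: str
    separation_mm: float  # plate separation d used for this scan
    tumor: Optional[TumorSpec] = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.view not in VIEWS:
            raise ValueError(f"unknown view {self.view!r}")
        if self.density_category not in DENSITY_CATEGORIES:
            raise ValueError(f"unknown density category {self.density_category!r}")
        if self.separation_mm <= 0:
            raise ValueError("plate separation must be positive")


@dataclass
class SubjectSpec:
    """Per-subject generation parameters; unset fields are drawn from defaults."""

    subject_id: str
    group: str  # "healthy" | "cancer"
    density: Optional[str] = None
    glandular_fraction: Optional[float] = None
    asymmetry: Optional[float] = None  # fixed fractional L/R offset of the breast average
    asymmetry_mean: float = 0.05  # E[a] of the half-normal draw when asymmetry is None
    tumor_side: Optional[str] = None
    tumor_visibility: str = "both"  # both | cc-only | mlo-only
    tumor_contrast: float = DEFAULT_TUMOR_CONTRAST
    tumor_semi_axes: Optional[tuple[float, float]] = None
    d1_mm: Optional[float] = None
    grid: GridSpec = field(default_factory=GridSpec)

    def __post_init__(self) -> None:
        if self.group not in ("healthy", "cancer"):
            raise ValueError(f"unknown group {self.group!r}")
        if self.tumor_visibility not in ("both", "cc-only", "mlo-only"):
            raise ValueError(f"unknown tumor visibility {self.tumor_visibility!r}")
        if self.asymmetry is not None and self.asymmetry < 0:
            raise ValueError("asymmetry must be >= 0")
        if self.asymmetry_mean < 0:
            raise ValueError("asymmetry scale must be >= 0")


@dataclass
class SubjectScans:
    """The four phantoms of one subject plus ground-truth summaries."""

    subject_id: str
    group: str
    density: str
    phantoms: dict[str, BreastPhantom]  # keyed LCC/RCC/LMLO/RMLO
    d1_mm: float
    d2_mm: float
    asymmetry: float
    tumor_side: Optional[str]
    true_averages: dict[str, float]  # ground-truth breast-average per view key


@dataclass
class CohortSpec:
    """Cohort composition and generator calibration."""

    n_healthy: int = 20
    n_cancer: int = 14
    density_probs: dict[str, float] = field(
        default_factory=lambda: {"A": 0.10, "B": 0.35, "C": 0.40, "D": 0.15}
    )
    asymmetry_mean: float = 0.05
    tumor_contrast: float = DEFAULT_TUMOR_CONTRAST
    tumor_semi_axes: tuple[float, float] = DEFAULT_TUMOR_SEMI_AXES
    tumor_visibility: str = "both"
    master_seed: int = 0
    grid: GridSpec = field(default_factory=GridSpec)

    def __post_init__(self) -> None:
        if self.n_healthy < 0 or self.n_cancer < 0:
            raise ValueError("cohort sizes must be >= 0")
        total = sum(self.density_probs.values())
        if not math.isclose(total, 1.0, rel_tol=0, abs_tol=1e-9):
            raise ValueError("density probabilities must sum to 1")
        unknown = set(self.density_probs) - set(DENSITY_CATEGORIES)
        if unknown:
            raise ValueError(f"unknown density categories {sorted(unknown)}")


def _breast_mask(
    grid: GridSpec, ax_mm: float, ay_mm: float, center_x_mm: float
) -> np.ndarray:
    """Semi-ellipse abutting the chest-wall edge (y = 0)."""
    x, y = grid.pixel_centers()
    xx, yy = np.meshgrid(x, y)
    return ((xx - center_x_mm) / ax_mm) ** 2 + (yy / ay_mm) ** 2 <= 1.0


def _ellipse_mask(grid: GridSpec, tumor: TumorSpec) -> np.ndarray:
    x, y = grid.pixel_centers()
    xx, yy = np.meshgrid(x, y)
    cx, cy = tumor.center_mm
    ax, ay = tumor.semi_axes_mm
    return ((xx - cx) / ax) ** 2 + ((yy - cy) / ay) ** 2 <= 1.0


def generate_breast_phantom(
    grid: GridSpec,
    density: str,
    glandular_fraction: float,
    view: str,
    d_mm: float,
    tumor: Optional[TumorSpec] = None,
    seed: int = 0,
    *,
    fat_value: Optional[float] = None,
    breast_axes_frac: tuple[float, float] = (0.35, 0.70),
    center_x_frac: float = 0.5,
) -> BreastPhantom:
    """Generate one breast phantom.

    Parameters
    ----------
    grid
        Imaging-plane raster.
    density
        Mammographic density category A-D; selects the glandular band.
    glandular_fraction
        Areal fraction of the breast occupied by glandular tissue, in [0, 1].
    view
        One of LCC/RCC/LMLO/RMLO.  MLO views shrink the imaged breast area by
        ``MLO_AREA_SCALE``.
    d_mm
        Plate separation recorded for this scan (metadata; the 2D map itself
        is separation-independent).
    tumor
        Optional inclusion; its values overwrite the underlying tissue inside
        the breast.  Must intersect the breast region.
    seed
        Texture realization seed; identical inputs give bitwise-identical maps.
    fat_value
        Fat background permittivity; drawn uniformly from ``FAT_BAND`` when
        omitted.  Pass explicitly to share one fat value across a subject's
        four phantoms.
    """
    if not 0.0 <= glandular_fraction <= 1.0:
        raise ValueError("glandular_fraction must be in [0, 1]")
    if density not in DENSITY_CATEGORIES:
        raise ValueError(f"unknown density category {density!r}")
    rng = np.random.default_rng(seed)
    if fat_value is None:
        fat_value = rng.uniform(*FAT_BAND)
    else:
        rng.uniform(*FAT_BAND)  # keep the stream aligned across call styles

    ax_frac, ay_frac = breast_axes_frac
    if view.endswith("MLO"):
        scale = math.sqrt(MLO_AREA_SCALE)
        ax_frac, ay_frac = ax_frac * scale, ay_frac * scale
    ax_mm = ax_frac * grid.width_mm
    ay_mm = ay_frac * grid.height_mm
    mask = _breast_mask(grid, ax_mm, ay_mm, center_x_frac * grid.width_mm)

    eps = np.ones(grid.shape)
    eps[mask] = fat_value

    # glandular tissue: smoothed white noise thresholded to the target fraction
    n_gland = int(round(glandular_fraction * mask.sum()))
    if n_gland > 0:
        texture = rng.standard_normal(grid.shape)
        sigma_px = GLANDULAR_SMOOTHING_MM / grid.pixel_mm
        texture = ndimage.gaussian_filter(texture, sigma_px)
        vals = texture[mask]
        # threshold at the quantile giving exactly n_gland pixels
        order = np.argsort(vals)[::-1]
        gland_local = np.zeros(vals.shape, dtype=bool)
        gland_local[order[:n_gland]] = True
        gland_mask = np.zeros(grid.shape, dtype=bool)
        gland_mask[mask] = gland_local
        lo, hi = DENSITY_BANDS[density]
        eps[gland_mask] = rng.uniform(lo, hi, size=n_gland)

    if tumor is not None:
        tmask = _ellipse_mask(grid, tumor)
        if not (tmask & mask).any():
            raise ValueError("tumor not inside breast")
        eps[tmask & mask] = tumor.permittivity

    return BreastPhantom(
        grid=grid,
        epsilon_map=eps,
        breast_mask_true=mask,
        view=view,
        density_category=density,
        separation_mm=d_mm,
        tumor=tumor,
        seed=seed,
    )


def true_breast_average(phantom: BreastPhantom) -> float:
    """Ground-truth mean permittivity over the true breast mask."""
    if not phantom.breast_mask_true.any():
        raise ValueError("empty breast mask")
    return float(phantom.epsilon_map[phantom.breast_mask_true].mean())


def _expected_average(fat: float, g: float, density: str) -> float:
    lo, hi = DENSITY_BANDS[density]
    return fat + g * ((lo + hi) / 2.0 - fat)


def generate_subject(spec: SubjectSpec, seed: int = 0) -> SubjectScans:
    """Generate the four phantoms (LCC/RCC/LMLO/RMLO) of one subject.

    The left/right glandular fractions are offset so that the fractional
    difference of the true breast averages equals the subject's asymmetry
    parameter ``a`` (drawn half-normal with mean ``asymmetry_mean`` when not
    fixed).  Cancer subjects receive one tumor on the designated side, visible
    in both views of that side by default.
    """
    rng = np.random.default_rng(seed)
    density = spec.density
    if density is None:
        density = str(rng.choice(DENSITY_CATEGORIES))
    g = spec.glandular_fraction
    if g is None:
        g = float(np.clip(DENSITY_GLANDULAR_FRACTION[density] + rng.uniform(-0.05, 0.05), 0.02, 0.95))
    a = spec.asymmetry
    if a is None:
        # half-normal with mean asymmetry_mean: sigma = mean * sqrt(pi/2)
        a = abs(rng.normal(0.0, spec.asymmetry_mean * math.sqrt(math.pi / 2.0)))
    fat = rng.uniform(*FAT_BAND)
    high_side = str(rng.choice(SIDES))
    d1 = spec.d1_mm if spec.d1_mm is not None else float(rng.uniform(50.0, 70.0))
    d2 = d1 - 5.0
    ax_frac = float(rng.uniform(0.28, 0.40))
    ay_frac = float(rng.uniform(0.60, 0.80))

    # glandular-fraction offset achieving a fractional breast-average gap of a
    lo, hi = DENSITY_BANDS[density]
    band_mean = (lo + hi) / 2.0
    delta_g = a * _expected_average(fat, g, density) / (band_mean - fat)
    g_side = {}
    for side in SIDES:
        sign = 0.5 if side == high_side else -0.5
        g_side[side] = float(np.clip(g + sign * delta_g, 0.01, 0.99))

    tumor_side = None
    tumor_value = 1.0
    tumor_axes = spec.tumor_semi_axes or DEFAULT_TUMOR_SEMI_AXES
    if spec.group == "cancer":
        tumor_side = spec.tumor_side or str(rng.choice(SIDES))
        # contrast relative to the expected average of the replaced tissue, so
        # zero contrast leaves the breast average unchanged in expectation
        tumor_value = (1.0 + spec.tumor_contrast) * _expected_average(
            fat, g_side[tumor_side], density
        )

    phantom_seeds = {v: int(s) for v, s in zip(VIEWS, rng.integers(0, 2**31 - 1, size=4))}
    phantoms: dict[str, BreastPhantom] = {}
    for view in VIEWS:
        side = view[0]
        tumor = None
        if tumor_side == side:
            visible = (
                spec.tumor_visibility == "both"
                or (spec.tumor_visibility == "cc-only" and view.endswith("CC"))
                or (spec.tumor_visibility == "mlo-only" and view.endswith("MLO"))
            )
            if visible:
                scale = math.sqrt(MLO_AREA_SCALE) if view.endswith("MLO") else 1.0
                center = (
                    0.5 * spec.grid.width_mm,
                    0.40 * ay_frac * scale * spec.grid.height_mm,
                )
                tumor = TumorSpec(center, tumor_axes, tumor_value)
        phantoms[view] = generate_breast_phantom(
            spec.grid,
            density,
            g_side[side],
            view,
            d2,
            tumor=tumor,
            seed=phantom_seeds[view],
            fat_value=fat,
            breast_axes_frac=(ax_frac, ay_frac),
        )

    return SubjectScans(
        subject_id=spec.subject_id,
        group=spec.group,
        density=density,
        phantoms=phantoms,
        d1_mm=d1,
        d2_mm=d2,
        asymmetry=a,
        tumor_side=tumor_side,
        true_averages={v: true_breast_average(p) for v, p in phantoms.items()},
    )


def generate_cohort(spec: CohortSpec) -> list[SubjectScans]:
    """Generate a reproducible cohort of healthy and cancer subjects."""
    rng = np.random.default_rng(spec.master_seed)
    cats = sorted(spec.density_probs)
    probs = [spec.density_probs[c] for c in cats]
    subjects = []
    n_total = spec.n_healthy + spec.n_cancer
    seeds = rng.integers(0, 2**31 - 1, size=n_total)
    for i in range(n_total):
        group = "healthy" if i < spec.n_healthy else "cancer"
        label = f"H{i + 1:03d}" if group == "healthy" else f"C{i - spec.n_healthy + 1:03d}"
        density = str(rng.choice(cats, p=probs))
        sub_spec = SubjectSpec(
            subject_id=label,
            group=group,
            density=density,
            asymmetry_mean=spec.asymmetry_mean,
            tumor_contrast=spec.tumor_contrast,
            tumor_semi_axes=spec.tumor_semi_axes,
            tumor_visibility=spec.tumor_visibility,
            grid=spec.grid,
        )
        subjects.append(generate_subject(sub_spec, seed=int(seeds[i])))
    return subjects


def homogeneous_phantom(
    grid: GridSpec, permittivity: float, d_mm: float, view: str = "LCC"
) -> BreastPhantom:
    """Uniform slab filling the whole grid; used for physics round-trip checks."""
    if permittivity < 1:
        raise ValueError("relative permittivity must be >= 1")
    mask = np.ones(grid.shape, dtype=bool)
    return BreastPhantom(
        grid=grid,
        epsilon_map=np.full(grid.shape, float(permittivity)),
        breast_mask_true=mask,
        view=view,
        density_category="A",
        separation_mm=d_mm,
    )
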