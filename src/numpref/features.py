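"""Non-numerical visual features of dot displays.

Thirteen features are tracked per display, alongside numerosity itself:

=======================  ======  ==========================================
feature                  axis    definition
=======================  ======  ==========================================
individual_item_area     linear  mean item area (deg^2)
individual_item_perim.   linear  mean item perimeter (deg)
individual_item_radius   linear  mean circle-equivalent radius (deg)
total_item_area          linear  summed item area (deg^2)
total_item_perimeter     log10   summed item perimeter (deg)
convex_hull_area         log10   area inside the hull of all item edges
convex_hull_perimeter    log10   length of that hull (deg)
luminance_density        linear  total item area / hull area
edge_density             log10   total item perimeter / hull area (deg^-1)
numerical_density        linear  numerosity / hull area (deg^-2)
display_rms_contrast     linear  SD of intensities over the aperture
hull_rms_contrast        linear  SD of intensities within the hull
high_sf_energy           log10   contrast energy above 4 cycles/deg
=======================  ======  ==========================================

The axis flag says on which scale a feature enters tuning models and
summary statistics (log10 columns match the published tables' ``log()``
markers). Values are stored on the linear scale and transformed on use.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.spatial import ConvexHull, QhullError
from matplotlib.path import Path as MplPath

from .design import DesignSequence
from .stimuli import ConfigurationSpec, DotDisplay, RenderedImage, place_items, render

__all__ = [
    "FEATURE_AXES",
    "FEATURE_NAMES",
    "FeatureTimecourse",
    "HullPolygon",
    "item_features",
    "convex_hull",
    "convex_hull_of_points",
    "densities",
    "rms_contrast",
    "binary_rms_contrast",
    "high_sf_energy",
    "feature_timecourses",
]

FEATURE_AXES: dict[str, str] = {
    "numerosity": "log10",
    "individual_item_area": "linear",
    "individual_item_perimeter": "linear",
    "individual_item_radius": "linear",
    "total_item_area": "linear",
    "total_item_perimeter": "log10",
    "convex_hull_area": "log10",
    "convex_hull_perimeter": "log10",
    "luminance_density": "linear",
    "edge_density": "log10",
    "numerical_density": "linear",
    "display_rms_contrast": "linear",
    "hull_rms_contrast": "linear",
    "high_sf_energy": "log10",
}

#: the thirteen non-numerical features (numerosity excluded)
FEATURE_NAMES: tuple[str, ...] = tuple(k for k in FEATURE_AXES if k != "numerosity")


@dataclass(frozen=True)
class FeatureTimecourse:
    """One feature's value at every design step of one configuration."""

    feature: str
    configuration: str
    values: np.ndarray       # linear scale, one value per design sample
    axis: str                # 'log10' or 'linear'

    def __post_init__(self) -> None:
        if self.axis not in ("log10", "linear"):
            raise ValueError("axis must be 'log10' or 'linear'")
        object.__setattr__(self, "values", np.asarray(self.values, dtype=float))

    def model_values(self) -> np.ndarray:
        """Values on the model/statistics axis; NaN marks undefined steps."""
        v = self.values
        if self.axis == "linear":
            return v.copy()
        out = np.full_like(v, np.nan)
        ok = np.isfinite(v) & (v > 0)
        out[ok] = np.log10(v[ok])
        return out


@dataclass(frozen=True)
class HullPolygon:
    """Convex hull of an item set: counter-clockwise vertices, area, perimeter."""

    vertices: np.ndarray
    area: float       # deg^2
    perimeter: float  # deg

    def contains_mask(self, X: np.ndarray, Y: np.ndarray) -> np.ndarray:
        if len(self.vertices) < 3:
            return np.zeros_like(X, dtype=bool)
        path = MplPath(self.vertices)
        pts = np.column_stack([X.ravel(), Y.ravel()])
        return path.contains_points(pts).reshape(X.shape)


def _exact_mean(values: np.ndarray) -> float:
    """Mean that returns the shared value exactly when all entries are equal.

    Keeps regime-controlled features constant to the last bit, rather than
    accumulating summation round-off across items.
    """
    values = np.asarray(values, dtype=float)
    if np.all(values == values[0]):
        return float(values[0])
    return float(values.mean())


def item_features(display: DotDisplay) -> tuple[float, float, float, float]:
    """(individual area, individual perimeter, total area, total perimeter).

    Individual values are display means over items; totals are mean x count
    so that a regime's controlled total is exactly constant across the
    design. Analytic geometry, not pixel counts.
    """
    n = display.numerosity
    areas = np.array([it.area for it in display.items])
    perims = np.array([it.perimeter for it in display.items])
    ind_area = _exact_mean(areas)
    ind_perim = _exact_mean(perims)
    return ind_area, ind_perim, ind_area * n, ind_perim * n


def convex_hull_of_points(points: np.ndarray) -> HullPolygon:
    """Hull of a raw 2-D point set, tolerating degenerate (collinear) sets.

    A rank-deficient set gets area 0 and perimeter twice the span (the
    rubber band doubles back on itself).
    """
    points = np.asarray(points, dtype=float)
    try:
        hull = ConvexHull(points)
    except QhullError:
        centered = points - points.mean(axis=0)
        if np.allclose(centered, 0.0):
            return HullPolygon(points[:1], 0.0, 0.0)
        direction = centered[np.argmax(np.hypot(*centered.T))]
        direction = direction / np.hypot(*direction)
        proj = centered @ direction
        lo, hi = points[np.argmin(proj)], points[np.argmax(proj)]
        span = float(np.hypot(*(hi - lo)))
        return HullPolygon(np.array([lo, hi]), 0.0, 2.0 * span)
    verts = points[hull.vertices]
    # Qhull 2-D: volume is the enclosed area, area is the boundary length
    return HullPolygon(verts, float(hull.volume), float(hull.area))


def convex_hull(display: DotDisplay, boundary_samples_per_item: int = 64) -> HullPolygon:
    """Convex hull wrapped around item *edges* (not centers)."""
    return convex_hull_of_points(display.boundary_points(boundary_samples_per_item))


def densities(display: DotDisplay, hull: HullPolygon) -> tuple[float, float, float]:
    """(luminance, edge, numerical) density within the convex hull.

    Returns NaNs when the hull is degenerate (zero area) — the step is
    flagged undefined and tuned models treat it as evoking no response.
    """
    if hull.area <= 0.0:
        return (math.nan, math.nan, math.nan)
    _, _, tot_area, tot_perim = item_features(display)
    return (tot_area / hull.area, tot_perim / hull.area, display.numerosity / hull.area)


def rms_contrast(image: RenderedImage, region: np.ndarray) -> float:
    """Population SD of pixel intensities within a boolean region mask.

    For a binary image this equals ``sqrt(p (1 - p))`` with p the white
    fraction of the region.
    """
    region = np.asarray(region, dtype=bool)
    if region.shape != image.pixels.shape:
        raise ValueError("region mask must match the image shape")
    vals = image.pixels[region]
    if vals.size == 0:
        raise ValueError("empty region")
    return float(vals.std())


def binary_rms_contrast(white_fraction: float) -> float:
    """Closed-form RMS contrast of a binary region with white fraction p."""
    if not 0.0 <= white_fraction <= 1.0:
        raise ValueError("white fraction must lie in [0, 1]")
    return math.sqrt(white_fraction * (1.0 - white_fraction))


def high_sf_energy(image: RenderedImage, cutoff_cpd: float = 4.0) -> float:
    """Contrast energy above ``cutoff_cpd`` cycles/degree (linear units).

    The mean-subtracted image is Fourier transformed; squared magnitudes
    are summed over bins with radial spatial frequency above the cutoff and
    normalized per pixel (mean-square contrast units), so the value is
    stable under resolution changes. Returns 0 for a blank image (log10 of
    the track is then flagged undefined downstream).
    """
    ppd = image.pixels_per_degree
    if ppd <= 2.0 * cutoff_cpd:
        raise ValueError("pixels_per_degree must exceed twice the frequency cutoff")
    img = image.pixels - image.pixels.mean()
    ny, nx = img.shape
    F = np.fft.fft2(img)
    fy = np.fft.fftfreq(ny, d=1.0 / ppd)
    fx = np.fft.fftfreq(nx, d=1.0 / ppd)
    FY, FX = np.meshgrid(fy, fx, indexing="ij")
    radial = np.hypot(FX, FY)
    sel = radial > cutoff_cpd
    return float(np.sum(np.abs(F[sel]) ** 2) / (nx * ny) ** 2)


def feature_timecourses(
    design: DesignSequence,
    config: ConfigurationSpec,
    seed: int,
    pixels_per_degree: float = 128.0,
    boundary_samples_per_item: int = 64,
    cutoff_cpd: float = 4.0,
) -> dict[str, FeatureTimecourse]:
    """All thirteen feature tracks plus the numerosity track for one regime.

    One freshly randomized display is generated per design step (as in the
    experiment, where item placement changes between presentations). RMS
    contrast features use the binary closed form sqrt(p(1-p)), which is
    exact for non-overlapping binary items; high-spatial-frequency energy
    is measured on the rasterized display.
    """
    numerosities = design.numerosities()
    rng = np.random.default_rng(seed)
    step_seeds = rng.integers(0, 2**31 - 1, size=len(numerosities))
    aperture_area = math.pi * config.aperture_radius ** 2

    cols: dict[str, list[float]] = {name: [] for name in FEATURE_AXES}
    for n, s in zip(numerosities, step_seeds):
        display = place_items(config, int(n), int(s))
        ind_a, ind_p, tot_a, tot_p = item_features(display)
        hull = convex_hull(display, boundary_samples_per_item)
        lum_d, edge_d, num_d = densities(display, hull)
        image = render(display, pixels_per_degree)
        hsf = high_sf_energy(image, cutoff_cpd)

        cols["numerosity"].append(float(n))
        cols["individual_item_area"].append(ind_a)
        cols["individual_item_perimeter"].append(ind_p)
        cols["individual_item_radius"].append(math.sqrt(ind_a / math.pi))
        cols["total_item_area"].append(tot_a)
        cols["total_item_perimeter"].append(tot_p)
        cols["convex_hull_area"].append(hull.area)
        cols["convex_hull_perimeter"].append(hull.perimeter)
        cols["luminance_density"].append(lum_d)
        cols["edge_density"].append(edge_d)
        cols["numerical_density"].append(num_d)
        cols["display_rms_contrast"].append(binary_rms_contrast(tot_a / aperture_area))
        cols["hull_rms_contrast"].append(
            binary_rms_contrast(min(1.0, tot_a / hull.area)) if hull.area > 0 else math.nan
        )
        cols["high_sf_energy"].append(hsf)

    return {
        name: FeatureTimecourse(name, config.name, np.array(vals), FEATURE_AXES[name])
        for name, vals in cols.items()
    }


def analytic_timecourses(
    design: DesignSequence, config: ConfigurationSpec
) -> dict[str, FeatureTimecourse]:
    """Placement-independent feature tracks (item geometry and display RMS only).

    These features depend only on the regime's analytic geometry, never on
    random placement, so no displays are generated. Used for the published
    summary-table reproduction.
    """
    from .stimuli import item_geometry

    numerosities = design.numerosities()
    aperture_area = math.pi * config.aperture_radius ** 2
    cols: dict[str, list[float]] = {
        k: []
        for k in (
            "numerosity",
            "individual_item_area",
            "individual_item_perimeter",
            "individual_item_radius",
            "total_item_area",
            "total_item_perimeter",
            "display_rms_contrast",
        )
    }
    for n in numerosities:
        n = int(n)
        area, perim = item_geometry(config, n)
        cols["numerosity"].append(float(n))
        cols["individual_item_area"].append(area)
        cols["individual_item_perimeter"].append(perim)
        cols["individual_item_radius"].append(math.sqrt(area / math.pi))
        cols["total_item_area"].append(area * n)
        cols["total_item_perimeter"].append(perim * n)
        cols["display_rms_contrast"].append(binary_rms_contrast(area * n / aperture_area))
    return {
        name: FeatureTimecourse(name, config.name, np.array(vals), FEATURE_AXES[name])
        for name, vals in cols.items()
    }
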