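"""Dot-array stimulus configurations, item geometry, placement and rendering.

Five stimulus regimes are generated, all sharing the numerosity progression
but differing in how non-numerical features co-vary with numerosity:

``constant_area``
    total item area fixed; items shrink as numerosity grows.
``constant_item_size``
    each item keeps the same area; totals grow with numerosity.
``constant_perimeter``
    total item perimeter fixed; per-item perimeter shrinks as 1/n.
``high_density``
    same per-item sizes as ``constant_area`` but items grouped inside a
    smaller placement region.
``variable_features``
    fixed per-item area, random shapes (circle, square, equilateral
    triangle, 2:1 ellipse), random orientation.

All coordinates are degrees of visual angle, origin at the aperture
center. Item areas and perimeters are analytic; rasterization is only for
image-based features.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping

import numpy as np
from matplotlib.path import Path as MplPath
from scipy.special import ellipe

__all__ = [
    "CONFIGURATION_NAMES",
    "ConfigurationSpec",
    "Item",
    "DotDisplay",
    "RenderedImage",
    "PackingInfeasible",
    "default_configurations",
    "item_geometry",
    "place_items",
    "render",
]

CONFIGURATION_NAMES = (
    "constant_area",
    "constant_item_size",
    "constant_perimeter",
    "high_density",
    "variable_features",
)

#: default shape set for the variable_features regime
DEFAULT_SHAPES = ("circle", "square", "triangle", "ellipse")

# defaults reproducing the published per-configuration feature tables
DEFAULT_TOTAL_AREA = 0.064            # deg^2 (constant_area / high_density)
DEFAULT_ITEM_AREA = 0.187 / 8.8       # deg^2 (constant_item_size); prints as 0.021
DEFAULT_TOTAL_PERIMETER = 10 ** 0.609  # deg (constant_perimeter)
DEFAULT_VF_ITEM_AREA = 0.0134         # deg^2 (variable_features); prints as 0.013
DEFAULT_APERTURE_RADIUS = 0.75        # deg
DEFAULT_HD_PLACEMENT_RADIUS = 0.375   # deg


class PackingInfeasible(RuntimeError):
    """Raised when overlap-free item placement fails within the attempt budget."""


@dataclass(frozen=True)
class ConfigurationSpec:
    """Parameters of one stimulus regime.

    Only the parameters relevant to the named regime are required; the
    rest may stay ``None``.
    """

    name: str
    total_area: float | None = None        # deg^2
    item_area: float | None = None         # deg^2
    total_perimeter: float | None = None   # deg
    aperture_radius: float = DEFAULT_APERTURE_RADIUS
    placement_radius: float | None = None  # deg; defaults to aperture_radius
    shape_set: tuple[str, ...] = DEFAULT_SHAPES

    def __post_init__(self) -> None:
        if self.name not in CONFIGURATION_NAMES:
            raise ValueError(f"unknown configuration {self.name!r}")
        required = {
            "constant_area": "total_area",
            "high_density": "total_area",
            "constant_item_size": "item_area",
            "variable_features": "item_area",
            "constant_perimeter": "total_perimeter",
        }[self.name]
        if getattr(self, required) is None:
            raise ValueError(f"{self.name} requires {required}")
        if self.aperture_radius <= 0:
            raise ValueError("aperture_radius must be positive")
        if self.placement_radius is not None and self.placement_radius > self.aperture_radius:
            raise ValueError("placement_radius must not exceed aperture_radius")

    @property
    def effective_placement_radius(self) -> float:
        return self.aperture_radius if self.placement_radius is None else self.placement_radius


def default_configurations() -> dict[str, ConfigurationSpec]:
    """The five regimes with the default sizes that reproduce the feature tables."""
    return {
        "constant_area": ConfigurationSpec("constant_area", total_area=DEFAULT_TOTAL_AREA),
        "constant_item_size": ConfigurationSpec("constant_item_size", item_area=DEFAULT_ITEM_AREA),
        "constant_perimeter": ConfigurationSpec(
            "constant_perimeter", total_perimeter=DEFAULT_TOTAL_PERIMETER
        ),
        "high_density": ConfigurationSpec(
            "high_density",
            total_area=DEFAULT_TOTAL_AREA,
            placement_radius=DEFAULT_HD_PLACEMENT_RADIUS,
        ),
        "variable_features": ConfigurationSpec(
            "variable_features", item_area=DEFAULT_VF_ITEM_AREA
        ),
    }


def item_geometry(config: ConfigurationSpec, n: int) -> tuple[float, float]:
    """Per-item (area deg^2, perimeter deg) for numerosity ``n``.

    Items are circles (variable_features reports the circle-equivalent
    nominal geometry here; per-item perimeter then depends on the shape
    sampled at placement time).
    """
    if n < 1:
        raise ValueError("numerosity must be >= 1")
    name = config.name
    if name in ("constant_area", "high_density"):
        area = config.total_area / n
        return area, 2.0 * math.sqrt(math.pi * area)
    if name in ("constant_item_size", "variable_features"):
        area = config.item_area
        return area, 2.0 * math.sqrt(math.pi * area)
    if name == "constant_perimeter":
        perim = config.total_perimeter / n
        return perim * perim / (4.0 * math.pi), perim
    raise ValueError(f"unknown configuration {name!r}")


# ----------------------------------------------------------------------
# shapes

_ELLIPSE_RATIO = 2.0  # major:minor axis ratio for the ellipse shape


def _shape_geometry(shape: str, area: float) -> tuple[float, float, np.ndarray | None]:
    """Return (perimeter, circumradius, unit-pose vertices or None for circle)."""
    if shape == "circle":
        r = math.sqrt(area / math.pi)
        return 2.0 * math.pi * r, r, None
    if shape == "square":
        s = math.sqrt(area)
        half = s / 2.0
        verts = np.array([[-half, -half], [half, -half], [half, half], [-half, half]])
        return 4.0 * s, half * math.sqrt(2.0), verts
    if shape == "triangle":
        s = math.sqrt(4.0 * area / math.sqrt(3.0))
        circ = s / math.sqrt(3.0)
        ang = np.array([math.pi / 2, math.pi / 2 + 2 * math.pi / 3, math.pi / 2 + 4 * math.pi / 3])
        verts = circ * np.column_stack([np.cos(ang), np.sin(ang)])
        return 3.0 * s, circ, verts
    if shape == "ellipse":
        a = math.sqrt(_ELLIPSE_RATIO * area / math.pi)
        b = a / _ELLIPSE_RATIO
        m = 1.0 - (b / a) ** 2  # eccentricity squared
        perim = 4.0 * a * float(ellipe(m))
        theta = np.linspace(0.0, 2.0 * math.pi, 96, endpoint=False)
        verts = np.column_stack([a * np.cos(theta), b * np.sin(theta)])
        return perim, a, verts
    raise ValueError(f"unknown shape {shape!r}")


@dataclass(frozen=True)
class Item:
    """One stimulus item: analytic geometry plus pose."""

    center: tuple[float, float]
    shape: str
    area: float       # deg^2, analytic
    perimeter: float  # deg, analytic
    radius: float     # circumradius used for containment / overlap tests
    angle: float = 0.0

    def boundary_points(self, samples: int = 64) -> np.ndarray:
        """Sample points on the item boundary (for convex-hull computation).

        Curved boundaries (circle, ellipse) are sampled on the slightly
        inflated circumscribing polygon (factor ``1/cos(pi/samples)``), so
        the polygonal hull always contains the whole item and the hull
        area never falls below the total item area.
        """
        cx, cy = self.center
        if self.shape == "circle":
            theta = np.linspace(0.0, 2.0 * math.pi, samples, endpoint=False)
            r = self.radius / math.cos(math.pi / samples)
            return np.column_stack([cx + r * np.cos(theta), cy + r * np.sin(theta)])
        if self.shape == "ellipse":
            a = math.sqrt(_ELLIPSE_RATIO * self.area / math.pi) / math.cos(math.pi / samples)
            b = a / _ELLIPSE_RATIO
            theta = np.linspace(0.0, 2.0 * math.pi, samples, endpoint=False)
            pts = np.column_stack([a * np.cos(theta), b * np.sin(theta)])
            return _rotate(pts, self.angle) + np.array([cx, cy])
        _, _, verts = _shape_geometry(self.shape, self.area)
        pts = _densify_polygon(verts, samples)
        return _rotate(pts, self.angle) + np.array([cx, cy])

    def _poly_vertices(self) -> np.ndarray | None:
        """World-frame polygon vertices, or None for an exact circle."""
        if self.shape == "circle":
            return None
        _, _, verts = _shape_geometry(self.shape, self.area)
        return _rotate(verts, self.angle) + np.asarray(self.center)


def _rotate(points: np.ndarray, angle: float) -> np.ndarray:
    c, s = math.cos(angle), math.sin(angle)
    rot = np.array([[c, -s], [s, c]])
    return points @ rot.T


def _densify_polygon(verts: np.ndarray, total: int) -> np.ndarray:
    """Distribute ``total`` boundary samples along polygon edges by length."""
    if len(verts) >= total:
        return verts
    edges = np.roll(verts, -1, axis=0) - verts
    lengths = np.hypot(edges[:, 0], edges[:, 1])
    counts = np.maximum(1, np.round(total * lengths / lengths.sum()).astype(int))
    pts = []
    for v, e, k in zip(verts, edges, counts):
        t = np.arange(k) / k
        pts.append(v + t[:, None] * e)
    return np.concatenate(pts)


@dataclass(frozen=True)
class DotDisplay:
    """Geometric item set for one (configuration, numerosity) presentation."""

    configuration: str
    numerosity: int
    items: tuple[Item, ...]
    aperture_radius: float

    def __post_init__(self) -> None:
        if len(self.items) != self.numerosity:
            raise ValueError("number of items must equal numerosity")

    def boundary_points(self, samples_per_item: int = 64) -> np.ndarray:
        return np.concatenate([it.boundary_points(samples_per_item) for it in self.items])


def place_items(
    config: ConfigurationSpec,
    n: int,
    seed: int | np.random.Generator,
    max_attempts: int = 10_000,
) -> DotDisplay:
    """Place ``n`` non-overlapping items by uniform rejection sampling.

    Centers are drawn uniformly inside the placement region; a draw is
    rejected if the item's bounding circle would leave the aperture or
    touch another item's bounding circle. Deterministic given the seed.

    Raises
    ------
    PackingInfeasible
        if no overlap-free arrangement is found within ``max_attempts``
        candidate draws.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    area, nominal_perim = item_geometry(config, n)

    specs: list[tuple[str, float, float, float, float]] = []
    for _ in range(n):
        if config.name == "variable_features":
            shape = str(rng.choice(config.shape_set))
            angle = float(rng.uniform(0.0, 2.0 * math.pi)) if shape != "circle" else 0.0
        else:
            shape, angle = "circle", 0.0
        perim, circum, _ = _shape_geometry(shape, area)
        specs.append((shape, area, perim, circum, angle))

    # place larger items first: tightest constraints go early
    specs.sort(key=lambda s: -s[3])

    attempts = 0
    while True:
        placed: list[Item] = []
        failed = False
        for shape, a, perim, circum, angle in specs:
            reach = config.effective_placement_radius
            limit = min(reach, config.aperture_radius - circum)
            if limit < 0:
                raise PackingInfeasible(
                    f"{config.name}: item circumradius {circum:.3f} exceeds aperture"
                )
            while True:
                attempts += 1
                if attempts > max_attempts:
                    raise PackingInfeasible(
                        f"{config.name}: no packing for n={n} in {max_attempts} attempts"
                    )
                rad = limit * math.sqrt(rng.uniform())
                theta = rng.uniform(0.0, 2.0 * math.pi)
                cx, cy = rad * math.cos(theta), rad * math.sin(theta)
                ok = all(
                    math.hypot(cx - it.center[0], cy - it.center[1]) > circum + it.radius
                    for it in placed
                )
                if ok:
                    placed.append(Item((cx, cy), shape, a, perim, circum, angle))
                    break
                if attempts % 2000 == 0:
                    failed = True  # restart from scratch to escape dead ends
                    break
            if failed:
                break
        if not failed:
            return DotDisplay(config.name, n, tuple(placed), config.aperture_radius)


@dataclass(frozen=True)
class RenderedImage:
    """Binary rasterization of a display, centered on the aperture."""

    pixels: np.ndarray          # 2-D float array in {0.0, 1.0}, y-down
    pixels_per_degree: float

    @property
    def half_extent(self) -> float:
        return self.pixels.shape[0] / (2.0 * self.pixels_per_degree)

    def pixel_centers(self) -> tuple[np.ndarray, np.ndarray]:
        """World coordinates (deg) of pixel centers as (X, Y) grids."""
        npx = self.pixels.shape[0]
        coords = (np.arange(npx) + 0.5) / self.pixels_per_degree - self.half_extent
        x = coords
        y = -coords  # y-down image rows
        return np.meshgrid(x, y)


def render(display: DotDisplay, pixels_per_degree: float = 200.0) -> RenderedImage:
    """Rasterize a display to a binary image (pixel-center sampling).

    The grid spans the aperture square ``[-R, R]^2``. Resolutions below
    32 px/deg are rejected: item edges would alias too strongly for the
    image-based features.
    """
    if pixels_per_degree < 32:
        raise ValueError("pixels_per_degree must be >= 32")
    R = display.aperture_radius
    npx = int(math.ceil(2.0 * R * pixels_per_degree))
    img = np.zeros((npx, npx), dtype=float)
    coords = (np.arange(npx) + 0.5) / pixels_per_degree - npx / (2.0 * pixels_per_degree)
    X, Y = np.meshgrid(coords, -coords)
    for it in display.items:
        cx, cy = it.center
        if it.shape == "circle":
            img[(X - cx) ** 2 + (Y - cy) ** 2 <= it.radius ** 2] = 1.0
        elif it.shape == "ellipse":
            a = math.sqrt(_ELLIPSE_RATIO * it.area / math.pi)
            b = a / _ELLIPSE_RATIO
            dx, dy = X - cx, Y - cy
            c, s = math.cos(it.angle), math.sin(it.angle)
            u = dx * c + dy * s
            v = -dx * s + dy * c
            img[(u / a) ** 2 + (v / b) ** 2 <= 1.0] = 1.0
        else:
            verts = it._poly_vertices()
            path = MplPath(verts)
            pts = np.column_stack([X.ravel(), Y.ravel()])
            img.ravel()[path.contains_points(pts)] = 1.0
    return RenderedImage(img, float(pixels_per_degree))


def aperture_mask(image: RenderedImage, radius: float) -> np.ndarray:
    """Boolean mask of pixels whose centers fall inside the circular aperture."""
    X, Y = image.pixel_centers()
    return X ** 2 + Y ** 2 <= radius ** 2
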