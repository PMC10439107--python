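"""Printed-dot geometry reconstruction and stimulus surface area.

Workflow: binarize the views (Otsu), take the per-dot equivalent-circle
radius from the top view, extract the upper contour of the largest protrusion
in the side view, fit a second-degree polynomial with classical 95 %
t-intervals, and approximate the dot as a paraboloid of revolution whose
lateral (curved) surface area feeds the per-pattern stimulus size
A_pattern * C_thaumatin.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats
from skimage import filters, measure

from .patterns import DotPattern

__all__ = [
    "DotImageSet",
    "ContourFit",
    "ParaboloidDot",
    "StimulusSize",
    "binarize",
    "radius_from_topview",
    "profile_from_sideview",
    "fit_parabola",
    "paraboloid_area",
    "paraboloid_volume",
    "paraboloid_dot",
    "dot_from_images",
    "stimulus_size",
]


@dataclass(frozen=True)
class DotImageSet:
    """Top- and side-view grayscale images with a shared mm/px scale."""

    top_view: np.ndarray
    side_view: np.ndarray
    scale: float  # mm/px
    provenance: str = "file"

    def __post_init__(self) -> None:
        if self.scale <= 0:
            raise ValueError("scale must be > 0")
        if self.top_view.size == 0 or self.side_view.size == 0:
            raise ValueError("images must be non-empty")


@dataclass(frozen=True)
class ContourFit:
    """OLS fit of z = c2 x^2 + c1 x + c0 with 95 % t-interval half-widths."""

    coefficients: tuple[float, float, float]  # (c2, c1, c0)
    ci95_halfwidths: tuple[float, float, float]
    residual_sd: float
    n_points: int

    def predict(self, x: np.ndarray) -> np.ndarray:
        c2, c1, c0 = self.coefficients
        x = np.asarray(x, dtype=float)
        return c2 * x**2 + c1 * x + c0

    @property
    def vertex_height(self) -> float:
        """Height of the fitted parabola's vertex above z = 0."""
        c2, c1, c0 = self.coefficients
        if c2 == 0:
            return c0
        return c0 - c1**2 / (4.0 * c2)


@dataclass(frozen=True)
class ParaboloidDot:
    """Ideal paraboloid dot of base radius ``a`` and apex height ``h`` (mm)."""

    a: float
    h: float
    lateral_area: float
    volume: float


@dataclass(frozen=True)
class StimulusSize:
    a_pattern: float       # mm^2, summed exposed area of thaumatin-bearing dots
    c_thaumatin: float     # area-weighted mass fraction
    product: float         # mm^2 * mass fraction

    def product_percent(self) -> float:
        """Product with concentration expressed in %w/w (mm^2 * %)."""
        return self.product * 100.0


def binarize(image: np.ndarray, method: str = "otsu") -> np.ndarray:
    """Threshold a grayscale image; foreground (True) is the brighter phase."""
    img = np.asarray(image, dtype=float)
    if img.ndim != 2:
        raise ValueError(f"expected a 2-D grayscale image, got shape {img.shape}")
    if np.ptp(img) == 0:
        raise ValueError("image is uniform: no threshold separates foreground")
    if method == "otsu":
        thresh = filters.threshold_otsu(img)
    elif method == "mean":
        thresh = img.mean()
    else:
        raise ValueError(f"unknown binarization method {method!r}")
    return img > thresh


def radius_from_topview(
    mask: np.ndarray, scale: float, min_area_px: int = 5
) -> list[float]:
    """Equivalent-circle radius (mm) per connected component, left to right.

    Components touching the image border are excluded (partial dots bias the
    equivalent radius); components below ``min_area_px`` are treated as noise.
    """
    if scale <= 0:
        raise ValueError("scale must be > 0")
    labels = measure.label(np.asarray(mask, dtype=bool))
    h, w = labels.shape
    out: list[tuple[float, float]] = []
    for region in measure.regionprops(labels):
        if region.area < min_area_px:
            continue
        r0, c0, r1, c1 = region.bbox
        if r0 == 0 or c0 == 0 or r1 == h or c1 == w:
            continue
        radius = math.sqrt(region.area / math.pi) * scale
        out.append((region.centroid[1], radius))
    if not out:
        warnings.warn("no dot components found in top view", stacklevel=2)
        return []
    out.sort(key=lambda t: t[0])
    return [radius for _, radius in out]


def profile_from_sideview(mask: np.ndarray, scale: float) -> np.ndarray:
    """(x, z) contour of the tallest protrusion above the sample's top face.

    The baseline is the dominant (modal) top-surface row of the silhouette;
    the largest contiguous run of columns rising above it is returned as
    heights (mm) over the baseline, with one flanking zero-height point on
    each side where available.  x is measured from the protrusion centre.
    """
    if scale <= 0:
        raise ValueError("scale must be > 0")
    arr = np.asarray(mask, dtype=bool)
    any_fg = arr.any(axis=0)
    if not any_fg.any():
        raise ValueError("side-view mask is empty")
    tops = np.where(any_fg, arr.argmax(axis=0), -1)
    occupied = np.flatnonzero(any_fg)
    vals, counts = np.unique(tops[occupied], return_counts=True)
    baseline = int(vals[np.argmax(counts)])
    above = np.zeros_like(any_fg)
    above[occupied] = tops[occupied] < baseline
    if not above.any():
        raise ValueError("no protrusion above the baseline in side view")
    # largest contiguous run of protruding columns
    runs = []
    start = None
    for i, flag in enumerate(above.tolist() + [False]):
        if flag and start is None:
            start = i
        elif not flag and start is not None:
            runs.append((start, i))
            start = None
    s, e = max(runs, key=lambda r: r[1] - r[0])
    cols = list(range(s, e))
    if s - 1 >= 0 and any_fg[s - 1]:
        cols.insert(0, s - 1)
    if e < arr.shape[1] and any_fg[e]:
        cols.append(e)
    cols_arr = np.array(cols)
    z = (baseline - tops[cols_arr]).clip(min=0) * scale
    x = (cols_arr + 0.5) * scale
    x = x - x.mean()
    return np.column_stack([x, z])


def fit_parabola(points: np.ndarray) -> ContourFit:
    """OLS second-degree polynomial fit with per-coefficient 95 % t-intervals.

    With exactly 3 points the interpolation is exact and the confidence
    half-widths are reported as infinite (zero residual degrees of freedom).
    """
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2:
        raise ValueError("points must be an (n, 2) array of (x, z)")
    n = pts.shape[0]
    if n < 3:
        raise ValueError(f"need >= 3 points to fit a parabola, got {n}")
    x, z = pts[:, 0], pts[:, 1]
    if np.ptp(x) == 0:
        raise ValueError("all x values identical: rank-deficient fit")
    X = np.column_stack([x**2, x, np.ones_like(x)])
    coef, _, rank, _ = np.linalg.lstsq(X, z, rcond=None)
    if rank < 3:
        raise ValueError("rank-deficient design: cannot fit a parabola")
    resid = z - X @ coef
    dof = n - 3
    if dof > 0:
        s2 = float(resid @ resid) / dof
        cov = s2 * np.linalg.inv(X.T @ X)
        tcrit = stats.t.ppf(0.975, dof)
        halfwidths = tuple(tcrit * math.sqrt(max(c, 0.0)) for c in np.diag(cov))
        residual_sd = math.sqrt(s2)
    else:
        halfwidths = (math.inf, math.inf, math.inf)
        residual_sd = 0.0
    return ContourFit(tuple(coef), halfwidths, residual_sd, n)


def paraboloid_area(a: float, h: float) -> float:
    """Lateral surface area (mm^2) of a paraboloid cap of radius a, height h.

    Closed form for z = h (1 - rho^2/a^2):
        S = (pi a / (6 h^2)) ((a^2 + 4 h^2)^{3/2} - a^3)
    continuous at h -> 0 where it reduces to the flat disk pi a^2.
    """
    if a <= 0:
        raise ValueError("radius a must be > 0")
    if h < 0:
        raise ValueError("height h must be >= 0")
    if h == 0:
        return math.pi * a * a
    # (a^2 + 4h^2)^{3/2} - a^3 = a^3 expm1(1.5 log1p(4h^2/a^2)), stable as h -> 0
    t = 4.0 * h * h / (a * a)
    return math.pi * a**4 / (6.0 * h * h) * math.expm1(1.5 * math.log1p(t))


def paraboloid_volume(a: float, h: float) -> float:
    """Volume (mm^3) under z = h (1 - rho^2/a^2): pi a^2 h / 2."""
    if a <= 0:
        raise ValueError("radius a must be > 0")
    if h < 0:
        raise ValueError("height h must be >= 0")
    return math.pi * a * a * h / 2.0


def paraboloid_dot(a: float, h: float) -> ParaboloidDot:
    return ParaboloidDot(a, h, paraboloid_area(a, h), paraboloid_volume(a, h))


def dot_from_images(images: DotImageSet) -> tuple[ParaboloidDot, ContourFit]:
    """Reconstruct (a, h) from a top/side image pair.

    Radius comes from the top view (mean equivalent-circle radius over the
    detected dots); height from the side-view contour's fitted vertex.
    """
    top_mask = binarize(images.top_view)
    radii = radius_from_topview(top_mask, images.scale)
    if not radii:
        raise ValueError("no dots detected in top view")
    a = float(np.mean(radii))
    side_mask = binarize(images.side_view)
    profile = profile_from_sideview(side_mask, images.scale)
    fit = fit_parabola(profile)
    h = max(fit.vertex_height, 0.0)
    return paraboloid_dot(a, h), fit


def stimulus_size(pattern: DotPattern, dot_geometry: ParaboloidDot) -> StimulusSize:
    """Pattern-level stimulus size A_pattern * C_thaumatin.

    A_pattern sums the lateral area of thaumatin-bearing dots (for Layer, the
    coated top-face area).  Mixed-ink patterns accumulate the product per ink.
    """
    if pattern.design_name == "Layer" or (not pattern.dots and pattern.layer_coat_mass_ug):
        if pattern.layer_ink is None:
            raise ValueError("Layer pattern without a coat ink")
        area = pattern.geometry.length * pattern.geometry.width
        conc = pattern.layer_ink.effective_thaumatin
        return StimulusSize(area, conc, area * conc)
    a_pattern = 0.0
    product = 0.0
    for dot in pattern.dots:
        conc = dot.ink.effective_thaumatin
        if conc > 0:
            a_pattern += dot_geometry.lateral_area
            product += dot_geometry.lateral_area * conc
    c_eff = product / a_pattern if a_pattern > 0 else 0.0
    return StimulusSize(a_pattern, c_eff, product)
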