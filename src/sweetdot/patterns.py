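"""Ink formulations and dot-pattern designs for surface-structured samples.

The study's seven sample designs place thaumatin-loaded cocoa-butter dots on a
36 x 24 x 3 mm chocolate plate while keeping the total thaumatin mass per
sample constant.  Dot counts per design are fixed (184 / 92 / 46); the layout
here is a declared canonical convention: a centred square lattice of pitch
2.0 mm (16 columns x 12 rows) with two cells trimmed at each corner, and
checkerboard subsets for the spaced designs.  Meso designs use a denser
1.5 mm-pitch cluster layout with empty bands separating contrasting inks.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np

__all__ = [
    "CompositionError",
    "GeometryError",
    "InkFormulation",
    "SampleGeometry",
    "DotSpec",
    "DotPattern",
    "TastantLoad",
    "DESIGN_NAMES",
    "make_ink",
    "table_inks",
    "generate_pattern",
    "dot_distances",
    "classify_scale",
    "cluster_gap",
    "tastant_load",
    "render_bitmap",
    "pattern_to_json",
    "pattern_from_json",
]


class CompositionError(ValueError):
    """Raised when ink mass fractions are inconsistent."""


class GeometryError(ValueError):
    """Raised when a requested layout does not fit the printable region."""


_FRAC_TOL = 1e-9

# Canonical micro grid: 16 x 12 cells at 2.0 mm pitch, centred on the plate.
GRID_COLS = 16
GRID_ROWS = 12
GRID_PITCH = 2.0
# Two cells removed at each corner (the corner cell and its x neighbour);
# this trims 192 -> 184 and splits 4/4 across checkerboard parities so the
# spaced subsets count exactly 92 and 46.
_CORNER_CELLS = frozenset(
    {
        (0, 0), (1, 0), (GRID_COLS - 2, 0), (GRID_COLS - 1, 0),
        (0, GRID_ROWS - 1), (1, GRID_ROWS - 1),
        (GRID_COLS - 2, GRID_ROWS - 1), (GRID_COLS - 1, GRID_ROWS - 1),
    }
)

DESIGN_NAMES = (
    "Bulk",
    "Homogeneous",
    "SpacedFull",
    "SpacedHalf",
    "SpacedQuarter",
    "Centered",
    "Periphery",
    "Layer",
)

_DESIGN_ALIASES = {
    "bulk": "Bulk",
    "homogeneous": "Homogeneous",
    "spacedfull": "SpacedFull",
    "spfull": "SpacedFull",
    "full": "SpacedFull",
    "spacedhalf": "SpacedHalf",
    "sphalf": "SpacedHalf",
    "half": "SpacedHalf",
    "spacedquarter": "SpacedQuarter",
    "spquarter": "SpacedQuarter",
    "quarter": "SpacedQuarter",
    "centered": "Centered",
    "periphery": "Periphery",
    "layer": "Layer",
}

#: Default nominal printed dot diameter (mm), mid-range of the measured
#: 1.36-1.6 mm diameters.
DEFAULT_DOT_DIAMETER = 1.5
#: Default jetted drop mass (ug).
DEFAULT_DROP_MASS_UG = 390.0
#: Default plate mass (g).
DEFAULT_PLATE_MASS_G = 2.34


@dataclass(frozen=True)
class InkFormulation:
    """A printable ink: seeded cocoa butter carrying a W/O emulsion.

    ``emulsion_composition`` maps emulsion component names to mass fractions
    *of the emulsion*.  ``effective_thaumatin`` is the thaumatin mass fraction
    of the whole ink (C_thaumatin).
    """

    name: str
    seeded_cocoa_butter_frac: float
    emulsion_frac: float
    emulsion_composition: Mapping[str, float]

    @property
    def effective_thaumatin(self) -> float:
        return self.emulsion_frac * self.emulsion_composition.get("thaumatin", 0.0)


def make_ink(
    name: str,
    emulsion_thaumatin_frac: float,
    emulsion_frac: float = 0.1,
    components: Mapping[str, float] | None = None,
) -> InkFormulation:
    """Build an ink from its emulsion thaumatin fraction and emulsion share.

    ``components`` gives the non-thaumatin emulsion components as mass
    fractions of the emulsion; if the fractions do not sum to 1 the ``water``
    entry is adjusted to close the balance (within [0, 1]).
    """
    comps = dict(components) if components is not None else {"PGPR": 0.03, "CCT_oil": 0.52}
    comps["thaumatin"] = float(emulsion_thaumatin_frac)
    if "water" not in comps:
        comps["water"] = 1.0 - sum(comps.values())
    for comp, frac in comps.items():
        if not (-_FRAC_TOL <= frac <= 1.0 + _FRAC_TOL):
            raise CompositionError(f"emulsion component {comp!r} fraction {frac} outside [0, 1]")
    total = sum(comps.values())
    if abs(total - 1.0) > 1e-6:
        raise CompositionError(
            f"emulsion composition sums to {total}, expected 1 "
            f"(components: {sorted(comps)})"
        )
    # renormalize exactly
    comps = {k: v / total for k, v in comps.items()}
    if not (0.0 <= emulsion_frac <= 1.0):
        raise CompositionError(f"emulsion_frac {emulsion_frac} outside [0, 1]")
    return InkFormulation(
        name=name,
        seeded_cocoa_butter_frac=1.0 - emulsion_frac,
        emulsion_frac=float(emulsion_frac),
        emulsion_composition=comps,
    )


def table_inks() -> dict[str, InkFormulation]:
    """The four study inks A-D (9:1 seeded cocoa butter : emulsion)."""
    thaumatin = {"A": 0.009, "B": 0.018, "C": 0.036, "D": 0.0}
    water = {"A": 0.441, "B": 0.432, "C": 0.414, "D": 0.45}
    inks = {}
    for label in "ABCD":
        inks[label] = make_ink(
            label,
            thaumatin[label],
            emulsion_frac=0.1,
            components={"water": water[label], "PGPR": 0.03, "CCT_oil": 0.52},
        )
    return inks


@dataclass(frozen=True)
class SampleGeometry:
    """Chocolate plate bounding box and printable margin (all mm)."""

    length: float = 36.0
    width: float = 24.0
    height: float = 3.0
    printable_margin: float = 0.5

    def __post_init__(self) -> None:
        if not (self.length > self.width > self.height > 0):
            raise GeometryError(
                f"expected length > width > height > 0, got "
                f"{self.length} / {self.width} / {self.height}"
            )
        if self.printable_margin < 0:
            raise GeometryError("printable_margin must be >= 0")

    @property
    def printable_x(self) -> tuple[float, float]:
        return (self.printable_margin, self.length - self.printable_margin)

    @property
    def printable_y(self) -> tuple[float, float]:
        return (self.printable_margin, self.width - self.printable_margin)

    def contains(self, x: float, y: float, tol: float = 1e-9) -> bool:
        x0, x1 = self.printable_x
        y0, y1 = self.printable_y
        return (x0 - tol <= x <= x1 + tol) and (y0 - tol <= y <= y1 + tol)


@dataclass(frozen=True)
class DotSpec:
    """One printed dot: centre (mm, origin at plate corner, x along length)."""

    center_x: float
    center_y: float
    ink: InkFormulation
    nominal_diameter: float = DEFAULT_DOT_DIAMETER


@dataclass(frozen=True)
class DotPattern:
    design_name: str
    dots: tuple[DotSpec, ...]
    scale_class: str  # micro | meso | none
    geometry: SampleGeometry = field(default_factory=SampleGeometry)
    bulk_thaumatin_frac: float = 0.0
    layer_coat_mass_ug: float = 0.0
    layer_ink: InkFormulation | None = None

    def __len__(self) -> int:
        return len(self.dots)

    def centers(self) -> np.ndarray:
        """(n, 2) array of dot centres in mm."""
        return np.array([(d.center_x, d.center_y) for d in self.dots], dtype=float).reshape(-1, 2)


def _micro_cells(subset: str) -> list[tuple[int, int]]:
    cells = []
    for j in range(GRID_ROWS):
        for i in range(GRID_COLS):
            if (i, j) in _CORNER_CELLS:
                continue
            if subset == "half" and (i + j) % 2 != 0:
                continue
            if subset == "quarter" and not (i % 2 == 0 and j % 2 == 0):
                continue
            cells.append((i, j))
    return cells


def _micro_dots(
    geometry: SampleGeometry, ink: InkFormulation, diameter: float, subset: str = "full"
) -> tuple[DotSpec, ...]:
    x0 = (geometry.length - (GRID_COLS - 1) * GRID_PITCH) / 2.0
    y0 = (geometry.width - (GRID_ROWS - 1) * GRID_PITCH) / 2.0
    dots = []
    for i, j in _micro_cells(subset):
        x = x0 + i * GRID_PITCH
        y = y0 + j * GRID_PITCH
        if not geometry.contains(x, y):
            raise GeometryError(
                f"canonical grid cell ({i}, {j}) at ({x}, {y}) mm falls outside "
                f"the printable region of {geometry}"
            )
        dots.append(DotSpec(x, y, ink, diameter))
    return tuple(dots)


# Meso cluster layout (pitch 1.5 mm == nominal dot diameter, the minimum
# non-overlapping spacing).  Central block: 7 cols x 14 rows minus 6 cells
# (corners + row-centre of top and bottom rows) -> 92 dots.  End bands:
# 4 cols x 12 rows minus the two outer corners -> 46 dots each (92 total).
_MESO_PITCH = 1.5


def _meso_block_cells() -> list[tuple[int, int]]:
    removed = {(0, 0), (3, 0), (6, 0), (0, 13), (3, 13), (6, 13)}
    return [(i, j) for j in range(14) for i in range(7) if (i, j) not in removed]


def _meso_band_cells(side: str) -> list[tuple[int, int]]:
    # outer corners (plate-edge side) removed
    outer = 0 if side == "left" else 3
    removed = {(outer, 0), (outer, 11)}
    return [(i, j) for j in range(12) for i in range(4) if (i, j) not in removed]


def _meso_dots(
    geometry: SampleGeometry,
    block_ink: InkFormulation,
    band_ink: InkFormulation,
    diameter: float,
) -> tuple[DotSpec, ...]:
    p = _MESO_PITCH
    # central block, centred on the plate
    bx0 = geometry.length / 2.0 - 3.0 * p
    by0 = geometry.width / 2.0 - 6.5 * p
    dots = [
        DotSpec(bx0 + i * p, by0 + j * p, block_ink, diameter)
        for i, j in _meso_block_cells()
    ]
    # end bands flush with the printable margin
    band_y0 = geometry.width / 2.0 - 5.5 * p
    left_x0 = geometry.printable_x[0]
    right_x0 = geometry.printable_x[1] - 3.0 * p
    for side, x0 in (("left", left_x0), ("right", right_x0)):
        for i, j in _meso_band_cells(side):
            dots.append(DotSpec(x0 + i * p, band_y0 + j * p, band_ink, diameter))
    for d in dots:
        if not geometry.contains(d.center_x, d.center_y):
            raise GeometryError(
                f"meso dot at ({d.center_x}, {d.center_y}) mm falls outside the "
                f"printable region of {geometry}"
            )
    return tuple(dots)


def generate_pattern(
    design_name: str,
    geometry: SampleGeometry | None = None,
    nominal_diameter: float = DEFAULT_DOT_DIAMETER,
    inks: Mapping[str, InkFormulation] | None = None,
    drop_mass_ug: float = DEFAULT_DROP_MASS_UG,
    plate_mass_g: float = DEFAULT_PLATE_MASS_G,
    layer_coat_mass_ug: float | None = None,
    seed: int | None = None,
) -> DotPattern:
    """Generate a canonical sample design.

    All canonical designs are deterministic; ``seed`` is accepted for
    interface uniformity and ignored.

    Dot counts: Bulk / Homogeneous / SpacedFull / Centered / Periphery 184,
    SpacedHalf 92, SpacedQuarter 46, Layer 0 (a uniform ink-A coat instead).
    """
    key = design_name.replace("_", "").replace("-", "").replace(" ", "").replace(".", "").lower()
    if key not in _DESIGN_ALIASES:
        raise ValueError(f"unknown design {design_name!r}; expected one of {DESIGN_NAMES}")
    name = _DESIGN_ALIASES[key]
    geometry = geometry or SampleGeometry()
    inks = dict(inks) if inks is not None else table_inks()

    if name == "Layer":
        coat = layer_coat_mass_ug
        if coat is None:
            coat = 184 * drop_mass_ug  # same ink-A mass as the full dotted designs
        return DotPattern(name, (), "none", geometry, layer_coat_mass_ug=coat, layer_ink=inks["A"])
    if name == "Bulk":
        dots = _micro_dots(geometry, inks["D"], nominal_diameter, "full")
        dotted_load_ug = 184 * drop_mass_ug * inks["A"].effective_thaumatin
        bulk_frac = dotted_load_ug / (plate_mass_g * 1e6)
        return DotPattern(name, dots, "none", geometry, bulk_thaumatin_frac=bulk_frac)
    if name in ("Homogeneous", "SpacedFull"):
        return DotPattern(name, _micro_dots(geometry, inks["A"], nominal_diameter, "full"),
                          "micro", geometry)
    if name == "SpacedHalf":
        return DotPattern(name, _micro_dots(geometry, inks["B"], nominal_diameter, "half"),
                          "micro", geometry)
    if name == "SpacedQuarter":
        return DotPattern(name, _micro_dots(geometry, inks["C"], nominal_diameter, "quarter"),
                          "micro", geometry)
    if name == "Centered":
        return DotPattern(name, _meso_dots(geometry, inks["B"], inks["D"], nominal_diameter),
                          "meso", geometry)
    if name == "Periphery":
        return DotPattern(name, _meso_dots(geometry, inks["D"], inks["B"], nominal_diameter),
                          "meso", geometry)
    raise AssertionError(name)


def dot_distances(pattern: DotPattern, metric: str = "edge") -> np.ndarray:
    """Nearest-neighbour distance per dot (mm).

    ``metric='center'`` gives centre-to-centre distance; ``'edge'`` subtracts
    the nominal diameter (floored at 0).  Fewer than two dots -> empty array.
    """
    if metric not in ("center", "edge"):
        raise ValueError(f"unknown metric {metric!r}")
    pts = pattern.centers()
    n = len(pts)
    if n < 2:
        return np.empty(0)
    d = np.linalg.norm(pts[:, None, :] - pts[None, :, :], axis=-1)
    np.fill_diagonal(d, np.inf)
    nn = d.min(axis=1)
    if metric == "edge":
        diam = np.array([dot.nominal_diameter for dot in pattern.dots])
        nn = np.maximum(nn - diam, 0.0)
    return nn


MICRO_GAP_MM = 2.5
MESO_GAP_MM = 8.0


def cluster_gap(pattern: DotPattern) -> float:
    """Minimum distance between thaumatin-bearing and contrasting dot
    clusters, measured along the plate's long axis.  NaN when the pattern
    lacks one of the two populations.
    """
    loaded = [d.center_x for d in pattern.dots if d.ink.effective_thaumatin > 0]
    blank = [d.center_x for d in pattern.dots if d.ink.effective_thaumatin == 0]
    if not loaded or not blank:
        return float("nan")
    la = np.asarray(loaded)
    ba = np.asarray(blank)
    return float(np.abs(la[:, None] - ba[None, :]).min())


def classify_scale(pattern: DotPattern) -> str:
    """micro / meso / none per the study's dot-to-dot distance convention.

    meso: contrasting ink clusters separated by > 8 mm along the long axis.
    micro: thaumatin-bearing dots with max nearest-neighbour edge gap
    <= 2.5 mm.  none: no thaumatin-bearing dots (Layer, Bulk, empty).
    """
    loaded = [d for d in pattern.dots if d.ink.effective_thaumatin > 0]
    if not loaded:
        return "none"
    gap = cluster_gap(pattern)
    if math.isfinite(gap) and gap > MESO_GAP_MM:
        return "meso"
    sub = DotPattern(pattern.design_name, tuple(loaded), pattern.scale_class, pattern.geometry)
    gaps = dot_distances(sub, metric="edge")
    if gaps.size and gaps.max() <= MICRO_GAP_MM + 1e-9:
        return "micro"
    return "none"


@dataclass(frozen=True)
class TastantLoad:
    total_ug: float
    per_ink_ug: Mapping[str, float]
    bulk_ug: float = 0.0
    coat_ug: float = 0.0


def tastant_load(
    pattern: DotPattern,
    drop_mass_ug: float = DEFAULT_DROP_MASS_UG,
    plate_mass_g: float = DEFAULT_PLATE_MASS_G,
) -> TastantLoad:
    """Total thaumatin mass (ug) deposited on a sample, itemized by ink."""
    if drop_mass_ug <= 0:
        raise ValueError("drop_mass_ug must be > 0")
    per_ink: dict[str, float] = {}
    for dot in pattern.dots:
        per_ink[dot.ink.name] = per_ink.get(dot.ink.name, 0.0) + (
            drop_mass_ug * dot.ink.effective_thaumatin
        )
    bulk_ug = pattern.bulk_thaumatin_frac * plate_mass_g * 1e6
    coat_ug = 0.0
    if pattern.layer_coat_mass_ug and pattern.layer_ink is not None:
        coat_ug = pattern.layer_coat_mass_ug * pattern.layer_ink.effective_thaumatin
    total = sum(per_ink.values()) + bulk_ug + coat_ug
    return TastantLoad(total, per_ink, bulk_ug, coat_ug)


def render_bitmap(pattern: DotPattern, pixel_pitch: float = 2.0) -> np.ndarray:
    """Rasterize dot centres to a binary bitmap covering the plate.

    True (white) pixels mark dots.  Pixel (row, col) covers
    [col*p, (col+1)*p) x [row*p, (row+1)*p); each dot lights the pixel
    containing its centre.  Two dots mapping to one pixel is ambiguous and
    raises :class:`GeometryError`.
    """
    if pixel_pitch <= 0:
        raise ValueError("pixel_pitch must be > 0")
    geo = pattern.geometry
    cols = int(math.ceil(geo.length / pixel_pitch - 1e-9))
    rows = int(math.ceil(geo.width / pixel_pitch - 1e-9))
    bitmap = np.zeros((rows, cols), dtype=bool)
    for dot in pattern.dots:
        c = int(dot.center_x / pixel_pitch)
        r = int(dot.center_y / pixel_pitch)
        c = min(c, cols - 1)
        r = min(r, rows - 1)
        if bitmap[r, c]:
            raise GeometryError(
                f"two dots map to pixel (row {r}, col {c}) at pitch {pixel_pitch} mm/px"
            )
        bitmap[r, c] = True
    return bitmap


def _ink_to_dict(ink: InkFormulation) -> dict:
    return {
        "name": ink.name,
        "seeded_cocoa_butter_frac": ink.seeded_cocoa_butter_frac,
        "emulsion_frac": ink.emulsion_frac,
        "emulsion_composition": dict(ink.emulsion_composition),
    }


def pattern_to_json(pattern: DotPattern) -> str:
    inks = {}
    for dot in pattern.dots:
        inks[dot.ink.name] = dot.ink
    if pattern.layer_ink is not None:
        inks[pattern.layer_ink.name] = pattern.layer_ink
    payload = {
        "design_name": pattern.design_name,
        "scale_class": pattern.scale_class,
        "geometry": {
            "length": pattern.geometry.length,
            "width": pattern.geometry.width,
            "height": pattern.geometry.height,
            "printable_margin": pattern.geometry.printable_margin,
        },
        "bulk_thaumatin_frac": pattern.bulk_thaumatin_frac,
        "layer_coat_mass_ug": pattern.layer_coat_mass_ug,
        "layer_ink": pattern.layer_ink.name if pattern.layer_ink else None,
        "inks": {k: _ink_to_dict(v) for k, v in inks.items()},
        "dots": [
            {"x": d.center_x, "y": d.center_y, "ink": d.ink.name,
             "diameter": d.nominal_diameter}
            for d in pattern.dots
        ],
    }
    return json.dumps(payload, indent=2)


def pattern_from_json(text: str) -> DotPattern:
    payload = json.loads(text)
    inks = {
        k: InkFormulation(
            name=v["name"],
            seeded_cocoa_butter_frac=v["seeded_cocoa_butter_frac"],
            emulsion_frac=v["emulsion_frac"],
            emulsion_composition=v["emulsion_composition"],
        )
        for k, v in payload["inks"].items()
    }
    geometry = SampleGeometry(**payload["geometry"])
    dots = tuple(
        DotSpec(d["x"], d["y"], inks[d["ink"]], d["diameter"]) for d in payload["dots"]
    )
    layer_ink = inks.get(payload["layer_ink"]) if payload.get("layer_ink") else None
    return DotPattern(
        design_name=payload["design_name"],
        dots=dots,
        scale_class=payload["scale_class"],
        geometry=geometry,
        bulk_thaumatin_frac=payload.get("bulk_thaumatin_frac", 0.0),
        layer_coat_mass_ug=payload.get("layer_coat_mass_ug", 0.0),
        layer_ink=layer_ink,
    )
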