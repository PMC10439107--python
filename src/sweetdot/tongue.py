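"""Biomimetic tongue surface and tastant smearing under oscillatory shear.

Papillae (filiform / fungiform) are randomly placed with a minimum
centre-to-centre distance, shaped as inverted paraboloid bumps scaled to the
measured heights, sampled to a structured heightfield grid and exported as a
Wavefront OBJ.  Oscillatory shear over the dotted sample is modelled as a
mass-conserving 1-D box smear of each dot's thaumatin along the oscillation
axis, with the resulting exposure map split into anterior/posterior regions.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from skimage import measure

from .patterns import DotPattern, tastant_load, DEFAULT_DROP_MASS_UG

__all__ = [
    "PapillaSpec",
    "PapillaeField",
    "TongueMesh",
    "ShearKinematics",
    "ExposureMap",
    "PackingError",
    "FILIFORM",
    "FUNGIFORM",
    "segment_papillae",
    "filiform_number_density",
    "place_papillae",
    "papilla_height",
    "build_mesh",
    "export_obj",
    "load_obj",
    "smear_exposure",
    "exposure_cv",
    "region_split",
]


class PackingError(RuntimeError):
    """Raised when dart-throwing placement cannot reach the requested count."""


@dataclass(frozen=True)
class PapillaSpec:
    """One papilla class: radius and height in mm."""

    kind: str  # filiform | fungiform
    radius: float
    height: float

    def __post_init__(self) -> None:
        if self.radius <= 0 or self.height <= 0:
            raise ValueError("papilla radius and height must be > 0")


# Literature geometry: r_Fi 180 um, h_Fi 195 um, h_Fu 390 um.  The fungiform
# radius is not reported alongside; 0.5 mm is a representative value.
FILIFORM = PapillaSpec("filiform", radius=0.180, height=0.195)
FUNGIFORM = PapillaSpec("fungiform", radius=0.500, height=0.390)


@dataclass(frozen=True)
class PapillaeField:
    bbox: tuple[float, float]  # (width_x, width_y) mm
    papillae: tuple[tuple[float, float, PapillaSpec], ...]
    min_distance: float
    seed: int | None = None

    def __len__(self) -> int:
        return len(self.papillae)


@dataclass(frozen=True)
class TongueMesh:
    x: np.ndarray  # 1-D grid coordinates (mm)
    y: np.ndarray
    z: np.ndarray  # (len(y), len(x)) heights (mm)
    resolution: float
    source_field: PapillaeField | None = None


@dataclass(frozen=True)
class ShearKinematics:
    """Oscillation parameters; only half_amplitude enters the smear kernel."""

    velocity: float = 10.0        # v_T, mm/s
    normal_force: float = 1.0     # F_N, N
    half_amplitude: float = 5.0   # A/2, mm
    axis: str = "x"

    def __post_init__(self) -> None:
        if min(self.velocity, self.normal_force, self.half_amplitude) <= 0:
            raise ValueError("kinematic parameters must be > 0")
        if self.axis not in ("x", "y"):
            raise ValueError("axis must be 'x' or 'y'")


@dataclass(frozen=True)
class ExposureMap:
    """Thaumatin mass per grid cell over the tongue-contact plane."""

    x: np.ndarray          # cell-centre coordinates along the long axis (mm)
    y: np.ndarray
    mass: np.ndarray       # (len(y), len(x)) ug per cell
    cell_size: float       # mm
    region_boundary: float  # anterior/posterior split along the long axis (mm)

    @property
    def density(self) -> np.ndarray:
        """Surface density, ug/mm^2."""
        return self.mass / (self.cell_size**2)

    @property
    def total_mass(self) -> float:
        return float(self.mass.sum())


def segment_papillae(
    image: np.ndarray,
    radius_cutoff_mm: float = 0.3,
    scale: float = 0.02,
    min_area_px: int = 4,
) -> tuple[np.ndarray, np.ndarray, tuple[int, int]]:
    """Split a stained-tongue image into fungiform/filiform masks and counts.

    Components are thresholded (Otsu on non-uniform images), labelled and
    classified by equivalent-circle radius: >= ``radius_cutoff_mm`` is
    fungiform, smaller is filiform.  Returns (filiform_mask, fungiform_mask,
    (n_fungiform, n_filiform)).
    """
    img = np.asarray(image, dtype=float)
    if np.ptp(img) == 0:
        warnings.warn("blank image: no papillae found", stacklevel=2)
        empty = np.zeros(img.shape, dtype=bool)
        return empty, empty.copy(), (0, 0)
    from skimage import filters

    mask = img > filters.threshold_otsu(img)
    labels = measure.label(mask)
    fili = np.zeros(img.shape, dtype=bool)
    fungi = np.zeros(img.shape, dtype=bool)
    n_fu = n_fi = 0
    for region in measure.regionprops(labels):
        if region.area < min_area_px:
            continue
        radius = math.sqrt(region.area / math.pi) * scale
        target = labels == region.label
        if radius >= radius_cutoff_mm:
            fungi |= target
            n_fu += 1
        else:
            fili |= target
            n_fi += 1
    if n_fu + n_fi == 0:
        warnings.warn("no papillae components above the area filter", stacklevel=2)
    return fili, fungi, (n_fu, n_fi)


def filiform_number_density(
    area_fraction: float, r_fi_mm: float, min_dist_mm: float
) -> float:
    """Filiform count per mm^2: areal coverage / (radius * minimum spacing)."""
    if not (0 < area_fraction <= 1):
        raise ValueError("area_fraction must be in (0, 1]")
    if r_fi_mm <= 0 or min_dist_mm <= 0:
        raise ValueError("radius and minimum distance must be > 0")
    return area_fraction / (r_fi_mm * min_dist_mm)


def place_papillae(
    densities: Mapping[PapillaSpec, float],
    bbox: tuple[float, float],
    min_distance: float,
    seed: int | None = 0,
    max_attempts: int = 10_000,
) -> PapillaeField:
    """Dart-throwing placement of papillae at the requested number densities.

    ``densities`` maps each papilla class to a count per mm^2; the realized
    count is round(density * area).  Candidate centres violating the minimum
    centre-to-centre distance are rejected; exhausting ``max_attempts``
    consecutive rejections raises :class:`PackingError` with the achieved
    fraction.  Deterministic per seed.
    """
    if min_distance < 0:
        raise ValueError("min_distance must be >= 0")
    wx, wy = bbox
    area = wx * wy
    rng = np.random.default_rng(seed)
    placed: list[tuple[float, float, PapillaSpec]] = []
    coords: list[tuple[float, float]] = []
    requested_total = 0
    for spec, dens in densities.items():
        count = int(round(dens * area))
        requested_total += count
        for _ in range(count):
            for attempt in range(max_attempts):
                x = rng.uniform(0.0, wx)
                y = rng.uniform(0.0, wy)
                if all((x - px) ** 2 + (y - py) ** 2 >= min_distance**2
                       for px, py in coords):
                    coords.append((x, y))
                    placed.append((x, y, spec))
                    break
            else:
                raise PackingError(
                    f"placed {len(placed)}/{requested_total} papillae "
                    f"({len(placed) / requested_total:.0%}) before exhausting "
                    f"{max_attempts} attempts at min_distance {min_distance} mm"
                )
    return PapillaeField((wx, wy), tuple(placed), min_distance, seed)


def papilla_height(x: float, y: float, spec: PapillaSpec) -> float:
    """Height (mm) of a papilla bump at offset (x, y) from its centre.

    Inverted-paraboloid template: z = h * max(0, 1 - (x^2 + y^2) / r^2),
    rising to the measured height at the centre and meeting the base at r.
    """
    frac = 1.0 - (x * x + y * y) / (spec.radius**2)
    return spec.height * frac if frac > 0 else 0.0


def build_mesh(field: PapillaeField, resolution: float) -> TongueMesh:
    """Sample the papillae field to a structured heightfield grid.

    Overlapping papillae combine by pointwise maximum.  ``resolution`` must
    resolve the smallest papilla (<= half its radius).
    """
    if resolution <= 0:
        raise ValueError("resolution must be > 0")
    if field.papillae:
        min_radius = min(spec.radius for _, _, spec in field.papillae)
        if resolution > min_radius / 2.0 + 1e-12:
            raise ValueError(
                f"resolution {resolution} mm too coarse for papilla radius "
                f"{min_radius} mm (need <= {min_radius / 2.0})"
            )
    wx, wy = field.bbox
    x = np.arange(0.0, wx + resolution / 2.0, resolution)
    y = np.arange(0.0, wy + resolution / 2.0, resolution)
    z = np.zeros((y.size, x.size))
    for px, py, spec in field.papillae:
        i0 = max(int((px - spec.radius) / resolution), 0)
        i1 = min(int((px + spec.radius) / resolution) + 2, x.size)
        j0 = max(int((py - spec.radius) / resolution), 0)
        j1 = min(int((py + spec.radius) / resolution) + 2, y.size)
        if i0 >= i1 or j0 >= j1:
            continue
        xs = x[i0:i1] - px
        ys = y[j0:j1] - py
        frac = 1.0 - (xs[None, :] ** 2 + ys[:, None] ** 2) / spec.radius**2
        bump = spec.height * np.clip(frac, 0.0, None)
        np.maximum(z[j0:j1, i0:i1], bump, out=z[j0:j1, i0:i1])
    return TongueMesh(x, y, z, resolution, field)


def export_obj(mesh: TongueMesh, path) -> None:
    """Write the heightfield as a triangulated Wavefront OBJ (y-up, mm)."""
    ny, nx = mesh.z.shape
    with open(path, "w") as fh:
        fh.write("# sweetdot tongue heightfield\n")
        for j in range(ny):
            for i in range(nx):
                fh.write(f"v {mesh.x[i]:.6f} {mesh.z[j, i]:.6f} {mesh.y[j]:.6f}\n")
        for j in range(ny - 1):
            for i in range(nx - 1):
                v00 = j * nx + i + 1
                v10 = v00 + 1
                v01 = v00 + nx
                v11 = v01 + 1
                fh.write(f"f {v00} {v10} {v11}\n")
                fh.write(f"f {v00} {v11} {v01}\n")


def load_obj(path) -> tuple[np.ndarray, np.ndarray]:
    """Read back OBJ vertices: (n, 3) positions (x, height, y) and faces."""
    verts = []
    faces = []
    with open(path) as fh:
        for line in fh:
            parts = line.split()
            if not parts:
                continue
            if parts[0] == "v":
                verts.append([float(p) for p in parts[1:4]])
            elif parts[0] == "f":
                faces.append([int(p.split("/")[0]) - 1 for p in parts[1:4]])
    return np.asarray(verts), np.asarray(faces, dtype=int)


def smear_exposure(
    pattern: DotPattern,
    drop_mass_ug: float = DEFAULT_DROP_MASS_UG,
    kinematics: ShearKinematics | None = None,
    grid_resolution: float = 0.5,
) -> ExposureMap:
    """Thaumatin exposure map after oscillatory shearing of a dotted sample.

    Each dot's thaumatin mass is spread uniformly over a segment of full
    length 2 x (A/2) centred on the dot along the oscillation axis (1-D box
    kernel, exact cell-overlap weights) and deposited at the dot's cross-axis
    cell.  For Layer the coat mass starts uniform over the plate face.  Total
    mass is conserved exactly.
    """
    kin = kinematics or ShearKinematics()
    geo = pattern.geometry
    dx = grid_resolution
    half = kin.half_amplitude
    if kin.axis == "x":
        long_extent, cross_extent = geo.length, geo.width
    else:
        long_extent, cross_extent = geo.width, geo.length
    n_long = int(math.ceil((long_extent + 2 * half) / dx))
    n_cross = int(math.ceil(cross_extent / dx))
    long_edges = -half + np.arange(n_long + 1) * dx
    mass = np.zeros((n_cross, n_long))

    def deposit(pos_long: float, pos_cross: float, m: float) -> None:
        if m <= 0:
            return
        row = min(max(int(pos_cross / dx), 0), n_cross - 1)
        lo, hi = pos_long - half, pos_long + half
        if hi == lo:  # degenerate zero-amplitude kernel: point deposit
            col = int(np.clip((pos_long - long_edges[0]) / dx, 0, n_long - 1))
            mass[row, col] += m
            return
        overlap = np.clip(np.minimum(long_edges[1:], hi) - np.maximum(long_edges[:-1], lo),
                          0.0, None)
        mass[row] += m * overlap / (hi - lo)

    if pattern.dots:
        for dot in pattern.dots:
            m = drop_mass_ug * dot.ink.effective_thaumatin
            if m == 0:
                continue
            pl = dot.center_x if kin.axis == "x" else dot.center_y
            pc = dot.center_y if kin.axis == "x" else dot.center_x
            deposit(pl, pc, m)
    elif pattern.layer_coat_mass_ug and pattern.layer_ink is not None:
        total = pattern.layer_coat_mass_ug * pattern.layer_ink.effective_thaumatin
        # uniform coat: one pseudo-source per surface cell
        n_src_long = int(math.ceil(long_extent / dx))
        src_long = (np.arange(n_src_long) + 0.5) * dx * long_extent / (n_src_long * dx)
        src_cross = (np.arange(n_cross) + 0.5) * dx
        m_cell = total / (n_src_long * n_cross)
        for pc in src_cross:
            for pl in src_long:
                deposit(pl, pc, m_cell)

    long_centers = (long_edges[:-1] + long_edges[1:]) / 2.0
    cross_centers = (np.arange(n_cross) + 0.5) * dx
    return ExposureMap(
        x=long_centers,
        y=cross_centers,
        mass=mass,
        cell_size=dx,
        region_boundary=long_extent / 2.0,
    )


def exposure_cv(exposure: ExposureMap) -> float:
    """Coefficient of variation of the along-axis concentration profile."""
    profile = exposure.mass.sum(axis=0)
    mean = profile.mean()
    if mean == 0:
        return float("nan")
    return float(profile.std() / mean)


def region_split(
    exposure: ExposureMap, boundary: float | None = None
) -> tuple[float, float]:
    """Mass fractions anterior (long-axis < boundary) / posterior of it."""
    b = exposure.region_boundary if boundary is None else boundary
    total = exposure.total_mass
    if total <= 0:
        warnings.warn("zero total mass: region fractions undefined", stacklevel=2)
        return (float("nan"), float("nan"))
    anterior = float(exposure.mass[:, exposure.x < b].sum())
    return (anterior / total, (total - anterior) / total)
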