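"""Synthetic fixtures with known ground truth for every other module.

Panel ratings are drawn as cell mean + Gaussian assessor effect + Gaussian
session effect + Gaussian residual, clipped to the 0-100 scale (clipping
fraction reported).  Dot image pairs and stained-tongue images are rendered
with exact geometric ground truth so the reconstruction and segmentation
pipelines can be round-trip tested without any external data.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .dotrecon import DotImageSet
from .sensory import RatingRecord, TIMEPOINTS, records_to_frame
from . import tongue as tongue_mod

__all__ = [
    "PanelConfig",
    "RatingsTable",
    "DotRenderConfig",
    "TongueRenderConfig",
    "MICRO_SAMPLES",
    "MESO_SAMPLES",
    "gen_ratings",
    "default_study_config",
    "render_dot",
    "render_tongue",
]

MICRO_SAMPLES = ("Bulk", "Homogeneous", "SpacedFull", "SpacedHalf", "SpacedQuarter", "Layer")
MESO_SAMPLES = ("Bulk", "Homogeneous", "Centered", "Periphery")


@dataclass(frozen=True)
class PanelConfig:
    n_assessors: int
    n_sessions: int
    samples: tuple[str, ...]
    cell_means: Mapping[tuple[str, str], float]  # (sample, timepoint) -> mean
    assessor_sd: float = 8.0
    session_sd: float = 0.0
    residual_sd: float = 10.0
    seed: int | None = 0

    def __post_init__(self) -> None:
        for key, m in self.cell_means.items():
            if not (0.0 <= m <= 100.0):
                raise ValueError(f"cell mean {m} for {key} outside [0, 100]")
        if min(self.assessor_sd, self.session_sd, self.residual_sd) < 0:
            raise ValueError("standard deviations must be >= 0")


@dataclass(frozen=True)
class RatingsTable:
    """Generated panel with the clipping fraction exposed."""

    records: tuple[RatingRecord, ...]
    clipped_fraction: float
    config: PanelConfig

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)

    def to_frame(self):
        return records_to_frame(self.records)


def gen_ratings(config: PanelConfig) -> RatingsTable:
    """Full-factorial assessor x sample x timepoint x session panel.

    Deterministic per seed; intensities are clipped to [0, 100] and the
    clipped fraction is reported on the returned table.
    """
    rng = np.random.default_rng(config.seed)
    n_a, n_s = config.n_assessors, config.n_sessions
    assessor_eff = rng.normal(0.0, config.assessor_sd, size=n_a) if config.assessor_sd else np.zeros(n_a)
    session_eff = rng.normal(0.0, config.session_sd, size=n_s) if config.session_sd else np.zeros(n_s)
    records: list[RatingRecord] = []
    clipped = 0
    for ai in range(n_a):
        assessor = f"A{ai + 1:02d}"
        for sample in config.samples:
            for tp in TIMEPOINTS:
                mean = config.cell_means[(sample, tp)]
                for si in range(n_s):
                    raw = (
                        mean
                        + assessor_eff[ai]
                        + session_eff[si]
                        + rng.normal(0.0, config.residual_sd)
                    )
                    val = min(max(raw, 0.0), 100.0)
                    if val != raw:
                        clipped += 1
                    records.append(RatingRecord(assessor, sample, si + 1, tp, val))
    frac = clipped / len(records) if records else 0.0
    return RatingsTable(tuple(records), frac, config)


def default_study_config(part: str, seed: int | None = 0) -> PanelConfig:
    """Declared panel fixtures encoding the study's printed effect ratios.

    micro: dotted samples at 4x the Bulk mean at t_start/t_max (+300 %) and
    3x at t_end (+200 %), dotted t_max anchored at the warm-up intensity 50.
    meso: Centered t_max at 0.76x Periphery (-24 %); dotted samples again 4x
    Bulk at t_max.  Absolute bar heights are fixtures, not measurements.
    """
    if part == "micro":
        bulk = {"start": 12.0, "max": 12.5, "end": 15.0}
        dotted = {"start": 48.0, "max": 50.0, "end": 45.0}
        means = {}
        for sample in MICRO_SAMPLES:
            src = bulk if sample == "Bulk" else dotted
            for tp in TIMEPOINTS:
                means[(sample, tp)] = src[tp]
        return PanelConfig(14, 2, MICRO_SAMPLES, means, seed=seed)
    if part == "meso":
        cells = {
            "Bulk": {"start": 12.0, "max": 12.5, "end": 15.0},
            "Homogeneous": {"start": 48.0, "max": 50.0, "end": 45.0},
            "Periphery": {"start": 46.0, "max": 50.0, "end": 42.0},
            "Centered": {"start": 36.0, "max": 38.0, "end": 32.0},
        }
        means = {
            (sample, tp): cells[sample][tp]
            for sample in MESO_SAMPLES
            for tp in TIMEPOINTS
        }
        return PanelConfig(17, 2, MESO_SAMPLES, means, seed=seed)
    raise ValueError(f"unknown study part {part!r}; expected 'micro' or 'meso'")


@dataclass(frozen=True)
class DotRenderConfig:
    a: float = 0.8        # mm
    h: float = 0.32       # mm
    scale: float = 0.01   # mm/px
    noise_sd: float = 0.0  # fraction of foreground/background contrast
    illumination_gradient: float = 0.0  # peak-to-peak fraction of contrast
    margin_mm: float = 0.3
    base_mm: float = 0.5  # side-view slab thickness below the baseline
    seed: int | None = 0

    def __post_init__(self) -> None:
        if min(self.a, self.h, self.scale) <= 0:
            raise ValueError("a, h and scale must be > 0")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")


def _decorate(img: np.ndarray, cfg: DotRenderConfig, rng) -> np.ndarray:
    out = img.astype(float)
    if cfg.illumination_gradient:
        ramp = np.linspace(-cfg.illumination_gradient / 2.0,
                           cfg.illumination_gradient / 2.0, img.shape[1])
        out = out + ramp[None, :]
    if cfg.noise_sd:
        out = out + rng.normal(0.0, cfg.noise_sd, size=img.shape)
    return out


def render_dot(config: DotRenderConfig) -> tuple[DotImageSet, dict]:
    """Render a top/side image pair for an ideal paraboloid dot.

    Top view: bright disk of radius ``a``.  Side view: bright silhouette of
    z = h (1 - x^2/a^2) sitting on a base slab.  Ground truth (a, h and the
    clean masks) is returned alongside.
    """
    cfg = config
    a_px = cfg.a / cfg.scale
    h_px = cfg.h / cfg.scale
    if a_px < 2 or h_px < 2:
        raise ValueError(
            f"dot unresolvable at scale {cfg.scale} mm/px: a={a_px:.1f} px, h={h_px:.1f} px"
        )
    rng = np.random.default_rng(cfg.seed)
    margin = cfg.margin_mm

    # top view
    w = int(round(2 * (cfg.a + margin) / cfg.scale))
    cx = w / 2.0
    yy, xx = np.mgrid[0:w, 0:w]
    top_mask = ((xx + 0.5 - cx) ** 2 + (yy + 0.5 - cx) ** 2) <= a_px**2
    top = _decorate(top_mask, cfg, rng)

    # side view
    width = int(round(2 * (cfg.a + margin) / cfg.scale))
    base_px = int(round(cfg.base_mm / cfg.scale))
    head_px = int(round(margin / cfg.scale))
    height = head_px + int(math.ceil(h_px)) + base_px
    baseline_row = head_px + int(math.ceil(h_px))
    side_mask = np.zeros((height, width), dtype=bool)
    side_mask[baseline_row:, :] = True
    xs = (np.arange(width) + 0.5 - width / 2.0) * cfg.scale
    inside = np.abs(xs) < cfg.a
    z_mm = np.where(inside, cfg.h * (1.0 - xs**2 / cfg.a**2), 0.0)
    z_px = np.round(z_mm / cfg.scale).astype(int)
    for col in np.flatnonzero(z_px > 0):
        side_mask[baseline_row - z_px[col]:baseline_row, col] = True
    side = _decorate(side_mask, cfg, rng)

    truth = {
        "a": cfg.a,
        "h": cfg.h,
        "top_mask": top_mask,
        "side_mask": side_mask,
        "baseline_row": baseline_row,
    }
    return DotImageSet(top, side, cfg.scale, provenance="synthetic"), truth


@dataclass(frozen=True)
class TongueRenderConfig:
    bbox: tuple[float, float] = (20.0, 15.0)  # mm
    n_fungiform: int = 12
    fungiform_radius: float = 0.5   # mm
    n_filiform: int = 80
    filiform_radius: float = 0.18   # mm
    scale: float = 0.02             # mm/px
    fungiform_level: float = 1.0
    filiform_level: float = 0.6
    noise_sd: float = 0.0
    min_distance: float | None = None
    seed: int | None = 0

    def __post_init__(self) -> None:
        if self.n_fungiform < 0 or self.n_filiform < 0:
            raise ValueError("papilla counts must be >= 0")
        if self.fungiform_radius <= self.filiform_radius:
            raise ValueError("size classes must be separable: fungiform radius larger")


def render_tongue(config: TongueRenderConfig) -> tuple[np.ndarray, list]:
    """Render a stained-tongue image: two disk populations on a dark field.

    Returns the image and the ground-truth list of (x, y, PapillaSpec)
    placements (reusing the tongue module's dart-throwing placement).
    """
    cfg = config
    wx, wy = cfg.bbox
    fu_spec = tongue_mod.PapillaSpec("fungiform", cfg.fungiform_radius, 0.39)
    fi_spec = tongue_mod.PapillaSpec("filiform", cfg.filiform_radius, 0.195)
    min_dist = cfg.min_distance
    if min_dist is None:
        min_dist = 2.0 * cfg.fungiform_radius + 2.0 * cfg.filiform_radius
    # keep whole disks inside the frame so counting stays exact
    inset = cfg.fungiform_radius + 2 * cfg.scale
    inner = (wx - 2 * inset, wy - 2 * inset)
    inner_area = inner[0] * inner[1]
    densities = {fu_spec: cfg.n_fungiform / inner_area, fi_spec: cfg.n_filiform / inner_area}
    fld0 = tongue_mod.place_papillae(densities, inner, min_dist, seed=cfg.seed)
    fld = tongue_mod.PapillaeField(
        cfg.bbox,
        tuple((x + inset, y + inset, spec) for x, y, spec in fld0.papillae),
        min_dist,
        cfg.seed,
    )

    h = int(round(wy / cfg.scale))
    w = int(round(wx / cfg.scale))
    img = np.zeros((h, w))
    yy, xx = np.mgrid[0:h, 0:w]
    px = (xx + 0.5) * cfg.scale
    py = (yy + 0.5) * cfg.scale
    for x, y, spec in fld.papillae:
        level = cfg.fungiform_level if spec.kind == "fungiform" else cfg.filiform_level
        disk = (px - x) ** 2 + (py - y) ** 2 <= spec.radius**2
        img[disk] = np.maximum(img[disk], level)
    if cfg.noise_sd:
        rng = np.random.default_rng(None if cfg.seed is None else cfg.seed + 1)
        img = img + rng.normal(0.0, cfg.noise_sd, size=img.shape)
    return img, list(fld.papillae)
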