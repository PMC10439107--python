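"""Bitmap-to-valve-schedule rasterization emulating the gantry inkjet workflow.

A binary bitmap is interpreted line by line, top to bottom; the scan direction
is inverted after every printed line (serpentine).  Each white pixel produces
one peak-and-hold valve event at the pixel centre, with the actuation position
offset against the travel direction so the drop (which inherits the head's
lateral velocity during its free flight) lands on the trigger position.
"""

from __future__ import annotations

import csv
import io
import json
import warnings
from dataclasses import dataclass, field, asdict
from typing import Sequence

import numpy as np

from .patterns import SampleGeometry

__all__ = [
    "PrintSettings",
    "ValveEvent",
    "PrintSchedule",
    "BitmapFormatError",
    "rasterize",
    "deflection_correction",
    "schedule_mass",
    "thaumatin_mass",
    "simulate_deposition",
    "schedule_to_csv",
    "schedule_to_json",
]


class BitmapFormatError(ValueError):
    """Raised for non-binary bitmap input."""


@dataclass(frozen=True)
class PrintSettings:
    """Gantry and valve parameters.

    Valve timing values (t_p/I_p/t_h/I_h) are placeholders carried through the
    schedule untouched; drop_speed is a free-flight estimate that only scales
    the deflection correction.
    """

    x_speed: float = 50.0       # mm/s
    y_speed: float = 200.0      # mm/s
    piston_height: float = 20.0  # mm
    drop_mass_ug: float = 390.0
    drop_speed: float = 1000.0  # mm/s
    peak_current_ma: float = 500.0
    peak_time_ms: float = 0.5
    hold_current_ma: float = 120.0
    hold_time_ms: float = 2.0
    pixel_pitch: float = 2.0    # mm/px

    def __post_init__(self) -> None:
        for name in ("x_speed", "y_speed", "piston_height", "drop_mass_ug",
                     "drop_speed", "pixel_pitch"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        if self.hold_time_ms < 0:
            raise ValueError("hold_time_ms must be >= 0")


@dataclass(frozen=True)
class ValveEvent:
    trigger_x: float
    trigger_y: float
    corrected_x: float
    corrected_y: float
    line_index: int
    direction: int  # +1 scanning towards +x, -1 towards -x
    t_p: float
    i_p: float
    t_h: float
    i_h: float
    drop_mass: float


@dataclass(frozen=True)
class PrintSchedule:
    events: tuple[ValveEvent, ...]
    settings: PrintSettings
    source_bitmap_shape: tuple[int, int]

    def __len__(self) -> int:
        return len(self.events)


def deflection_correction(
    lateral_velocity: float, piston_height: float, drop_speed: float
) -> float:
    """Lateral drop displacement (mm) accrued during free flight.

    The drop leaves the valve with the head's lateral velocity and falls the
    piston height at ``drop_speed``; the actuation point is shifted by this
    offset *against* the travel direction so the drop lands on the trigger
    position.
    """
    if drop_speed <= 0:
        raise ValueError("drop_speed must be > 0")
    if piston_height <= 0:
        raise ValueError("piston_height must be > 0")
    return lateral_velocity * piston_height / drop_speed


def _as_binary(bitmap: np.ndarray) -> np.ndarray:
    arr = np.asarray(bitmap)
    if arr.ndim != 2:
        raise BitmapFormatError(f"bitmap must be 2-D, got shape {arr.shape}")
    if arr.dtype == bool:
        return arr
    values = np.unique(arr)
    if set(values.tolist()) <= {0, 1}:
        return arr.astype(bool)
    if set(values.tolist()) <= {0, 255}:
        return arr > 0
    raise BitmapFormatError(
        f"bitmap is not binary (values {values[:8].tolist()}...); "
        "expected {0,1}, {0,255} or bool"
    )


def rasterize(
    bitmap: np.ndarray,
    settings: PrintSettings | None = None,
    geometry: SampleGeometry | None = None,
) -> PrintSchedule:
    """Turn a binary bitmap into a serpentine, line-major valve schedule.

    One event per white pixel; trigger positions are pixel centres scaled by
    ``settings.pixel_pitch``.  Empty lines are skipped without inverting the
    scan direction.  If ``geometry`` is given, corrected positions outside the
    printable region raise a warning listing the offending pixels.
    """
    settings = settings or PrintSettings()
    arr = _as_binary(bitmap)
    pitch = settings.pixel_pitch
    offset = deflection_correction(settings.x_speed, settings.piston_height,
                                   settings.drop_speed)
    events: list[ValveEvent] = []
    out_of_bounds: list[tuple[int, int]] = []
    direction = 1
    for row in range(arr.shape[0]):
        cols = np.flatnonzero(arr[row])
        if cols.size == 0:
            continue
        ordered = cols if direction == 1 else cols[::-1]
        ty = (row + 0.5) * pitch
        for col in ordered:
            tx = (col + 0.5) * pitch
            cx = tx - direction * offset
            if geometry is not None and not geometry.contains(cx, ty):
                out_of_bounds.append((row, int(col)))
            events.append(
                ValveEvent(
                    trigger_x=tx, trigger_y=ty,
                    corrected_x=cx, corrected_y=ty,
                    line_index=row, direction=direction,
                    t_p=settings.peak_time_ms, i_p=settings.peak_current_ma,
                    t_h=settings.hold_time_ms, i_h=settings.hold_current_ma,
                    drop_mass=settings.drop_mass_ug,
                )
            )
        direction = -direction
    if out_of_bounds:
        warnings.warn(
            f"{len(out_of_bounds)} corrected drop positions leave the printable "
            f"region: pixels {out_of_bounds[:10]}",
            stacklevel=2,
        )
    return PrintSchedule(tuple(events), settings, arr.shape)


def schedule_mass(schedule: PrintSchedule) -> float:
    """Total deposited ink mass (ug)."""
    return float(sum(ev.drop_mass for ev in schedule.events))


def thaumatin_mass(schedule: PrintSchedule, ink) -> float:
    """Thaumatin mass (ug) deposited when the schedule jets ``ink``."""
    return schedule_mass(schedule) * ink.effective_thaumatin


def simulate_deposition(
    schedule: PrintSchedule, jitter_sd_mm: float = 0.0, seed: int | None = None
) -> np.ndarray:
    """Realized drop centres: corrected positions plus isotropic Gaussian jitter.

    Returns an (n, 2) array; ``jitter_sd_mm == 0`` reproduces the corrected
    positions exactly.
    """
    if jitter_sd_mm < 0:
        raise ValueError("jitter_sd_mm must be >= 0")
    centers = np.array(
        [(ev.corrected_x, ev.corrected_y) for ev in schedule.events], dtype=float
    ).reshape(-1, 2)
    if jitter_sd_mm > 0:
        rng = np.random.default_rng(seed)
        centers = centers + rng.normal(0.0, jitter_sd_mm, size=centers.shape)
    return centers


_CSV_FIELDS = (
    "line_index", "direction", "trigger_x", "trigger_y",
    "corrected_x", "corrected_y", "t_p", "i_p", "t_h", "i_h", "drop_mass",
)


def schedule_to_csv(schedule: PrintSchedule) -> str:
    buf = io.StringIO()
    writer = csv.DictWriter(buf, fieldnames=_CSV_FIELDS)
    writer.writeheader()
    for ev in schedule.events:
        row = asdict(ev)
        writer.writerow({k: row[k] for k in _CSV_FIELDS})
    return buf.getvalue()


def schedule_to_json(schedule: PrintSchedule) -> str:
    return json.dumps(
        {
            "settings": asdict(schedule.settings),
            "source_bitmap_shape": list(schedule.source_bitmap_shape),
            "events": [asdict(ev) for ev in schedule.events],
        },
        indent=2,
    )
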