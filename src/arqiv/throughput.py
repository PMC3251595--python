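"""Plate-reader throughput model.

Screening capacity per reader is determined by the full-plate scan time
(which grows with scan pattern density and flash count), the well count,
and a flat robotics handling overhead of 15 seconds per 96-well plate:

    per_subject_s  = plate_scan_s / wells
    daily_capacity = floor( hours * 3600 / (per_subject_s + handling_s / wells) )

Raw, un-bucketed capacities are reported; published capacity figures are
lower bounds ("> N subjects/day") and should be checked with >=.  The
default assumes 24 h continuous operation — pass ``hours`` explicitly to
model a shorter screening day.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from .plate_io import ValidationError

__all__ = ["ThroughputEstimate", "per_subject_time", "daily_capacity", "estimate", "capacity_table"]


@dataclass(frozen=True)
class ThroughputEstimate:
    plate_scan_seconds: float
    wells_per_plate: int
    handling_seconds_per_plate: float
    hours_per_day: float
    per_subject_seconds: float
    daily_capacity: int

    def __post_init__(self) -> None:
        if min(
            self.plate_scan_seconds,
            self.wells_per_plate,
            self.handling_seconds_per_plate + 1,
            self.hours_per_day,
        ) <= 0:
            raise ValidationError("throughput inputs must be positive")


def per_subject_time(plate_scan_seconds: float, wells: int = 96) -> float:
    """Seconds of scan time per subject: full-plate scan time / wells.

    Returned at full precision; round to 2 decimals for display.
    """
    if wells < 1:
        raise ValidationError("wells must be >= 1")
    if plate_scan_seconds <= 0:
        raise ValidationError("plate scan time must be > 0")
    return plate_scan_seconds / wells


def daily_capacity(
    per_subject_s: float,
    handling_s: float = 15.0,
    wells: int = 96,
    hours: float = 24.0,
) -> int:
    """Subjects scannable per reader per day, with per-plate handling
    overhead amortized across wells."""
    if per_subject_s <= 0 or hours <= 0 or wells < 1 or handling_s < 0:
        raise ValidationError("throughput inputs must be positive")
    return math.floor(hours * 3600.0 / (per_subject_s + handling_s / wells))


def estimate(
    plate_scan_seconds: float,
    wells: int = 96,
    handling_s: float = 15.0,
    hours: float = 24.0,
) -> ThroughputEstimate:
    ps = per_subject_time(plate_scan_seconds, wells)
    return ThroughputEstimate(
        plate_scan_seconds=plate_scan_seconds,
        wells_per_plate=wells,
        handling_seconds_per_plate=handling_s,
        hours_per_day=hours,
        per_subject_seconds=ps,
        daily_capacity=daily_capacity(ps, handling_s, wells, hours),
    )


def capacity_table(
    scan_times: dict[str, float],
    wells: int = 96,
    handling_s: float = 15.0,
    hours: float = 24.0,
) -> str:
    """Human-readable capacity table for labelled full-plate scan times."""
    lines = [
        f"{'setting':<12} {'plate scan (s)':>14} {'per subject (s)':>16} {'capacity/day':>13}"
    ]
    for label, t in scan_times.items():
        e = estimate(t, wells=wells, handling_s=handling_s, hours=hours)
        lines.append(
            f"{label:<12} {t:>14.0f} {e.per_subject_seconds:>16.2f} {e.daily_capacity:>13,d}"
        )
    return "\n".join(lines)
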