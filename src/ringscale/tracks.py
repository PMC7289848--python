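"""Per-cell summaries from per-frame measurements.

Each cell is followed over the frames in which its ring is detected; the
per-cell statistic consumed by the scaling analysis is the median ring
diameter and the median mother-cell volume over those frames. Cells whose
ring was identified for fewer than 5 frames are rejected. Aging tracks are
normalized to the first division (d_norm = d/d(1), V_norm = V/V(1)), and
mutant populations are compared with a reference fit through the deviation
ratio measured/expected diameter.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np

from .geometry import CellGeometry
from .ring import RingMeasurement
from .scaling import PowerLawFit


@dataclass(frozen=True)
class CellTrack:
    """Ordered per-frame (ring measurement, geometry) pairs for one cell."""

    cell_id: str
    frames: tuple[tuple[RingMeasurement, CellGeometry], ...]

    def __post_init__(self) -> None:
        idx = [rm.frame for rm, _ in self.frames]
        if any(b <= a for a, b in zip(idx, idx[1:])):
            raise ValueError("frames must be strictly increasing")


@dataclass(frozen=True)
class CellSummary:
    """Per-cell medians over valid-ring frames."""

    cell_id: str
    median_diameter: float  # µm
    median_volume: float  # fL
    median_length: float  # µm
    median_intensity: float  # a.u.
    n_ring_frames: int
    accepted: bool


@dataclass(frozen=True)
class AgingRecord:
    """One generation of a replicatively aging mother cell."""

    cell_id: str
    generation: int  # 1-based
    volume_at_cytokinesis: float  # fL
    diameter: float  # µm
    daughter_volume: float = float("nan")  # fL
    d_norm: float = float("nan")
    v_norm: float = float("nan")


def aggregate_track(track: CellTrack, min_frames: int = 5) -> CellSummary:
    """Medians over frames with a valid ring detection.

    A track with no valid frame yields a rejected summary (NaN medians),
    not an exception; acceptance requires at least ``min_frames`` valid
    ring frames.
    """
    valid = [
        (rm, geo)
        for rm, geo in track.frames
        if rm.valid and not math.isnan(rm.diameter)
    ]
    n = len(valid)
    if n == 0:
        return CellSummary(
            track.cell_id, float("nan"), float("nan"), float("nan"), float("nan"), 0, False
        )
    med = lambda vals: float(np.median(vals))  # noqa: E731
    return CellSummary(
        cell_id=track.cell_id,
        median_diameter=med([rm.diameter for rm, _ in valid]),
        median_volume=med([g.volume for _, g in valid]),
        median_length=med([g.length for _, g in valid]),
        median_intensity=med([rm.total_intensity for rm, _ in valid]),
        n_ring_frames=n,
        accepted=n >= min_frames,
    )


def normalize_aging(records: Sequence[AgingRecord]) -> list[AgingRecord]:
    """Attach d_norm and V_norm relative to each cell's first division."""
    by_cell: dict[str, list[AgingRecord]] = {}
    for rec in records:
        by_cell.setdefault(rec.cell_id, []).append(rec)
    out: list[AgingRecord] = []
    for cell_id, recs in by_cell.items():
        recs = sorted(recs, key=lambda r: r.generation)
        first = next((r for r in recs if r.generation == 1), None)
        if first is None:
            raise ValueError(f"cell {cell_id!r} has no generation-1 record")
        for rec in recs:
            out.append(
                replace(
                    rec,
                    d_norm=rec.diameter / first.diameter,
                    v_norm=rec.volume_at_cytokinesis / first.volume_at_cytokinesis,
                )
            )
    return out


def deviation_ratio(summary: CellSummary, reference: PowerLawFit) -> float:
    """Measured diameter over the diameter expected from the reference fit
    at the same cell volume. 1.0 means the cell sits exactly on the fit."""
    if not (summary.median_volume > 0):
        raise ValueError("median volume must be positive")
    expected = float(reference.predict(summary.median_volume))
    return summary.median_diameter / expected
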