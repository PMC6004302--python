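"""Age-depth modelling from tie points, with hiatus (unconformity) support.

A model is piecewise linear between dated tie points within each continuous
depositional segment.  A hiatus splits the core into segments; querying a
depth below a hiatus whose underside carries no tie points returns a
:class:`BelowHiatus` sentinel carrying the qualitative age label (for the
Frame Lake core, ">7,000 BP") instead of a number.  Extrapolation beyond a
segment's dated range is refused.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core_io import AgeDepthTable, Hiatus, frame_lake_age_table

__all__ = [
    "AgeDepthModel",
    "BelowHiatus",
    "build_age_model",
    "sedimentation_rates",
    "frame_lake_age_model",
    "year_ad_to_bp",
]

BP_DATUM = 1950  # "before present" reference year


@dataclass(frozen=True)
class BelowHiatus:
    """Sentinel for depths under an unconformity with no dated floor."""

    depth: float
    hiatus_depth: float
    label: str

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return f"below unconformity at {self.hiatus_depth} cm, age {self.label}"


@dataclass
class AgeDepthModel:
    """Piecewise-linear interpolant over hiatus-delimited segments."""

    segments: list[AgeDepthTable]
    hiatuses: list[Hiatus] = field(default_factory=list)
    method: str = "piecewise-linear"

    @property
    def depth_range(self) -> tuple[float, float]:
        return (
            float(min(s.depths[0] for s in self.segments)),
            float(max(s.depths[-1] for s in self.segments)),
        )

    def assign_age(self, depth: float):
        """Calendar year AD at *depth*, or a :class:`BelowHiatus` sentinel."""
        for seg in self.segments:
            if seg.depths[0] <= depth <= seg.depths[-1]:
                return float(np.interp(depth, seg.depths, seg.years))
        for h in sorted(self.hiatuses, key=lambda h: h.depth):
            if depth > h.depth:
                deeper = [s for s in self.segments if s.depths[0] >= h.depth and s.depths[-1] >= depth]
                if not deeper:
                    return BelowHiatus(depth, h.depth, h.age_below_label or "undated")
        raise ValueError(f"depth {depth} outside the dated range; extrapolation refused")

    def table(self) -> pd.DataFrame:
        frames = [s.to_dataframe() for s in self.segments]
        return pd.concat(frames, ignore_index=True)


def build_age_model(
    table: AgeDepthTable, hiatuses: list[Hiatus] | None = None
) -> AgeDepthModel:
    """Split tie points at hiatuses and build the interpolant.

    Each continuous segment needs at least two tie points and strictly
    decreasing year with depth (already enforced by the table).
    """
    hiatuses = list(hiatuses) if hiatuses is not None else list(table.hiatuses)
    bounds = sorted(h.depth for h in hiatuses)
    lo, hi = table.depths[0], table.depths[-1]
    for h in hiatuses:
        if not (lo <= h.depth <= hi):
            raise ValueError(f"hiatus at {h.depth} cm outside the tie-point range")
    seg_idx = np.searchsorted(bounds, table.depths, side="left")
    segments = []
    for s in np.unique(seg_idx):
        mask = seg_idx == s
        if mask.sum() < 2:
            # a lone tie point sits on a segment edge; attach to neighbours
            # only when it is exactly a hiatus surface, else it is an error
            d = table.depths[mask][0]
            if d not in bounds:
                raise ValueError("a continuous segment needs >= 2 tie points")
        segments.append(
            AgeDepthTable(
                table.depths[mask],
                table.years[mask],
                rates=None if table.rates is None else table.rates[mask],
                ash_rates=None if table.ash_rates is None else table.ash_rates[mask],
            )
        )
    return AgeDepthModel(segments=segments, hiatuses=hiatuses)


def sedimentation_rates(model: AgeDepthModel) -> pd.DataFrame:
    """Interval sedimentation rates Δdepth/Δyear between successive tie points."""
    rows = []
    for seg in model.segments:
        for i in range(1, len(seg.depths)):
            dd = seg.depths[i] - seg.depths[i - 1]
            dy = seg.years[i - 1] - seg.years[i]  # years decrease with depth
            if dy == 0:
                raise ValueError(
                    f"zero time span between {seg.depths[i-1]} and {seg.depths[i]} cm"
                )
            rows.append(
                {
                    "depth_top": seg.depths[i - 1],
                    "depth_bottom": seg.depths[i],
                    "rate_cm_yr": dd / dy,
                }
            )
    return pd.DataFrame(rows)


def year_ad_to_bp(year_ad: float) -> float:
    """Calendar year AD to years before present (1950 datum)."""
    return BP_DATUM - year_ad


def frame_lake_age_model() -> AgeDepthModel:
    """The packaged Frame Lake model: 21 tie points above the 17 cm
    unconformity; below it the core is early Holocene (>7,000 BP)."""
    return build_age_model(frame_lake_age_table())
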