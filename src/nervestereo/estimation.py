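"""Density and total-number estimators.

The mean fiber density is the pooled ratio: total fibers counted in all
frames divided by the total frame area, reported in fibers/mm^2.  The
total number of myelinated fibers in the nerve is that density multiplied
by the whole-nerve cross-sectional area.  For electron microscopy the
nerve area measured at light microscopy is reused, since the EM screen
never images the whole nerve.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .counting import CountResult, SectionCounts
from .errors import EstimateError

__all__ = ["StereologyEstimate", "estimate_density", "estimate_total", "estimate"]

UM2_PER_MM2 = 1.0e6


@dataclass
class StereologyEstimate:
    """Density and total-number estimate for one nerve under one modality."""

    section_id: str
    modality: str
    total_counted: int
    total_frame_area: float  # um^2
    density_per_mm2: float
    nerve_area_um2: float
    total_fibers: float
    per_frame_counts: list[int] = field(default_factory=list)

    @property
    def total_fibers_rounded(self) -> int:
        return int(round(self.total_fibers))


def _as_results(counts) -> list[CountResult]:
    if isinstance(counts, SectionCounts):
        return counts.results
    return list(counts)


def estimate_density(counts) -> float:
    """Pooled fiber density in fibers/mm^2: sum of counts over sum of frame
    areas (ratio of sums, the standard pooling for systematic designs; for
    congruent frames it equals the mean of per-frame ratios)."""
    results = _as_results(counts)
    if not results:
        raise EstimateError("no counting frames")
    total_area = float(sum(r.frame_area for r in results))
    if total_area <= 0:
        raise EstimateError("total frame area must be positive")
    total = sum(r.n_counted for r in results)
    return total / total_area * UM2_PER_MM2


def estimate_total(density_per_mm2: float, nerve_area_um2: float) -> float:
    """Total fiber number: density times whole-nerve cross-sectional area."""
    if density_per_mm2 < 0:
        raise EstimateError("density must be non-negative")
    if nerve_area_um2 <= 0:
        raise EstimateError("nerve area must be positive")
    return density_per_mm2 * nerve_area_um2 / UM2_PER_MM2


def estimate(
    counts,
    nerve_area_um2: float,
    section_id: str = "",
    modality: str = "LM",
) -> StereologyEstimate:
    """Bundle density and total-number estimation for one section."""
    results = _as_results(counts)
    density = estimate_density(results)
    total = estimate_total(density, nerve_area_um2)
    return StereologyEstimate(
        section_id=section_id,
        modality=modality,
        total_counted=int(sum(r.n_counted for r in results)),
        total_frame_area=float(sum(r.frame_area for r in results)),
        density_per_mm2=density,
        nerve_area_um2=nerve_area_um2,
        total_fibers=total,
        per_frame_counts=[r.n_counted for r in results],
    )
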