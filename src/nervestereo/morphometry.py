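"""Per-fiber size parameters from axon and fiber areas.

For each counted fiber the axon and fiber cross-sectional areas are
measured; the circle-fitting (equal-area) diameters

    d = 2 * sqrt(axon_area / pi),    D = 2 * sqrt(fiber_area / pi)

then give the myelin thickness (D - d) / 2 and the g-ratio, by the
universal convention the dimensionless ratio g = d / D in (0, 1).  (The
inverse convention ``D_over_d`` is also selectable; see the methods note
for why the package defaults to d / D.)
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import MeasureError
from .synthetic import NerveSection

__all__ = [
    "FiberMeasurement",
    "circle_fit_diameter",
    "measure_fiber",
    "measure_section_fibers",
    "summarize_measurements",
]

_SIZE_COLUMNS = ["d_um", "D_um", "myelin_um", "g_ratio"]


@dataclass(frozen=True)
class FiberMeasurement:
    """Morphometry record for one counted fiber (lengths um, areas um^2)."""

    fiber_id: int
    axon_area: float
    fiber_area: float
    d: float
    D: float
    myelin_thickness: float
    g_ratio: float


def circle_fit_diameter(area: float) -> float:
    """Diameter of the circle with the given area: ``2 * sqrt(area / pi)``."""
    if area <= 0:
        raise MeasureError(f"area must be positive, got {area}")
    return 2.0 * math.sqrt(area / math.pi)


def measure_fiber(
    axon_area: float,
    fiber_area: float,
    fiber_id: int = 0,
    g_ratio_convention: str = "d_over_D",
) -> FiberMeasurement:
    """Full morphometry of one fiber from its two profile areas."""
    if axon_area <= 0:
        raise MeasureError(f"axon area must be positive, got {axon_area}")
    if axon_area >= fiber_area:
        raise MeasureError(
            f"axon area {axon_area} must be smaller than fiber area "
            f"{fiber_area} (myelin thickness would be non-positive)"
        )
    d = circle_fit_diameter(axon_area)
    D = circle_fit_diameter(fiber_area)
    if g_ratio_convention == "d_over_D":
        g = d / D
    elif g_ratio_convention == "D_over_d":
        g = D / d
    else:
        raise MeasureError(f"unknown g_ratio_convention {g_ratio_convention!r}")
    return FiberMeasurement(
        fiber_id=fiber_id,
        axon_area=axon_area,
        fiber_area=fiber_area,
        d=d,
        D=D,
        myelin_thickness=(D - d) / 2.0,
        g_ratio=g,
    )


def measure_section_fibers(
    section: NerveSection,
    fiber_ids=None,
    *,
    area_noise_sigma: float = 0.0,
    rng: np.random.Generator | None = None,
    g_ratio_convention: str = "d_over_D",
) -> pd.DataFrame:
    """Morphometry table for (a subset of) a section's fibers.

    Areas are derived from the ground-truth diameters, ``pi (d/2)^2`` and
    ``pi (D/2)^2``.  ``area_noise_sigma`` applies independent multiplicative
    lognormal noise to each area to emulate manual tracing error (default
    0: exact areas).
    """
    if fiber_ids is None:
        mask = np.ones(section.n_fibers, dtype=bool)
    else:
        mask = np.isin(section.fiber_id, np.asarray(list(fiber_ids)))
    d = section.d[mask]
    D = section.D[mask]
    ids = section.fiber_id[mask]
    axon_area = math.pi * (d / 2.0) ** 2
    fiber_area = math.pi * (D / 2.0) ** 2
    if area_noise_sigma > 0.0:
        if rng is None:
            rng = np.random.default_rng()
        axon_area = axon_area * np.exp(rng.normal(0, area_noise_sigma, d.size))
        fiber_area = fiber_area * np.exp(rng.normal(0, area_noise_sigma, d.size))
        bad = axon_area >= fiber_area
        # noise must never invert the axon/fiber order; redraw offenders
        while np.any(bad):
            axon_area[bad] = (
                math.pi * (d[bad] / 2.0) ** 2
                * np.exp(rng.normal(0, area_noise_sigma, int(bad.sum())))
            )
            fiber_area[bad] = (
                math.pi * (D[bad] / 2.0) ** 2
                * np.exp(rng.normal(0, area_noise_sigma, int(bad.sum())))
            )
            bad = axon_area >= fiber_area
    rows = [
        measure_fiber(a, fa, fiber_id=int(i), g_ratio_convention=g_ratio_convention)
        for i, a, fa in zip(ids, axon_area, fiber_area)
    ]
    return pd.DataFrame(
        {
            "fiber_id": [m.fiber_id for m in rows],
            "axon_area_um2": [m.axon_area for m in rows],
            "fiber_area_um2": [m.fiber_area for m in rows],
            "d_um": [m.d for m in rows],
            "D_um": [m.D for m in rows],
            "myelin_um": [m.myelin_thickness for m in rows],
            "g_ratio": [m.g_ratio for m in rows],
        }
    )


def summarize_measurements(measurements) -> pd.DataFrame:
    """Mean and sample SD (n-1 denominator) of d, D, myelin thickness and
    g-ratio over a set of fiber measurements.

    Accepts either a DataFrame from :func:`measure_section_fibers` or a
    list of :class:`FiberMeasurement`.
    """
    if isinstance(measurements, pd.DataFrame):
        df = measurements
    else:
        df = pd.DataFrame(
            {
                "d_um": [m.d for m in measurements],
                "D_um": [m.D for m in measurements],
                "myelin_um": [m.myelin_thickness for m in measurements],
                "g_ratio": [m.g_ratio for m in measurements],
            }
        )
    if len(df) == 0:
        raise MeasureError("cannot summarize zero measurements")
    out = pd.DataFrame(
        {
            "parameter": _SIZE_COLUMNS,
            "n": len(df),
            "mean": [df[c].mean() for c in _SIZE_COLUMNS],
            "sd": [df[c].std(ddof=1) if len(df) > 1 else 0.0 for c in _SIZE_COLUMNS],
        }
    )
    return out
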