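"""Synthetic nerve cross-sections with known ground truth.

A section is a circular nerve boundary densely populated with
non-overlapping myelinated fibers, each modelled as two concentric disks:
the axon (diameter ``d``) inside its myelin sheath (outer fiber diameter
``D``).  Two phenotypes are provided: an uninjured *control* nerve and a
*regenerated* nerve 25 days after a crush injury, which carries the same
number of fibers but with smaller axon and fiber diameters and thinner
myelin (higher g-ratio).  Each phenotype additionally contains a
sub-resolution tail of very small fibers that only electron microscopy can
resolve; this tail is what drives the systematic light-microscopy
undercount studied downstream.

All coordinates and lengths are in micrometres, with the origin at the
nerve center and y increasing upward.  Geometry is continuous and
vector-based; rasterization (:func:`render_section`) is presentation-only.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Iterator, Mapping

import numpy as np
import pandas as pd

from .errors import DistributionError, PackingError, RenderError

__all__ = [
    "DistributionSpec",
    "FiberPhenotypeParams",
    "Fiber",
    "NerveSection",
    "control_params",
    "regenerated_params",
    "generate_section",
    "section_to_table",
    "table_to_section",
    "render_section",
    "DEFAULT_NERVE_RADIUS_UM",
]

#: Default nerve cross-section radius (um).  Chosen so that the default
#: 1200-fiber control population packs at ~0.40 area fraction, comfortably
#: below the random-sequential-adsorption feasibility limit, while keeping
#: the fiber density in the 10^4/mm^2 range typical of rodent nerve.
DEFAULT_NERVE_RADIUS_UM = 160.0

_MAX_REJECTION_ROUNDS = 200


@dataclass(frozen=True)
class DistributionSpec:
    """Parametric 1-D distribution with optional strict support bounds.

    Families
    --------
    ``constant``   params: ``value``
    ``normal``     params: ``mean``, ``sd``
    ``lognormal``  params: ``median``, ``sigma_log``  (so that
                   ``ln X ~ Normal(ln median, sigma_log)``)

    ``low``/``high`` truncate the distribution to the open interval
    ``(low, high)`` by rejection resampling.
    """

    family: str
    params: Mapping[str, float]
    low: float | None = None
    high: float | None = None

    def __post_init__(self) -> None:
        p = dict(self.params)
        if self.family == "constant":
            required = {"value"}
        elif self.family == "normal":
            required = {"mean", "sd"}
        elif self.family == "lognormal":
            required = {"median", "sigma_log"}
        else:
            raise DistributionError(f"unknown distribution family {self.family!r}")
        if set(p) != required:
            raise DistributionError(
                f"{self.family} distribution needs params {sorted(required)}, "
                f"got {sorted(p)}"
            )
        if self.family == "normal" and p["sd"] < 0:
            raise DistributionError("normal sd must be >= 0")
        if self.family == "lognormal" and (p["median"] <= 0 or p["sigma_log"] < 0):
            raise DistributionError("lognormal needs median > 0 and sigma_log >= 0")
        if self.low is not None and self.high is not None and self.low >= self.high:
            raise DistributionError("empty truncation interval")
        if self.family == "constant" and not self._in_support(p["value"]):
            raise DistributionError("constant value outside truncation interval")

    def _in_support(self, x: float) -> bool:
        if self.low is not None and x <= self.low:
            return False
        if self.high is not None and x >= self.high:
            return False
        return True

    def _draw_raw(self, rng: np.random.Generator, n: int) -> np.ndarray:
        p = self.params
        if self.family == "constant":
            return np.full(n, float(p["value"]))
        if self.family == "normal":
            return rng.normal(p["mean"], p["sd"], size=n)
        return np.exp(rng.normal(np.log(p["median"]), p["sigma_log"], size=n))

    def draw(self, rng: np.random.Generator, n: int) -> np.ndarray:
        """Draw ``n`` values, rejection-resampling any outside the support."""
        out = self._draw_raw(rng, n)
        if self.low is None and self.high is None:
            return out
        for _ in range(_MAX_REJECTION_ROUNDS):
            bad = ~(
                ((out > self.low) if self.low is not None else True)
                & ((out < self.high) if self.high is not None else True)
            )
            n_bad = int(np.count_nonzero(bad))
            if n_bad == 0:
                return out
            out[bad] = self._draw_raw(rng, n_bad)
        raise DistributionError(
            f"rejection sampling from {self.family} into "
            f"({self.low}, {self.high}) did not converge"
        )

    def mean(self) -> float:
        """Closed-form mean of the *untruncated* distribution."""
        p = self.params
        if self.family == "constant":
            return float(p["value"])
        if self.family == "normal":
            return float(p["mean"])
        return float(p["median"] * math.exp(p["sigma_log"] ** 2 / 2.0))


@dataclass(frozen=True)
class FiberPhenotypeParams:
    """Distributional description of one experimental group's fibers.

    ``axon_diameter_dist`` governs the main (LM-resolvable) population;
    ``small_axon_diameter_dist`` governs the sub-resolution tail, a fraction
    ``small_fiber_fraction`` of all fibers whose axon diameters fall below
    the light-microscopy detection limit.  g-ratios (axon/fiber diameter)
    are drawn independently of axon diameter; the outer fiber diameter is
    ``D = d / g``.
    """

    group_label: str
    axon_diameter_dist: DistributionSpec
    g_ratio_dist: DistributionSpec
    target_fiber_count: int
    small_fiber_fraction: float = 0.0
    small_axon_diameter_dist: DistributionSpec | None = None

    def __post_init__(self) -> None:
        if self.group_label not in ("control", "regenerated"):
            raise DistributionError("group_label must be 'control' or 'regenerated'")
        if self.target_fiber_count < 0:
            raise DistributionError("target_fiber_count must be non-negative")
        if not 0.0 <= self.small_fiber_fraction <= 1.0:
            raise DistributionError("small_fiber_fraction must lie in [0, 1]")
        if self.small_fiber_fraction > 0 and self.small_axon_diameter_dist is None:
            raise DistributionError(
                "small_fiber_fraction > 0 requires small_axon_diameter_dist"
            )

    def scaled(self, size_multiplier: float) -> "FiberPhenotypeParams":
        """Return a copy with all diameter scales multiplied (animal effect)."""

        def scale(spec: DistributionSpec | None) -> DistributionSpec | None:
            if spec is None:
                return None
            p = dict(spec.params)
            if spec.family == "lognormal":
                p["median"] *= size_multiplier
            elif spec.family == "normal":
                p["mean"] *= size_multiplier
                p["sd"] *= size_multiplier
            else:
                p["value"] *= size_multiplier
            lo = None if spec.low is None else spec.low * size_multiplier
            hi = None if spec.high is None else spec.high * size_multiplier
            return DistributionSpec(spec.family, p, low=lo, high=hi)

        return replace(
            self,
            axon_diameter_dist=scale(self.axon_diameter_dist),
            small_axon_diameter_dist=scale(self.small_axon_diameter_dist),
        )


def control_params(target_fiber_count: int = 1200) -> FiberPhenotypeParams:
    """Default uninjured-nerve phenotype (artifact defaults, configurable)."""
    return FiberPhenotypeParams(
        group_label="control",
        axon_diameter_dist=DistributionSpec(
            "lognormal", {"median": 3.5, "sigma_log": 0.35}, low=0.0
        ),
        g_ratio_dist=DistributionSpec(
            "normal", {"mean": 0.65, "sd": 0.05}, low=0.4, high=0.85
        ),
        target_fiber_count=target_fiber_count,
        small_fiber_fraction=0.15,
        small_axon_diameter_dist=DistributionSpec(
            "lognormal", {"median": 0.35, "sigma_log": 0.2}, low=0.0
        ),
    )


def regenerated_params(target_fiber_count: int = 1200) -> FiberPhenotypeParams:
    """Default 25-day post-crush phenotype: same fiber count as control but
    smaller axons, smaller fibers and thinner myelin (higher g-ratio).

    The sub-resolution fraction matches the control default: regenerated
    and uninjured nerves show the same total count at *both* LM and EM, so
    the share of fibers below the LM limit must be comparable across
    groups; only the resolvable fibers' size distributions differ.
    """
    return FiberPhenotypeParams(
        group_label="regenerated",
        axon_diameter_dist=DistributionSpec(
            "lognormal", {"median": 2.2, "sigma_log": 0.35}, low=0.0
        ),
        g_ratio_dist=DistributionSpec(
            "normal", {"mean": 0.75, "sd": 0.05}, low=0.4, high=0.95
        ),
        target_fiber_count=target_fiber_count,
        small_fiber_fraction=0.15,
        small_axon_diameter_dist=DistributionSpec(
            "lognormal", {"median": 0.35, "sigma_log": 0.2}, low=0.0
        ),
    )


@dataclass(frozen=True)
class Fiber:
    """One myelinated fiber: concentric axon (d) and fiber (D) disks."""

    id: int
    center_x: float
    center_y: float
    axon_diameter: float
    fiber_diameter: float

    def __post_init__(self) -> None:
        if not 0.0 < self.axon_diameter < self.fiber_diameter:
            raise ValueError(
                f"fiber {self.id}: need 0 < d < D, got "
                f"d={self.axon_diameter}, D={self.fiber_diameter}"
            )


@dataclass
class NerveSection:
    """Ground-truth cross-section: nerve boundary disk plus fiber population.

    Fibers are stored as parallel numpy arrays for efficient geometric
    queries; :attr:`fibers` materializes :class:`Fiber` records on demand.
    """

    section_id: str
    nerve_radius: float
    fiber_id: np.ndarray
    x: np.ndarray
    y: np.ndarray
    d: np.ndarray
    D: np.ndarray
    nerve_center_x: float = 0.0
    nerve_center_y: float = 0.0
    cross_sectional_area: float | None = None
    rng_seed: int | None = None

    def __post_init__(self) -> None:
        self.fiber_id = np.asarray(self.fiber_id, dtype=np.int64)
        for name in ("x", "y", "d", "D"):
            setattr(self, name, np.asarray(getattr(self, name), dtype=float))
        if self.cross_sectional_area is None:
            self.cross_sectional_area = math.pi * self.nerve_radius**2

    @property
    def n_fibers(self) -> int:
        return int(self.fiber_id.size)

    @property
    def fibers(self) -> list[Fiber]:
        return [
            Fiber(int(i), float(x), float(y), float(d), float(D))
            for i, x, y, d, D in zip(self.fiber_id, self.x, self.y, self.d, self.D)
        ]

    def __iter__(self) -> Iterator[Fiber]:
        return iter(self.fibers)

    def subset(self, mask: np.ndarray, section_id: str | None = None) -> "NerveSection":
        """A new section keeping only the fibers selected by ``mask``.

        Nerve geometry (radius, center, cross-sectional area) is preserved:
        detection filters change what an observer sees, not the nerve.
        """
        return NerveSection(
            section_id=section_id or self.section_id,
            nerve_radius=self.nerve_radius,
            fiber_id=self.fiber_id[mask],
            x=self.x[mask],
            y=self.y[mask],
            d=self.d[mask],
            D=self.D[mask],
            nerve_center_x=self.nerve_center_x,
            nerve_center_y=self.nerve_center_y,
            cross_sectional_area=self.cross_sectional_area,
            rng_seed=self.rng_seed,
        )

    def validate(self) -> None:
        """Raise ValueError if any section invariant is violated."""
        if np.unique(self.fiber_id).size != self.n_fibers:
            raise ValueError("fiber ids are not unique")
        if not np.all((self.d > 0) & (self.d < self.D)):
            raise ValueError("need 0 < d < D for every fiber")
        r = self.D / 2.0
        dist = np.hypot(self.x - self.nerve_center_x, self.y - self.nerve_center_y)
        if not np.all(dist + r <= self.nerve_radius + 1e-9):
            raise ValueError("some fiber disk crosses the nerve boundary")
        if self.n_fibers > 1:
            # pairwise strict disk disjointness
            dx = self.x[:, None] - self.x[None, :]
            dy = self.y[:, None] - self.y[None, :]
            rr = r[:, None] + r[None, :]
            sep = dx**2 + dy**2 - rr**2
            np.fill_diagonal(sep, np.inf)
            if np.any(sep < -1e-9):
                raise ValueError("overlapping fiber disks")
        total_fiber_area = float(np.sum(math.pi * r**2))
        if self.cross_sectional_area <= total_fiber_area and self.n_fibers:
            raise ValueError("fiber area exceeds nerve cross-sectional area")


def _draw_diameters(
    params: FiberPhenotypeParams, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """Draw (d, D) for the whole population: main component plus the
    sub-resolution tail, in random order."""
    n = params.target_fiber_count
    n_small = int(rng.binomial(n, params.small_fiber_fraction)) if n else 0
    d_main = params.axon_diameter_dist.draw(rng, n - n_small)
    if n_small:
        d_small = params.small_axon_diameter_dist.draw(rng, n_small)
        d = np.concatenate([d_main, d_small])
    else:
        d = d_main
    if np.any(d <= 0):
        raise DistributionError("axon diameter draw produced non-positive value")
    g_spec = params.g_ratio_dist
    # enforce the open-(0,1) support required of any g-ratio distribution
    lo = 0.0 if g_spec.low is None else max(0.0, g_spec.low)
    hi = 1.0 if g_spec.high is None else min(1.0, g_spec.high)
    g_spec = DistributionSpec(g_spec.family, g_spec.params, low=lo, high=hi)
    g = g_spec.draw(rng, n)
    return d, d / g


def generate_section(
    params: FiberPhenotypeParams,
    nerve_radius: float = DEFAULT_NERVE_RADIUS_UM,
    seed: int = 0,
    *,
    section_id: str | None = None,
    packing_limit: float = 0.55,
    max_attempts: int = 10_000,
) -> NerveSection:
    """Pack a fiber population into a circular nerve section.

    Diameters are drawn first; fibers are then placed by random sequential
    adsorption, largest first, with uniform candidate centers inside the
    region where the whole fiber disk fits, rejecting overlaps.  The result
    is deterministic given ``seed``.

    Raises
    ------
    PackingError
        If the drawn population exceeds ``packing_limit`` of the nerve
        area, if a fiber cannot fit inside the nerve at all, or if a
        placement exceeds ``max_attempts`` candidate draws.
    """
    if nerve_radius <= 0:
        raise PackingError("nerve_radius must be positive")
    rng = np.random.default_rng(seed)
    d, D = _draw_diameters(params, rng)

    nerve_area = math.pi * nerve_radius**2
    fiber_area = float(np.sum(math.pi * (D / 2.0) ** 2))
    if fiber_area >= packing_limit * nerve_area:
        raise PackingError(
            f"fiber area {fiber_area:.1f} um^2 exceeds packing limit "
            f"{packing_limit:.2f} x nerve area {nerve_area:.1f} um^2"
        )

    order = np.argsort(-D, kind="stable")  # largest first
    d, D = d[order], D[order]
    n = d.size
    r = D / 2.0
    px = np.empty(n)
    py = np.empty(n)
    for i in range(n):
        max_center = nerve_radius - r[i]
        if max_center < 0:
            raise PackingError(
                f"fiber of diameter {D[i]:.3g} um cannot fit inside a nerve "
                f"of radius {nerve_radius:.3g} um"
            )
        placed = False
        for _ in range(max_attempts):
            rad = max_center * math.sqrt(rng.uniform())
            theta = rng.uniform(0.0, 2.0 * math.pi)
            cx = rad * math.cos(theta)
            cy = rad * math.sin(theta)
            if i:
                min_gap = (r[:i] + r[i]) ** 2
                if np.any((px[:i] - cx) ** 2 + (py[:i] - cy) ** 2 < min_gap):
                    continue
            px[i], py[i] = cx, cy
            placed = True
            break
        if not placed:
            raise PackingError(
                f"could not place fiber {i} (D={D[i]:.3g} um) "
                f"within {max_attempts} attempts"
            )

    return NerveSection(
        section_id=section_id or f"{params.group_label}-s{seed}",
        nerve_radius=nerve_radius,
        fiber_id=np.arange(n, dtype=np.int64),
        x=px,
        y=py,
        d=d,
        D=D,
        rng_seed=seed,
    )


_TABLE_COLUMNS = ["fiber_id", "x_um", "y_um", "axon_diameter_um", "fiber_diameter_um"]


def section_to_table(section: NerveSection) -> pd.DataFrame:
    """One row per fiber; round-trips losslessly with :func:`table_to_section`."""
    return pd.DataFrame(
        {
            "fiber_id": section.fiber_id,
            "x_um": section.x,
            "y_um": section.y,
            "axon_diameter_um": section.d,
            "fiber_diameter_um": section.D,
        }
    )


def table_to_section(
    table: pd.DataFrame,
    *,
    section_id: str = "imported",
    nerve_radius: float | None = None,
    cross_sectional_area: float | None = None,
    nerve_center: tuple[float, float] = (0.0, 0.0),
    rng_seed: int | None = None,
) -> NerveSection:
    """Build a :class:`NerveSection` from a fiber table (see io module for
    file-level parsing and validation)."""
    if nerve_radius is None:
        # smallest disk about the given center enclosing all fiber disks
        if len(table):
            dist = np.hypot(
                table["x_um"].to_numpy() - nerve_center[0],
                table["y_um"].to_numpy() - nerve_center[1],
            )
            nerve_radius = float(
                np.max(dist + table["fiber_diameter_um"].to_numpy() / 2.0)
            )
        else:
            nerve_radius = 1.0
    return NerveSection(
        section_id=section_id,
        nerve_radius=nerve_radius,
        fiber_id=table["fiber_id"].to_numpy(),
        x=table["x_um"].to_numpy(),
        y=table["y_um"].to_numpy(),
        d=table["axon_diameter_um"].to_numpy(),
        D=table["fiber_diameter_um"].to_numpy(),
        nerve_center_x=nerve_center[0],
        nerve_center_y=nerve_center[1],
        cross_sectional_area=cross_sectional_area,
        rng_seed=rng_seed,
    )


def render_section(
    section: NerveSection,
    pixel_size: float,
    *,
    pixel_budget: int = 64_000_000,
    background: int = 245,
    endoneurium: int = 220,
    myelin: int = 50,
    axoplasm: int = 200,
) -> np.ndarray:
    """Rasterize a section to an 8-bit grayscale image (toluidine-blue look:
    light background, dark myelin annuli, pale axon lumina).

    Pixel (row 0, col 0) is the top-left corner; rows map to decreasing y.
    """
    if pixel_size <= 0:
        raise RenderError("pixel_size must be positive")
    half = section.nerve_radius + 2.0 * pixel_size
    npix = int(math.ceil(2.0 * half / pixel_size))
    if npix * npix > pixel_budget:
        raise RenderError(
            f"image of {npix}x{npix} px exceeds pixel budget {pixel_budget}"
        )
    img = np.full((npix, npix), background, dtype=np.uint8)
    # pixel-center coordinates
    xs = -half + (np.arange(npix) + 0.5) * pixel_size + section.nerve_center_x
    ys = half - (np.arange(npix) + 0.5) * pixel_size + section.nerve_center_y
    yy = ys[:, None]
    xx = xs[None, :]
    inside = (xx - section.nerve_center_x) ** 2 + (
        yy - section.nerve_center_y
    ) ** 2 <= section.nerve_radius**2
    img[inside] = endoneurium
    for cx, cy, dax, dfib in zip(section.x, section.y, section.d, section.D):
        rf = dfib / 2.0
        c0 = max(0, int((cx - rf - xs[0]) / pixel_size))
        c1 = min(npix, int((cx + rf - xs[0]) / pixel_size) + 2)
        r0 = max(0, int((ys[0] - (cy + rf)) / pixel_size))
        r1 = min(npix, int((ys[0] - (cy - rf)) / pixel_size) + 2)
        sub_x = xs[c0:c1][None, :]
        sub_y = ys[r0:r1][:, None]
        rho2 = (sub_x - cx) ** 2 + (sub_y - cy) ** 2
        block = img[r0:r1, c0:c1]
        block[rho2 <= rf**2] = myelin
        block[rho2 <= (dax / 2.0) ** 2] = axoplasm
    return img
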