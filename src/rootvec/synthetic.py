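"""Seeded generators for maize-like root systems and soil-water map series.

This is the fixture engine of the package: it produces root systems with
known ground truth (architecture parameters), splits them into the partial
tracings the split-and-combine workflow starts from, renders binary masks
(the raster a flatbed scan analysis would see), and synthesizes time series
of radially depleting soil-water maps around the roots.

The growth model is deliberately minimal — a heading-update random walk with
gravitropic pull and Poisson lateral branching — not a published
functional-structural model; its only job is realistic-looking fixtures with
known parameters. Architecture targets a 20-day maize plant: one primary
axis, 2-3 seminal and 2-4 adventitious axes (5-8 first-order axes in all),
with laterals to order 3 inside a 50 x 50 cm rhizotron.

All draws come from a single ``numpy.random.default_rng(seed)`` stream in a
fixed order (axis counts first, then each axis and its laterals depth-first),
so outputs are reproducible bit-for-bit for a given seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .errors import ParameterError
from .root_model import (
    PartialTracing,
    Root,
    RootNode,
    RootSystem,
    require_valid,
)
from .soil_cross import GridGeometry, SoilGrid, distance_map

__all__ = [
    "ArchitectureParams",
    "WaterModelParams",
    "generate_root_system",
    "split_system",
    "render_mask",
    "mask_area",
    "generate_water_series",
]


@dataclass
class ArchitectureParams:
    """Parameters of the maize-like root-system generator (lengths in cm).

    ``gravitropism`` is the fraction of the current angle-to-vertical removed
    per growth step (0 = none, 1 = instant verticalization); diameters taper
    linearly tipward by ``taper_fraction``. Base diameters are deliberately
    on the thick side of real maize so that laterals stay resolvable when
    systems are rasterized at 5-10 px/cm (see render_mask).
    """

    n_primary: int = 1
    seminal_range: tuple[int, int] = (2, 3)
    adventitious_range: tuple[int, int] = (2, 4)
    step_length: float = 0.5
    gravitropism: dict[int, float] = field(
        default_factory=lambda: {1: 0.02, 2: 0.01, 3: 0.0}
    )
    heading_noise_sd: dict[int, float] = field(  # degrees per step
        default_factory=lambda: {1: 3.0, 2: 10.0, 3: 14.0}
    )
    lateral_density: dict[int, float] = field(  # laterals per cm of parent
        default_factory=lambda: {1: 0.8, 2: 0.3}
    )
    apical_zone: dict[int, float] = field(  # unbranched cm behind the tip
        default_factory=lambda: {1: 4.0, 2: 2.0}
    )
    base_diameter: dict[int, float] = field(
        default_factory=lambda: {1: 0.45, 2: 0.2, 3: 0.1}
    )
    taper_fraction: float = 0.2
    diameter_jitter_sd: float = 0.08  # relative sd of per-root diameter jitter
    length_range: dict[int, tuple[float, float]] = field(
        default_factory=lambda: {1: (35.0, 50.0), 2: (3.0, 8.0), 3: (0.5, 2.5)}
    )
    max_order: int = 3
    extent: tuple[float, float] = (50.0, 50.0)
    seed: int = 42

    def validate(self) -> None:
        if self.step_length <= 0:
            raise ParameterError("step_length must be > 0")
        if not (1 <= self.max_order <= 3):
            raise ParameterError("max_order must be in 1..3")
        for rng_ in (self.seminal_range, self.adventitious_range):
            if rng_[0] > rng_[1] or rng_[0] < 0:
                raise ParameterError(f"empty count range {rng_}")
        if self.n_primary < 0:
            raise ParameterError("n_primary must be >= 0")
        if self.n_primary + self.seminal_range[0] + self.adventitious_range[0] < 1:
            raise ParameterError("at least one first-order axis is required")
        for o in range(1, self.max_order + 1):
            if o not in self.base_diameter or self.base_diameter[o] <= 0:
                raise ParameterError(f"base_diameter missing/invalid for order {o}")
            if o not in self.length_range or self.length_range[o][0] < 0:
                raise ParameterError(f"length_range missing/invalid for order {o}")
        if not (0 <= self.taper_fraction < 1):
            raise ParameterError("taper_fraction must be in [0, 1)")
        if self.extent[0] <= 0 or self.extent[1] <= 0:
            raise ParameterError("extent must be positive")
        for o, g in self.gravitropism.items():
            if not (0 <= g <= 1):
                raise ParameterError(f"gravitropism[{o}] must be in [0, 1]")


def _grow_axis(
    rng: np.random.Generator,
    params: ArchitectureParams,
    start: tuple[float, float],
    heading_deg: float,
    order: int,
    target_length: float,
) -> tuple[list[tuple[float, float]], list[float]]:
    """Polyline coordinates and signed headings (deg from vertical) per node."""
    g = params.gravitropism.get(order, 0.0)
    sd = params.heading_noise_sd.get(order, 0.0)
    w, h = params.extent
    pts = [start]
    headings = [heading_deg]
    x, y = start
    angle = heading_deg
    length = 0.0
    while length + params.step_length <= target_length + 1e-12:
        angle = angle * (1.0 - g) + rng.normal(0.0, sd)
        rad = math.radians(angle)
        nx = x + params.step_length * math.sin(rad)
        ny = y + params.step_length * math.cos(rad)
        if not (0.0 <= nx <= w and 0.0 <= ny <= h):
            break  # growth clamped to the rhizotron extent
        pts.append((nx, ny))
        headings.append(angle)
        x, y = nx, ny
        length += params.step_length
    return pts, headings


def _node_diameters(n: int, base: float, taper: float) -> list[float]:
    if n == 1:
        return [base]
    return [base * (1.0 - taper * i / (n - 1)) for i in range(n)]


def _build_root(
    rng: np.random.Generator,
    params: ArchitectureParams,
    system: RootSystem,
    rid: str,
    order: int,
    start: tuple[float, float],
    heading_deg: float,
    parent_id: str | None,
    insertion: float | None,
) -> None:
    lo, hi = params.length_range[order]
    target = rng.uniform(lo, hi)
    base_d = params.base_diameter[order] * max(
        0.3, 1.0 + rng.normal(0.0, params.diameter_jitter_sd)
    )
    pts, headings = _grow_axis(rng, params, start, heading_deg, order, target)
    diams = _node_diameters(len(pts), base_d, params.taper_fraction)
    root = Root(
        id=rid,
        polyline=[RootNode(px, py, d) for (px, py), d in zip(pts, diams)],
        order=order,
        parent_id=parent_id,
        insertion_position=insertion,
    )
    system.add(root)

    if order >= params.max_order or order not in params.lateral_density:
        return
    lam = params.lateral_density[order]
    branchable = root.length - params.apical_zone.get(order, 0.0)
    if lam <= 0 or branchable <= 0:
        return
    count = rng.poisson(lam * branchable)
    positions = np.sort(rng.uniform(0.0, branchable, size=count))
    arcs = root.arc_lengths()
    for k, s in enumerate(positions, start=1):
        node = root.point_at(float(s))
        # local heading of the parent at the insertion point
        i = min(int(np.searchsorted(arcs, s, side="right")) - 1, len(headings) - 2)
        i = max(i, 0)
        parent_heading = headings[i + 1] if len(headings) > 1 else headings[0]
        side = 1.0 if rng.random() < 0.5 else -1.0
        branch_angle = rng.uniform(50.0, 80.0)
        _build_root(
            rng,
            params,
            system,
            rid=f"{rid}-{k}",
            order=order + 1,
            start=(node.x, node.y),
            heading_deg=parent_heading + side * branch_angle,
            parent_id=rid,
            insertion=float(s),
        )


def generate_root_system(params: ArchitectureParams | None = None) -> RootSystem:
    """Generate a maize-like root system; deterministic for a fixed seed.

    First-order axes start at the top-center seed position: the primary
    heading straight down, seminal axes at 10-35 degrees and adventitious
    axes at 40-75 degrees from vertical, alternating sides. Each axis grows
    stepwise, its heading pulled toward vertical and perturbed by gaussian
    noise; laterals arise as a Poisson process along the parent outside the
    apical zone, one order higher, thinner and less gravitropic. The output
    always passes validation.
    """
    params = params if params is not None else ArchitectureParams()
    params.validate()
    rng = np.random.default_rng(params.seed)
    system = RootSystem(label=f"synthetic maize seed={params.seed}", extent=params.extent)
    n_sem = int(rng.integers(params.seminal_range[0], params.seminal_range[1] + 1))
    n_adv = int(rng.integers(params.adventitious_range[0], params.adventitious_range[1] + 1))
    seed_pos = (params.extent[0] / 2.0, 0.0)

    axes: list[tuple[str, float]] = []
    for i in range(params.n_primary):
        axes.append((f"P{i + 1}", rng.normal(0.0, 2.0)))
    for i in range(n_sem):
        side = 1.0 if i % 2 == 0 else -1.0
        axes.append((f"S{i + 1}", side * rng.uniform(10.0, 35.0)))
    for i in range(n_adv):
        side = 1.0 if i % 2 == 0 else -1.0
        axes.append((f"A{i + 1}", side * rng.uniform(40.0, 75.0)))

    for rid, heading in axes:
        _build_root(
            rng,
            params,
            system,
            rid=rid,
            order=1,
            start=seed_pos,
            heading_deg=heading,
            parent_id=None,
            insertion=None,
        )
    require_valid(system)
    return system


def split_system(system: RootSystem) -> list[PartialTracing]:
    """Split a system into one partial tracing per first-order axis.

    Each part holds the axis and its entire subtree (parent links inside the
    part are kept; the axes themselves have none), with offsets (0, 0) —
    the registered common frame. ``merge_tracings`` over the parts
    reconstructs the original system exactly.
    """
    parts: list[PartialTracing] = []
    for base in system.base_roots():
        frag = RootSystem(label=system.label, extent=system.extent)
        for rid in system.subtree_ids(base.id):
            r = system[rid]
            frag.add(
                Root(
                    id=r.id,
                    polyline=list(r.polyline),
                    order=r.order,
                    parent_id=r.parent_id if rid != base.id else None,
                    insertion_position=r.insertion_position if rid != base.id else None,
                )
            )
        parts.append(PartialTracing(system=frag, offset_x=0.0, offset_y=0.0))
    return parts


def render_mask(system: RootSystem, pixels_per_cm: int = 10) -> np.ndarray:
    """Rasterize a root system into a binary mask (True = root).

    Each segment is stroked with width equal to its local mean diameter
    (at least 1 px) and round caps: a pixel is foreground when its center
    lies within half the stroke width of the segment. This pixel-center
    coverage rule keeps the expected mask area equal to the stroked-union
    area at every stroke orientation, so ``mask_area`` (foreground count /
    px_per_cm^2) tracks the vector projected area at 5+ px/cm.
    """
    if pixels_per_cm < 5:
        raise ParameterError("pixels_per_cm must be >= 5 to resolve lateral diameters")
    w, h = system.extent
    ncols = int(round(w * pixels_per_cm))
    nrows = int(round(h * pixels_per_cm))
    mask = np.zeros((nrows, ncols), dtype=bool)
    px = 1.0 / pixels_per_cm
    for root in system:
        pts = root.points()
        d = root.diameters()
        segments = (
            zip(pts[:-1], pts[1:], 0.5 * (d[:-1] + d[1:]))
            if len(pts) > 1
            else [(pts[0], pts[0], d[0])]
        )
        for a, b, mean_d in segments:
            half = max(mean_d * pixels_per_cm, 1.0) / 2.0 * px  # stroke half-width, cm
            lo_x = min(a[0], b[0]) - half
            hi_x = max(a[0], b[0]) + half
            lo_y = min(a[1], b[1]) - half
            hi_y = max(a[1], b[1]) + half
            c0 = max(int(np.floor(lo_x / px - 0.5)), 0)
            c1 = min(int(np.ceil(hi_x / px - 0.5)), ncols - 1)
            r0 = max(int(np.floor(lo_y / px - 0.5)), 0)
            r1 = min(int(np.ceil(hi_y / px - 0.5)), nrows - 1)
            if c1 < c0 or r1 < r0:
                continue
            cx = (np.arange(c0, c1 + 1) + 0.5) * px
            cy = (np.arange(r0, r1 + 1) + 0.5) * px
            X, Y = np.meshgrid(cx, cy)
            ab = b - a
            l2 = float(ab @ ab)
            if l2 > 0:
                t = np.clip(((X - a[0]) * ab[0] + (Y - a[1]) * ab[1]) / l2, 0.0, 1.0)
                dist = np.hypot(X - (a[0] + t * ab[0]), Y - (a[1] + t * ab[1]))
            else:
                dist = np.hypot(X - a[0], Y - a[1])
            mask[r0 : r1 + 1, c0 : c1 + 1] |= dist <= half
    return mask


def mask_area(mask: np.ndarray, pixels_per_cm: int) -> float:
    """Foreground area of a binary mask in cm^2."""
    return float(np.count_nonzero(mask)) / float(pixels_per_cm) ** 2


# ---------------------------------------------------------------------------
# water maps


@dataclass
class WaterModelParams:
    """Parameters of the radial soil-water depletion model.

    The water-content index at a pixel with distance ``d`` (cm) to the
    nearest root is ``W = clip(W0(t) - A(t) exp(-d / depletion_length) +
    noise, 0, 1)``. The bulk content ``W0`` declines linearly with cumulative
    daytime hours (flat at night: transpiration stops); the depletion
    amplitude ``A`` rises toward ``amplitude_max`` with daytime-hour
    timescale ``amplitude_timescale`` and is reduced by
    ``night_refill_fraction`` at night timestamps (water redistribution from
    the bulk soil toward the depleted zone around the roots).
    """

    w0_start: float = 0.75
    drying_rate: float = 0.005  # bulk decline per daytime hour
    amplitude_max: float = 0.35
    amplitude_timescale: float = 4.0  # daytime hours (morning onset of uptake)
    depletion_length: float = 2.0  # cm
    night_refill_fraction: float = 0.3
    noise_sd: float = 0.01
    timestamps: tuple[float, ...] = tuple(float(t) for t in range(0, 73, 4))
    day_window: tuple[float, float] = (6.0, 20.0)  # hour-of-day interval
    seed: int = 0

    def validate(self) -> None:
        if self.depletion_length <= 0:
            raise ParameterError("depletion_length must be > 0")
        if not (0 <= self.night_refill_fraction <= 1):
            raise ParameterError("night_refill_fraction must be in [0, 1]")
        if self.noise_sd < 0:
            raise ParameterError("noise_sd must be >= 0")
        if len(self.timestamps) == 0:
            raise ParameterError("at least one timestamp is required")
        if not (0 <= self.day_window[0] < self.day_window[1] <= 24):
            raise ParameterError("day_window must satisfy 0 <= start < end <= 24")

    def is_day(self, t: float) -> bool:
        hod = t % 24.0
        return self.day_window[0] <= hod < self.day_window[1]

    def daytime_hours(self, t: float) -> float:
        """Cumulative daytime hours in [0, t]."""
        d0, d1 = self.day_window
        full_days = int(t // 24.0)
        total = full_days * (d1 - d0)
        hod = t - 24.0 * full_days
        total += min(max(hod - d0, 0.0), d1 - d0)
        return total

    def bulk(self, t: float) -> float:
        return self.w0_start - self.drying_rate * self.daytime_hours(t)

    def amplitude(self, t: float) -> float:
        a = self.amplitude_max * (1.0 - math.exp(-self.daytime_hours(t) / self.amplitude_timescale))
        if not self.is_day(t):
            a *= 1.0 - self.night_refill_fraction
        return a


def generate_water_series(
    system: RootSystem,
    geometry: GridGeometry,
    params: WaterModelParams | None = None,
) -> list[SoilGrid]:
    """Synthesize a time series of soil-water maps depleting around the roots.

    Distances come from :func:`rootvec.soil_cross.distance_map` on
    ``geometry`` (the root system is static over the series); gaussian pixel
    noise is seeded by ``params.seed``. The geometry must cover the system's
    extent.
    """
    params = params if params is not None else WaterModelParams()
    params.validate()
    w_cov = geometry.origin_x + geometry.ncols * geometry.pixel_size
    h_cov = geometry.origin_y + geometry.nrows * geometry.pixel_size
    if w_cov < system.extent[0] - 1e-9 or h_cov < system.extent[1] - 1e-9:
        raise ParameterError(
            f"geometry covers {w_cov} x {h_cov} cm but the system extent is "
            f"{system.extent[0]} x {system.extent[1]} cm"
        )
    rng = np.random.default_rng(params.seed)
    decay = np.exp(-distance_map(geometry, system).distances / params.depletion_length)
    out: list[SoilGrid] = []
    for t in params.timestamps:
        w = params.bulk(t) - params.amplitude(t) * decay
        if params.noise_sd > 0:
            w = w + rng.normal(0.0, params.noise_sd, size=decay.shape)
        out.append(
            SoilGrid(
                np.clip(w, 0.0, 1.0),
                origin_x=geometry.origin_x,
                origin_y=geometry.origin_y,
                pixel_size=geometry.pixel_size,
                timestamp=float(t),
            )
        )
    return out


def two_axis_system(
    x_positions: Sequence[float] = (13.0, 37.0),
    extent: tuple[float, float] = (50.0, 50.0),
    diameter: float = 0.3,
) -> RootSystem:
    """A minimal sparse system: vertical axes spanning the full rhizotron depth.

    Useful as a water-analysis fixture where pixel-to-root distances must
    populate a wide range (up to ~13 cm with the default two axes in a 50 cm
    wide rhizotron).
    """
    system = RootSystem(label="two vertical axes", extent=extent)
    for i, x in enumerate(x_positions, start=1):
        system.add(
            Root(
                id=f"V{i}",
                polyline=[RootNode(x, 0.0, diameter), RootNode(x, extent[1], diameter)],
                order=1,
            )
        )
    return system
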