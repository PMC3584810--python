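"""Architectural trait suite for vectorized root systems.

Per-root morphology (length, surface, volume, diameters), distal cumulative
measures along a root, per-order depth profiles of root length, diameter
comparisons between orders with a compact letter display, per-order surface
proportions, orientation along the root axis, and Fitter's topological
indices (magnitude, altitude, exterior path length).

Geometry conventions: each polyline segment is treated as a cylinder of the
mean of its two node diameters for lateral surface, and as a conical frustum
for volume. Depth is the y coordinate (positive downward).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .errors import AnalysisError, GeometryError
from .root_model import Root, RootNode, RootSystem

__all__ = [
    "segment_measures",
    "trait_table",
    "distal_cumulative",
    "DepthProfile",
    "depth_profile",
    "diameter_stats",
    "surface_proportions",
    "OrientationProfile",
    "orientation_profile",
    "fitter_indices",
]

MEASURES = ("length", "surface", "volume")


def segment_measures(n1: RootNode, n2: RootNode) -> tuple[float, float, float]:
    """(length cm, lateral surface cm^2, frustum volume cm^3) of one segment.

    surface = pi * mean(d1, d2) * length; volume is the exact conical frustum
    (pi/12) * length * (d1^2 + d1*d2 + d2^2).
    """
    if n1.diameter < 0 or n2.diameter < 0:
        raise GeometryError("negative diameter")
    length = math.hypot(n2.x - n1.x, n2.y - n1.y)
    surface = math.pi * 0.5 * (n1.diameter + n2.diameter) * length
    volume = (
        math.pi / 12.0 * length
        * (n1.diameter**2 + n1.diameter * n2.diameter + n2.diameter**2)
    )
    return length, surface, volume


def _root_totals(root: Root) -> tuple[float, float, float, float]:
    """(length, surface, volume, projected area) of one root."""
    length = surface = volume = projected = 0.0
    for a, b in zip(root.polyline[:-1], root.polyline[1:]):
        l, s, v = segment_measures(a, b)
        length += l
        surface += s
        volume += v
        projected += l * 0.5 * (a.diameter + b.diameter)
    return length, surface, volume, projected


def _weighted_mean_diameter(root: Root) -> float:
    """Length-weighted mean diameter; plain node mean for zero-length roots."""
    num = den = 0.0
    for a, b in zip(root.polyline[:-1], root.polyline[1:]):
        l = math.hypot(b.x - a.x, b.y - a.y)
        num += l * 0.5 * (a.diameter + b.diameter)
        den += l
    if den == 0.0:
        return float(np.mean([n.diameter for n in root.polyline]))
    return num / den


def trait_table(system: RootSystem) -> pd.DataFrame:
    """Per-root trait table (one row per root).

    Columns: id, order, length_cm, surface_cm2, volume_cm3,
    projected_area_cm2 (length x mean diameter, the quantity a flatbed mask
    measures), mean_diameter_cm, insertion_position_cm, tip_depth_cm,
    parent_id.
    """
    rows = []
    for r in system:
        length, surface, volume, projected = _root_totals(r)
        rows.append(
            {
                "id": r.id,
                "order": r.order,
                "parent_id": r.parent_id if r.parent_id is not None else "",
                "length_cm": length,
                "surface_cm2": surface,
                "volume_cm3": volume,
                "projected_area_cm2": projected,
                "mean_diameter_cm": _weighted_mean_diameter(r),
                "insertion_position_cm": (
                    r.insertion_position if r.insertion_position is not None else np.nan
                ),
                "tip_depth_cm": r.polyline[-1].y,
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "id",
            "order",
            "length_cm",
            "surface_cm2",
            "volume_cm3",
            "projected_area_cm2",
            "mean_diameter_cm",
            "insertion_position_cm",
            "tip_depth_cm",
            "parent_id",
        ],
    )


def _measure_index(measure: str) -> int:
    if measure not in MEASURES:
        raise AnalysisError(f"unknown measure {measure!r}; expected one of {MEASURES}")
    return MEASURES.index(measure)


def _subtree_total(system: RootSystem, root_id: str, mi: int) -> float:
    total = 0.0
    for rid in system.subtree_ids(root_id):
        r = system[rid]
        for a, b in zip(r.polyline[:-1], r.polyline[1:]):
            total += segment_measures(a, b)[mi]
    return total


def distal_cumulative(
    system: RootSystem, root_id: str, position: float, measure: str = "surface"
) -> float:
    """Total ``measure`` distal of (tipward of) ``position`` on ``root_id``.

    Includes the tipward part of the root itself (the segment containing
    ``position`` is clipped exactly) plus the entire subtrees of all children
    inserted at arc length >= ``position``. At the tip the value is 0.
    """
    if root_id not in system:
        raise AnalysisError(f"unknown root id {root_id!r}")
    mi = _measure_index(measure)
    root = system[root_id]
    arcs = root.arc_lengths()
    if not (-1e-9 <= position <= arcs[-1] + 1e-9):
        raise AnalysisError(
            f"position {position} outside [0, {arcs[-1]}] on root {root_id!r}"
        )
    position = float(np.clip(position, 0.0, arcs[-1]))

    total = 0.0
    for i, (a, b) in enumerate(zip(root.polyline[:-1], root.polyline[1:])):
        s0, s1 = arcs[i], arcs[i + 1]
        if s1 <= position:
            continue
        if s0 >= position:
            total += segment_measures(a, b)[mi]
        else:  # clip at the query position
            cut = root.point_at(position)
            total += segment_measures(cut, b)[mi]
    for child in system.children_of(root_id):
        if child.insertion_position is not None and child.insertion_position >= position:
            total += _subtree_total(system, child.id, mi)
    return total


@dataclass
class DepthProfile:
    """Root length per depth bin, split by root order.

    ``lengths[i, k]`` is the length (cm) of order ``orders[i]`` roots inside
    the depth slab ``[edges[k], edges[k+1])``.
    """

    edges: np.ndarray  # (n_bins + 1,)
    orders: list[int]
    lengths: np.ndarray  # (n_orders, n_bins)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for i, order in enumerate(self.orders):
            for k in range(len(self.edges) - 1):
                rows.append(
                    {
                        "depth_top_cm": self.edges[k],
                        "depth_bottom_cm": self.edges[k + 1],
                        "order": order,
                        "length_cm": self.lengths[i, k],
                    }
                )
        return pd.DataFrame(rows, columns=["depth_top_cm", "depth_bottom_cm", "order", "length_cm"])


def depth_profile(system: RootSystem, bin_size: float = 1.0) -> DepthProfile:
    """Per-order root length profile over horizontal depth slabs.

    Each segment's length is apportioned to the slabs it crosses by exact
    clipping (fraction of the vertical span inside the slab), so the per-order
    bin sums equal the per-order totals exactly and the profile is invariant
    under bin refinement.
    """
    if bin_size <= 0:
        raise AnalysisError("bin_size must be > 0")
    orders = sorted({r.order for r in system if r.order is not None})
    segs = []  # (order_index, y_lo, y_hi, length)
    ys = []
    for r in system:
        if r.order is None:
            continue
        oi = orders.index(r.order)
        for a, b in zip(r.polyline[:-1], r.polyline[1:]):
            l = math.hypot(b.x - a.x, b.y - a.y)
            lo, hi = min(a.y, b.y), max(a.y, b.y)
            segs.append((oi, lo, hi, l))
            ys.extend((lo, hi))
    if not segs:
        return DepthProfile(np.array([0.0, bin_size]), orders, np.zeros((len(orders), 1)))
    k0 = math.floor(min(ys) / bin_size)
    # deepest point exactly on an edge belongs to the bin below it
    k1 = max(math.ceil(max(ys) / bin_size) - 1, k0)
    edges = (np.arange(k0, k1 + 2) * bin_size).astype(float)
    lengths = np.zeros((len(orders), len(edges) - 1))
    for oi, lo, hi, l in segs:
        if hi == lo:  # horizontal segment: all length to the slab containing y
            k = min(max(int(math.floor(lo / bin_size)) - k0, 0), lengths.shape[1] - 1)
            lengths[oi, k] += l
            continue
        overlap = np.clip(
            np.minimum(edges[1:], hi) - np.maximum(edges[:-1], lo), 0.0, None
        )
        lengths[oi] += l * overlap / (hi - lo)
    return DepthProfile(edges, orders, lengths)


# ---------------------------------------------------------------------------
# diameter comparison between orders


def _compact_letters(groups: list[int], significant: set[tuple[int, int]]) -> dict[int, str]:
    """Insert-and-absorb compact letter display.

    Groups sharing a letter are not significantly different; every
    significantly different pair ends up with disjoint letter sets.
    """
    columns: list[set[int]] = [set(groups)]
    for i, j in sorted(significant):
        for col in [c for c in columns if i in c and j in c]:
            columns.remove(col)
            for new in (col - {j}, col - {i}):
                if new and not any(new <= other for other in columns):
                    columns.append(new)
    columns.sort(key=lambda c: (min(groups.index(g) for g in c), sorted(c)))
    letters = {g: "" for g in groups}
    for letter, col in zip("abcdefghijklmnopqrstuvwxyz", columns):
        for g in col:
            letters[g] += letter
    return {g: "".join(sorted(s)) for g, s in letters.items()}


def diameter_stats(system: RootSystem, alpha: float = 0.01) -> pd.DataFrame:
    """Per-order root diameter statistics with a compact letter display.

    Each root is summarized by its length-weighted mean diameter; orders are
    compared pairwise by Welch's unequal-variance t-test at ``alpha`` (no
    multiplicity correction), and orders that are not significantly different
    share a letter. Orders with fewer than 2 roots are reported without a
    letter.
    """
    samples: dict[int, list[float]] = {}
    for r in system:
        if r.order is None:
            continue
        samples.setdefault(r.order, []).append(_weighted_mean_diameter(r))
    if not samples:
        raise AnalysisError("system has no roots with a known order")
    orders = sorted(samples)
    testable = [o for o in orders if len(samples[o]) >= 2]
    significant: set[tuple[int, int]] = set()
    for a_i in range(len(testable)):
        for b_i in range(a_i + 1, len(testable)):
            oa, ob = testable[a_i], testable[b_i]
            xa, xb = samples[oa], samples[ob]
            if np.std(xa) == 0 and np.std(xb) == 0 and np.mean(xa) == np.mean(xb):
                continue  # identical constant samples: not different
            p = stats.ttest_ind(xa, xb, equal_var=False).pvalue
            if p < alpha:
                significant.add((oa, ob))
    letters = _compact_letters(testable, significant) if testable else {}
    rows = []
    for o in orders:
        x = np.asarray(samples[o])
        rows.append(
            {
                "order": o,
                "n": len(x),
                "mean_diameter_cm": float(np.mean(x)),
                "sd_diameter_cm": float(np.std(x, ddof=1)) if len(x) > 1 else np.nan,
                "letters": letters.get(o, ""),
            }
        )
    return pd.DataFrame(rows, columns=["order", "n", "mean_diameter_cm", "sd_diameter_cm", "letters"])


def surface_proportions(system: RootSystem) -> dict[int, float]:
    """Fraction of total root surface contributed by each order.

    Fractions lie in [0, 1] and sum to 1. Raises for an empty or zero-surface
    system, where the proportions are undefined.
    """
    totals: dict[int, float] = {}
    for r in system:
        if r.order is None:
            continue
        _, surface, _, _ = _root_totals(r)
        totals[r.order] = totals.get(r.order, 0.0) + surface
    grand = sum(totals.values())
    if grand <= 0.0:
        raise AnalysisError("total surface is zero; proportions undefined")
    return {o: s / grand for o, s in sorted(totals.items())}


@dataclass
class OrientationProfile:
    """Angle from the vertical-down direction along a root's arc length."""

    positions: np.ndarray  # arc length (cm) at every polyline node
    angles: np.ndarray  # degrees in [0, 180]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"position_cm": self.positions, "angle_deg": self.angles})


def orientation_profile(root: Root, window: float = 1.0) -> OrientationProfile:
    """Orientation of a root along its axis.

    At each polyline node the local direction is the secant over a centered
    arc-length window (clamped at the ends); the reported angle is the
    unsigned angle between that direction and vertical-down, in degrees.
    """
    if window <= 0:
        raise GeometryError("window must be > 0")
    arcs = root.arc_lengths()
    total = arcs[-1]
    if total <= 0:
        raise GeometryError(f"root {root.id!r} has zero length")
    positions = arcs.copy()
    angles = np.empty_like(positions)
    for i, s in enumerate(positions):
        lo = max(0.0, s - window / 2.0)
        hi = min(total, s + window / 2.0)
        if hi - lo <= 0:  # degenerate only if total == 0, excluded above
            lo, hi = 0.0, total
        p0 = root.point_at(lo)
        p1 = root.point_at(hi)
        dx, dy = p1.x - p0.x, p1.y - p0.y
        norm = math.hypot(dx, dy)
        if norm == 0:  # window fell on a coincident-node stretch; widen to full root
            p0, p1 = root.polyline[0], root.polyline[-1]
            dx, dy = p1.x - p0.x, p1.y - p0.y
            norm = math.hypot(dx, dy)
        angles[i] = math.degrees(math.acos(np.clip(dy / norm, -1.0, 1.0)))
    return OrientationProfile(positions, angles)


# ---------------------------------------------------------------------------
# Fitter topological indices


def fitter_indices(system: RootSystem) -> pd.DataFrame:
    """Fitter's topological indices per tree of the forest.

    Links are the internodes between branching points and tips. magnitude =
    number of exterior links (tips); altitude = number of links on the longest
    base-to-tip path; exterior path length = sum over tips of the number of
    links from the base. An unbranched axis is a single link (magnitude,
    altitude and path length all 1).
    """
    cmap = system.children_map()

    def walk(root_id: str, base_links: int) -> tuple[int, int, int]:
        """(magnitude, altitude, exterior path length) of the subtree rooted
        at ``root_id`` whose own base vertex sits ``base_links`` links from
        the tree base."""
        children = sorted(
            cmap[root_id],
            key=lambda r: (
                r.insertion_position if r.insertion_position is not None else 0.0,
                r.id,
            ),
        )
        magnitude, altitude, path = 0, 0, 0
        for i, child in enumerate(children, start=1):
            m, a, p = walk(child.id, base_links + i)
            magnitude += m
            altitude = max(altitude, a)
            path += p
        tip_depth = base_links + len(children) + 1  # this root's own tip
        magnitude += 1
        altitude = max(altitude, tip_depth)
        path += tip_depth
        return magnitude, altitude, path

    rows = []
    for base in system.base_roots():
        m, a, p = walk(base.id, 0)
        rows.append(
            {"tree_id": base.id, "magnitude": m, "altitude": a, "exterior_path_length": p}
        )
    return pd.DataFrame(rows, columns=["tree_id", "magnitude", "altitude", "exterior_path_length"])
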