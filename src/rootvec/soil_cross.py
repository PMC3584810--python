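"""Crossing root architecture with raster soil-water maps.

The local analysis of root-soil interactions proceeds in three steps:
(1) reduce the water-content maps to an analysis resolution (block means,
typically 1 cm^2 pixels over a 50 x 50 cm rhizotron), (2) find for every
pixel the closest root segment (euclidean distance to the polyline
centerline), and (3) merge the soil and root information into one long table,
which can then be aggregated into per-distance-bin time series of water
content. Root growth over the (days-long) observation window is assumed
negligible, so a single distance map serves all timestamps.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit

from .errors import AnalysisError, GeometryError, ParameterError, ResamplingError
from .root_model import RootSystem

__all__ = [
    "GridGeometry",
    "SoilGrid",
    "DistanceMap",
    "downsample_grid",
    "distance_map",
    "join_soil_root",
    "distance_binned_series",
    "DepletionFit",
    "fit_depletion_profile",
]


@dataclass(frozen=True)
class GridGeometry:
    """Placement of a raster in the rhizotron frame.

    Pixel (row, col) has its center at
    ``(origin_x + (col + 0.5) h, origin_y + (row + 0.5) h)`` cm.
    """

    nrows: int
    ncols: int
    origin_x: float = 0.0
    origin_y: float = 0.0
    pixel_size: float = 1.0

    def __post_init__(self):
        if self.pixel_size <= 0:
            raise ParameterError("pixel_size must be > 0")
        if self.nrows < 1 or self.ncols < 1:
            raise ParameterError("grid must have at least one pixel")

    def pixel_centers(self) -> tuple[np.ndarray, np.ndarray]:
        """(X, Y) arrays of pixel-center coordinates, each (nrows, ncols)."""
        x = self.origin_x + (np.arange(self.ncols) + 0.5) * self.pixel_size
        y = self.origin_y + (np.arange(self.nrows) + 0.5) * self.pixel_size
        return np.meshgrid(x, y)

    def matches(self, other: "GridGeometry", tol: float = 1e-9) -> bool:
        return (
            self.nrows == other.nrows
            and self.ncols == other.ncols
            and abs(self.origin_x - other.origin_x) <= tol
            and abs(self.origin_y - other.origin_y) <= tol
            and abs(self.pixel_size - other.pixel_size) <= tol
        )


@dataclass
class SoilGrid:
    """A timestamped 2D water-content raster (unitless index in [0, 1])."""

    values: np.ndarray
    origin_x: float = 0.0
    origin_y: float = 0.0
    pixel_size: float = 1.0
    timestamp: float = 0.0  # hours since the start of the series

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ParameterError("grid values must be a 2D matrix")
        if self.pixel_size <= 0:
            raise ParameterError("pixel_size must be > 0")

    @property
    def geometry(self) -> GridGeometry:
        return GridGeometry(
            self.values.shape[0],
            self.values.shape[1],
            self.origin_x,
            self.origin_y,
            self.pixel_size,
        )

    def check_values(self, name: str = "grid") -> None:
        if not np.all(np.isfinite(self.values)):
            raise ParameterError(f"{name}: non-finite water-content values")
        if self.values.min() < 0.0 or self.values.max() > 1.0:
            raise ParameterError(f"{name}: water-content values outside [0, 1]")


def downsample_grid(grid: SoilGrid, target_pixel: float) -> SoilGrid:
    """Reduce a grid to a coarser pixel size by exact block means.

    ``target_pixel`` must be an integer multiple of the source pixel size and
    the source dimensions must be divisible by that factor; anything else
    raises :class:`ResamplingError` rather than silently cropping. Block means
    conserve the global mean exactly.
    """
    factor = target_pixel / grid.pixel_size
    k = int(round(factor))
    if k < 1 or abs(factor - k) > 1e-9:
        raise ResamplingError(
            f"target pixel {target_pixel} is not an integer multiple of {grid.pixel_size}"
        )
    if k == 1:
        return SoilGrid(
            grid.values.copy(), grid.origin_x, grid.origin_y, grid.pixel_size, grid.timestamp
        )
    r, c = grid.values.shape
    if r % k or c % k:
        raise ResamplingError(f"grid shape {r}x{c} not divisible by block factor {k}")
    blocks = grid.values.reshape(r // k, k, c // k, k).mean(axis=(1, 3))
    return SoilGrid(blocks, grid.origin_x, grid.origin_y, target_pixel, grid.timestamp)


@dataclass
class DistanceMap:
    """Per-pixel distance to the nearest root segment, with its identity.

    ``root_orders`` stores -1 where the nearest root has no recorded order.
    """

    distances: np.ndarray  # (nrows, ncols) cm
    root_ids: np.ndarray  # (nrows, ncols) object (str)
    root_orders: np.ndarray  # (nrows, ncols) int, -1 for unknown
    geometry: GridGeometry


def _polyline_min_dist(px: np.ndarray, py: np.ndarray, pts: np.ndarray) -> np.ndarray:
    """Min distance from flat pixel-center arrays to one polyline.

    Chunks over segments to bound memory on large rasters.
    """
    if len(pts) == 1:
        return np.hypot(px - pts[0, 0], py - pts[0, 1])
    a, b = pts[:-1], pts[1:]
    ab = b - a
    l2 = np.einsum("ij,ij->i", ab, ab)
    best = np.full(px.shape, np.inf)
    max_pairs = 20_000_000
    step = max(1, max_pairs // max(len(px), 1))
    for s in range(0, len(a), step):
        aa, bb = a[s : s + step], ab[s : s + step]
        ll = l2[s : s + step]
        dx = px[:, None] - aa[None, :, 0]
        dy = py[:, None] - aa[None, :, 1]
        t = dx * bb[None, :, 0] + dy * bb[None, :, 1]
        np.divide(t, np.where(ll > 0, ll, 1.0)[None, :], out=t)
        np.clip(t, 0.0, 1.0, out=t)
        ex = dx - t * bb[None, :, 0]
        ey = dy - t * bb[None, :, 1]
        d = np.sqrt(ex * ex + ey * ey).min(axis=1)
        np.minimum(best, d, out=best)
    return best


def distance_map(geometry: GridGeometry, system: RootSystem) -> DistanceMap:
    """Distance from every pixel center to its closest root segment.

    The distance is to the polyline centerline (root radius is ignored; root
    diameters are small against the pixel scale). Ties between roots resolve
    to the lexicographically smallest root id.
    """
    roots = sorted((r for r in system if len(r.polyline) >= 1), key=lambda r: r.id)
    if not roots:
        raise GeometryError("distance_map requires a system with at least one root")
    X, Y = geometry.pixel_centers()
    px, py = X.ravel(), Y.ravel()
    best = np.full(px.shape, np.inf)
    best_idx = np.zeros(px.shape, dtype=int)
    for i, root in enumerate(roots):
        d = _polyline_min_dist(px, py, root.points())
        upd = d < best  # strict: earlier (smaller) id wins exact ties
        best[upd] = d[upd]
        best_idx[upd] = i
    shape = (geometry.nrows, geometry.ncols)
    ids = np.array([r.id for r in roots], dtype=object)[best_idx].reshape(shape)
    orders = np.array(
        [r.order if r.order is not None else -1 for r in roots], dtype=int
    )[best_idx].reshape(shape)
    return DistanceMap(best.reshape(shape), ids, orders, geometry)


def join_soil_root(series: Sequence[SoilGrid], dmap: DistanceMap) -> pd.DataFrame:
    """Merge a water-map series with a distance map into one long table.

    One row per (pixel, timestamp) with the pixel's water content at that time
    and its (time-invariant) nearest-root distance and attributes.
    """
    series = list(series)
    if not series:
        raise AnalysisError("empty soil-grid series")
    for g in series:
        if not g.geometry.matches(dmap.geometry):
            raise AnalysisError(
                f"grid at t={g.timestamp} h does not match the distance-map geometry"
            )
    geo = dmap.geometry
    rows, cols = np.meshgrid(np.arange(geo.nrows), np.arange(geo.ncols), indexing="ij")
    X, Y = geo.pixel_centers()
    base = {
        "row": rows.ravel(),
        "col": cols.ravel(),
        "x_cm": X.ravel(),
        "y_cm": Y.ravel(),
        "distance_cm": dmap.distances.ravel(),
        "nearest_root_id": dmap.root_ids.ravel(),
        "nearest_root_order": dmap.root_orders.ravel(),
    }
    frames = []
    for g in series:
        df = pd.DataFrame(base)
        df.insert(4, "timestamp_h", g.timestamp)
        df.insert(5, "water_content", g.values.ravel())
        frames.append(df)
    return pd.concat(frames, ignore_index=True)


def distance_binned_series(
    table: pd.DataFrame, bin_edges: Iterable[float] | None = None
) -> pd.DataFrame:
    """Mean water content per (timestamp, distance bin).

    Default bins are 1 cm steps from 0 to 15 cm; distances at or beyond the
    last edge fall into an overflow bin ``[last_edge, inf)``. The output
    carries the pixel count and mean distance per bin, so the per-time global
    mean is exactly the count-weighted mean of the bin means.
    """
    if len(table) == 0:
        raise AnalysisError("empty soil-root table")
    edges = np.asarray(
        list(bin_edges) if bin_edges is not None else np.arange(0.0, 16.0), dtype=float
    )
    if len(edges) < 2 or np.any(np.diff(edges) <= 0):
        raise AnalysisError("bin edges must be strictly increasing with >= 2 values")
    d = table["distance_cm"].to_numpy()
    if d.min() < edges[0]:
        raise AnalysisError(f"distances below the first bin edge {edges[0]}")
    idx = np.minimum(np.searchsorted(edges, d, side="right") - 1, len(edges) - 1)
    work = pd.DataFrame(
        {
            "timestamp_h": table["timestamp_h"].to_numpy(),
            "bin": idx,
            "water_content": table["water_content"].to_numpy(),
            "distance_cm": d,
        }
    )
    grouped = (
        work.groupby(["timestamp_h", "bin"])
        .agg(
            mean_water_content=("water_content", "mean"),
            n=("water_content", "size"),
            mean_distance_cm=("distance_cm", "mean"),
        )
        .reset_index()
    )
    left = edges[grouped["bin"].to_numpy()]
    right = np.where(
        grouped["bin"].to_numpy() < len(edges) - 1,
        edges[np.minimum(grouped["bin"].to_numpy() + 1, len(edges) - 1)],
        np.inf,
    )
    grouped.insert(1, "bin_left_cm", left)
    grouped.insert(2, "bin_right_cm", right)
    return grouped.drop(columns=["bin"]).sort_values(
        ["timestamp_h", "bin_left_cm"], ignore_index=True
    )


@dataclass
class DepletionFit:
    """Least-squares fit of the radial depletion profile W(d) = W0 - A e^(-d/l).

    ``stderr`` holds the asymptotic standard errors from the fit covariance
    (NaN when the covariance is singular).
    """

    w0: float
    amplitude: float
    length_scale: float
    stderr: dict[str, float] = field(default_factory=dict)
    n_bins: int = 0
    timestamp: float | None = None

    def predict(self, d: np.ndarray) -> np.ndarray:
        return self.w0 - self.amplitude * np.exp(-np.asarray(d, float) / self.length_scale)

    def summary(self) -> str:
        se = self.stderr
        lines = [
            "Radial depletion profile fit: W(d) = W0 - A exp(-d / l)",
            f"  timestamp: {self.timestamp} h, bins: {self.n_bins}",
            f"  W0 (bulk water content)  = {self.w0:.4f} +/- {se.get('w0', float('nan')):.4f}",
            f"  A  (depletion amplitude) = {self.amplitude:.4f} +/- {se.get('amplitude', float('nan')):.4f}",
            f"  l  (depletion length cm) = {self.length_scale:.4f} +/- {se.get('length_scale', float('nan')):.4f}",
        ]
        return "\n".join(lines)


def fit_depletion_profile(
    binned: pd.DataFrame, timestamp: float | None = None
) -> DepletionFit:
    """Fit the exponential depletion profile to one timestamp of a binned series.

    Uses the per-bin mean distance as the abscissa and weights bins by their
    pixel counts. ``timestamp`` defaults to the last timestamp in the table.
    """
    if len(binned) == 0:
        raise AnalysisError("empty binned series")
    ts = binned["timestamp_h"].to_numpy()
    t = float(ts.max()) if timestamp is None else float(timestamp)
    sel = binned[np.isclose(ts, t)]
    if len(sel) < 3:
        raise AnalysisError(f"need >= 3 distance bins at t={t} h to fit 3 parameters")
    d = sel["mean_distance_cm"].to_numpy()
    w = sel["mean_water_content"].to_numpy()
    n = sel["n"].to_numpy().astype(float)

    def model(x, w0, a, ell):
        return w0 - a * np.exp(-x / ell)

    span = max(d.max() - d.min(), 1.0)
    p0 = (float(w.max()), float(max(w.max() - w.min(), 1e-3)), span / 3.0)
    popt, pcov = curve_fit(
        model,
        d,
        w,
        p0=p0,
        sigma=1.0 / np.sqrt(n),
        absolute_sigma=False,
        bounds=([0.0, 0.0, 1e-6], [1.0, 1.0, 10.0 * span]),
        maxfev=20000,
    )
    perr = np.sqrt(np.diag(pcov)) if np.all(np.isfinite(pcov)) else np.full(3, np.nan)
    return DepletionFit(
        w0=float(popt[0]),
        amplitude=float(popt[1]),
        length_scale=float(popt[2]),
        stderr={"w0": float(perr[0]), "amplitude": float(perr[1]), "length_scale": float(perr[2])},
        n_bins=len(sel),
        timestamp=t,
    )
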