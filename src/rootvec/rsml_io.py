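"""Reading and writing root systems (RSML 1.0) and raster soil grids.

RSML dialect
------------
We read and write RSML 1.0 with 2D geometry: each ``<root>`` carries a
``<geometry><polyline><point x= y=/></polyline></geometry>`` and a per-node
diameter as a ``<function name="diameter" domain="polyline">`` with one
sample per point. Laterals are nested ``<root>`` elements inside their
parent; branching order is the nesting depth (top level = 1, at most 3).
Coordinates are converted to cm on read using the declared metadata unit
(scaled by the optional ``<resolution>``, coordinate units per declared
unit). Missing diameter samples inherit the root's last seen diameter; a
root with no diameter information at all is a format error.

Grid format
-----------
Plain-text matrix with a 4-line header::

    origin_x 0.0
    origin_y 0.0
    pixel_size 0.1
    timestamp 4.0
    0.71 0.70 ...

8-bit grayscale images (PNG/TIFF via Pillow) are also accepted, values
mapped linearly to [0, 1], with the header supplied by a JSON sidecar file
(same path + ``.json``) or explicit keyword arguments.
"""

from __future__ import annotations

import json
import math
import os
import xml.etree.ElementTree as ET
from typing import Sequence

import numpy as np

from .errors import FormatError, SeriesError
from .root_model import (
    Root,
    RootNode,
    RootSystem,
    nearest_on_polyline,
    require_valid,
)
from .soil_cross import SoilGrid

__all__ = [
    "read_rsml",
    "write_rsml",
    "read_grid",
    "write_grid",
    "read_grid_image",
    "load_soil_series",
    "write_distance_map",
]

# scale factors to cm
_UNIT_TO_CM = {
    "m": 100.0,
    "dm": 10.0,
    "cm": 1.0,
    "mm": 0.1,
    "um": 1e-4,
    "µm": 1e-4,
    "micron": 1e-4,
    "inch": 2.54,
}

_FMT = "{:.12g}".format


def _unit_scale(unit: str | None, resolution: float) -> float:
    if unit is None or unit.strip().lower() not in _UNIT_TO_CM:
        raise FormatError(f"missing or unknown RSML unit {unit!r}")
    scale = _UNIT_TO_CM[unit.strip().lower()] / resolution
    if not (math.isfinite(scale) and scale > 0):
        raise FormatError(f"unit {unit!r} with resolution {resolution} gives no finite scale")
    return scale


def _local(tag: str) -> str:
    return tag.rsplit("}", 1)[-1]


def _findall(elem: ET.Element, name: str) -> list[ET.Element]:
    return [c for c in elem if _local(c.tag) == name]


def _find(elem: ET.Element, name: str) -> ET.Element | None:
    hits = _findall(elem, name)
    return hits[0] if hits else None


def _parse_root(
    elem: ET.Element,
    depth: int,
    scale: float,
    parent: Root | None,
    system: RootSystem,
    counter: list[int],
) -> None:
    if depth > 3:
        raise FormatError("root nesting depth exceeds 3 (orders 1-3)")
    rid = elem.get("ID") or elem.get("id") or elem.get("label")
    if not rid or rid in system:
        counter[0] += 1
        rid = f"root_{counter[0]}" if not rid else f"{rid}#{counter[0]}"
    geometry = _find(elem, "geometry")
    polyline_el = _find(geometry, "polyline") if geometry is not None else None
    points = _findall(polyline_el, "point") if polyline_el is not None else []
    if len(points) < 1:
        raise FormatError(f"root {rid!r}: polyline with no points")
    coords = []
    for p in points:
        try:
            coords.append((float(p.get("x")) * scale, float(p.get("y")) * scale))
        except (TypeError, ValueError) as exc:
            raise FormatError(f"root {rid!r}: point without numeric x/y") from exc

    diameters: list[float | None] = [None] * len(coords)
    functions = _find(elem, "functions")
    if functions is not None:
        for fn in _findall(functions, "function"):
            if fn.get("name") == "diameter":
                samples = _findall(fn, "sample")
                for i in range(min(len(samples), len(coords))):
                    raw = samples[i].get("value")
                    if raw is None:
                        raw = (samples[i].text or "").strip()
                    if raw:
                        diameters[i] = float(raw) * scale
    # fill gaps with the last seen diameter
    last: float | None = None
    for i, d in enumerate(diameters):
        if d is None:
            diameters[i] = last
        else:
            last = d
    if last is None:
        raise FormatError(f"root {rid!r}: no diameter information")
    first = next(d for d in diameters if d is not None)
    filled = [d if d is not None else first for d in diameters]

    root = Root(
        id=rid,
        polyline=[RootNode(x, y, d) for (x, y), d in zip(coords, filled)],
        order=depth,
        parent_id=parent.id if parent is not None else None,
    )
    if parent is not None:
        arc, _ = nearest_on_polyline(parent.polyline, (coords[0][0], coords[0][1]))
        root.insertion_position = arc
    system.add(root)
    for child in _findall(elem, "root"):
        _parse_root(child, depth + 1, scale, root, system, counter)


def read_rsml(path: str | os.PathLike) -> RootSystem:
    """Read an RSML 1.0 file into a validated :class:`RootSystem` (cm)."""
    try:
        tree = ET.parse(path)
    except ET.ParseError as exc:
        raise FormatError(f"{path}: not well-formed XML: {exc}") from exc
    rsml = tree.getroot()
    meta = _find(rsml, "metadata")
    unit = None
    resolution = 1.0
    extent = (50.0, 50.0)
    if meta is not None:
        unit_el = _find(meta, "unit")
        unit = unit_el.text if unit_el is not None else None
        res_el = _find(meta, "resolution")
        if res_el is not None and res_el.text:
            resolution = float(res_el.text)
            if resolution <= 0:
                raise FormatError(f"{path}: non-positive resolution")
    scale = _unit_scale(unit, resolution)

    scene = _find(rsml, "scene")
    label = ""
    system = RootSystem(label=label, extent=extent)
    counter = [0]
    if scene is not None:
        for plant in _findall(scene, "plant"):
            if not system.label:
                system.label = plant.get("label") or plant.get("ID") or ""
            props = _find(plant, "properties")
            if props is not None:
                vals = {}
                for prop in _findall(props, "property"):
                    vals[prop.get("name")] = prop.get("value")
                try:
                    system.extent = (
                        float(vals.get("extent_x", extent[0])),
                        float(vals.get("extent_y", extent[1])),
                    )
                except (TypeError, ValueError):
                    pass
            for root_el in _findall(plant, "root"):
                _parse_root(root_el, 1, scale, None, system, counter)
    require_valid(system, allow_orphans=False)
    return system


def write_rsml(system: RootSystem, path: str | os.PathLike) -> str:
    """Write a root system as RSML 1.0 (unit cm), byte-stable across runs.

    The system must validate (orphan laterals are allowed and are emitted as
    top-level roots, which loses their recorded order on a round trip).
    Nothing is written if validation fails.
    """
    require_valid(system, allow_orphans=True)

    rsml = ET.Element("rsml")
    meta = ET.SubElement(rsml, "metadata")
    ET.SubElement(meta, "version").text = "1"
    ET.SubElement(meta, "unit").text = "cm"
    ET.SubElement(meta, "resolution").text = "1"
    ET.SubElement(meta, "software").text = "rootvec"
    scene = ET.SubElement(rsml, "scene")
    plant = ET.SubElement(scene, "plant", {"ID": "1", "label": system.label or "plant"})
    props = ET.SubElement(plant, "properties")
    ET.SubElement(
        props, "property", {"name": "extent_x", "value": _FMT(system.extent[0])}
    )
    ET.SubElement(
        props, "property", {"name": "extent_y", "value": _FMT(system.extent[1])}
    )

    def emit(root: Root, parent_el: ET.Element) -> None:
        el = ET.SubElement(parent_el, "root", {"ID": root.id, "label": root.id})
        geom = ET.SubElement(el, "geometry")
        poly = ET.SubElement(geom, "polyline")
        for n in root.polyline:
            ET.SubElement(poly, "point", {"x": _FMT(n.x), "y": _FMT(n.y)})
        fns = ET.SubElement(el, "functions")
        fn = ET.SubElement(fns, "function", {"name": "diameter", "domain": "polyline"})
        for n in root.polyline:
            ET.SubElement(fn, "sample", {"value": _FMT(n.diameter)})
        for child in sorted(system.children_of(root.id), key=lambda r: r.id):
            emit(child, el)

    for base in sorted(system.base_roots(), key=lambda r: r.id):
        emit(base, plant)

    ET.indent(rsml, space="  ")
    data = ET.tostring(rsml, encoding="unicode", xml_declaration=True)
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write(data)
        fh.write("\n")
    return os.fspath(path)


# ---------------------------------------------------------------------------
# raster grids

_HEADER_KEYS = ("origin_x", "origin_y", "pixel_size", "timestamp")


def read_grid(path: str | os.PathLike, check_range: bool = True) -> SoilGrid:
    """Read a plain-text soil grid (4-line header + matrix)."""
    header: dict[str, float] = {}
    with open(path, "r", encoding="utf-8") as fh:
        for _ in range(len(_HEADER_KEYS)):
            line = fh.readline()
            parts = line.split()
            if len(parts) != 2 or parts[0] not in _HEADER_KEYS:
                raise FormatError(f"{path}: bad header line {line!r}")
            header[parts[0]] = float(parts[1])
        try:
            values = np.loadtxt(fh, ndmin=2)
        except ValueError as exc:
            raise FormatError(f"{path}: non-rectangular or non-numeric matrix") from exc
    if set(header) != set(_HEADER_KEYS):
        raise FormatError(f"{path}: incomplete header, need {_HEADER_KEYS}")
    grid = SoilGrid(
        values,
        origin_x=header["origin_x"],
        origin_y=header["origin_y"],
        pixel_size=header["pixel_size"],
        timestamp=header["timestamp"],
    )
    if check_range:
        grid.check_values(name=os.fspath(path))
    elif not np.all(np.isfinite(grid.values)):
        raise FormatError(f"{path}: non-finite values")
    return grid


def write_grid(
    grid: SoilGrid, path: str | os.PathLike, check_range: bool = True, fmt: str = "%.8g"
) -> str:
    """Write a soil grid in the plain-text format (header + matrix)."""
    if check_range:
        grid.check_values(name=os.fspath(path))
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write(f"origin_x {_FMT(grid.origin_x)}\n")
        fh.write(f"origin_y {_FMT(grid.origin_y)}\n")
        fh.write(f"pixel_size {_FMT(grid.pixel_size)}\n")
        fh.write(f"timestamp {_FMT(grid.timestamp)}\n")
        np.savetxt(fh, grid.values, fmt=fmt)
    return os.fspath(path)


def read_grid_image(
    path: str | os.PathLike,
    origin_x: float | None = None,
    origin_y: float | None = None,
    pixel_size: float | None = None,
    timestamp: float | None = None,
) -> SoilGrid:
    """Read an 8-bit grayscale image as a soil grid (values / 255).

    World placement comes from a JSON sidecar ``<path>.json`` holding
    ``origin_x, origin_y, pixel_size, timestamp``; explicit keyword arguments
    override the sidecar.
    """
    from PIL import Image

    sidecar = os.fspath(path) + ".json"
    meta: dict[str, float] = {}
    if os.path.exists(sidecar):
        with open(sidecar, "r", encoding="utf-8") as fh:
            meta = json.load(fh)
    vals = {
        "origin_x": origin_x if origin_x is not None else meta.get("origin_x", 0.0),
        "origin_y": origin_y if origin_y is not None else meta.get("origin_y", 0.0),
        "pixel_size": pixel_size if pixel_size is not None else meta.get("pixel_size"),
        "timestamp": timestamp if timestamp is not None else meta.get("timestamp", 0.0),
    }
    if vals["pixel_size"] is None:
        raise FormatError(f"{path}: pixel_size missing (no sidecar and no argument)")
    with Image.open(path) as img:
        arr = np.asarray(img.convert("L"), dtype=float) / 255.0
    return SoilGrid(
        arr,
        origin_x=float(vals["origin_x"]),
        origin_y=float(vals["origin_y"]),
        pixel_size=float(vals["pixel_size"]),
        timestamp=float(vals["timestamp"]),
    )


def load_soil_series(
    paths: Sequence[str | os.PathLike],
    timestamps: Sequence[float] | None = None,
) -> list[SoilGrid]:
    """Load a time series of soil grids, sorted by timestamp.

    All grids must share shape, origin and pixel size; ``timestamps`` (hours)
    overrides the per-file header values and must then match ``paths`` in
    length. Duplicate timestamps are a series error.
    """
    if timestamps is not None and len(timestamps) != len(paths):
        raise SeriesError(
            f"{len(paths)} paths but {len(timestamps)} timestamps"
        )
    grids: list[SoilGrid] = []
    for i, p in enumerate(paths):
        g = read_grid(p)
        if timestamps is not None:
            g.timestamp = float(timestamps[i])
        grids.append(g)
    if not grids:
        return []
    ref = grids[0].geometry
    for p, g in zip(paths, grids):
        if not g.geometry.matches(ref):
            raise SeriesError(f"{p}: geometry differs from the first grid in the series")
    ts = [g.timestamp for g in grids]
    if len(set(ts)) != len(ts):
        raise SeriesError(f"duplicate timestamps in series: {sorted(ts)}")
    return sorted(grids, key=lambda g: g.timestamp)


def write_distance_map(dmap, grid_path, attributes_path) -> tuple[str, str]:
    """Write a distance map: distances in the grid format + a CSV of nearest roots."""
    import pandas as pd

    geo = dmap.geometry
    write_grid(
        SoilGrid(
            dmap.distances,
            origin_x=geo.origin_x,
            origin_y=geo.origin_y,
            pixel_size=geo.pixel_size,
            timestamp=0.0,
        ),
        grid_path,
        check_range=False,
    )
    rows, cols = np.meshgrid(np.arange(geo.nrows), np.arange(geo.ncols), indexing="ij")
    pd.DataFrame(
        {
            "row": rows.ravel(),
            "col": cols.ravel(),
            "distance_cm": dmap.distances.ravel(),
            "nearest_root_id": dmap.root_ids.ravel(),
            "nearest_root_order": dmap.root_orders.ravel(),
        }
    ).to_csv(attributes_path, index=False)
    return os.fspath(grid_path), os.fspath(attributes_path)
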