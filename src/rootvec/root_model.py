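"""Vectorized root-system data model and the split-and-combine merge.

A root system is a forest of polyline roots. Each :class:`Root` is an ordered
list of nodes carrying rhizotron coordinates (cm, x rightward, y downward) and
a local diameter (cm). Branching order follows the field convention: order 1
for axes arising at the plant base (primary, seminal, adventitious in maize),
order ``n + 1`` for laterals borne on an order-``n`` root; orders above 3 are
not represented.

The module also implements the computational half of the split-and-combine
workflow: root-system fragments are traced separately (one scan per fragment),
registered into a common frame by a translation offset, and merged back into a
single system, re-attaching laterals whose parent axis was traced in another
fragment.
"""

from __future__ import annotations

import copy
import math
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Sequence

import numpy as np

from .errors import GeometryError, ParameterError, SystemValidationError, TopologyError

MAX_ORDER = 3

__all__ = [
    "MAX_ORDER",
    "RootNode",
    "Root",
    "RootSystem",
    "PartialTracing",
    "Violation",
    "MergeRecord",
    "MergeResult",
    "validate_system",
    "nearest_on_polyline",
    "merge_tracings",
    "attach_root",
    "translate_system",
    "systems_allclose",
]


@dataclass(frozen=True)
class RootNode:
    """A single polyline node: position (cm) and local root diameter (cm)."""

    x: float
    y: float
    diameter: float


@dataclass
class Root:
    """One root as a polyline with per-node diameters.

    ``order`` may be ``None`` on fragments for a lateral whose parent was
    traced in another fragment and whose order was not recorded; a fully
    validated system always has concrete orders.
    """

    id: str
    polyline: list[RootNode]
    order: int | None = 1
    parent_id: str | None = None
    insertion_position: float | None = None

    # -- geometry helpers -------------------------------------------------

    def points(self) -> np.ndarray:
        """(n, 2) array of node coordinates."""
        return np.array([[n.x, n.y] for n in self.polyline], dtype=float)

    def diameters(self) -> np.ndarray:
        return np.array([n.diameter for n in self.polyline], dtype=float)

    def arc_lengths(self) -> np.ndarray:
        """Cumulative arc length at every node, starting at 0."""
        pts = self.points()
        if len(pts) == 0:
            raise GeometryError(f"root {self.id!r} has an empty polyline")
        seg = np.linalg.norm(np.diff(pts, axis=0), axis=1)
        return np.concatenate([[0.0], np.cumsum(seg)])

    @property
    def length(self) -> float:
        """Total arc length (cm)."""
        return float(self.arc_lengths()[-1])

    def point_at(self, s: float) -> RootNode:
        """Interpolated node (position and diameter) at arc length ``s``."""
        arcs = self.arc_lengths()
        s = float(np.clip(s, 0.0, arcs[-1]))
        i = int(np.searchsorted(arcs, s, side="right")) - 1
        i = min(max(i, 0), len(arcs) - 2) if len(arcs) > 1 else 0
        if len(self.polyline) == 1:
            return self.polyline[0]
        a, b = self.polyline[i], self.polyline[i + 1]
        span = arcs[i + 1] - arcs[i]
        t = 0.0 if span == 0 else (s - arcs[i]) / span
        return RootNode(
            x=a.x + t * (b.x - a.x),
            y=a.y + t * (b.y - a.y),
            diameter=a.diameter + t * (b.diameter - a.diameter),
        )


@dataclass
class RootSystem:
    """A forest of roots in a common rhizotron frame.

    ``extent`` is the rhizotron face (width, height) in cm; the default
    50 x 50 cm matches the thin rhizotrons this data model targets.
    """

    roots: dict[str, Root] = field(default_factory=dict)
    label: str = ""
    extent: tuple[float, float] = (50.0, 50.0)

    def add(self, root: Root) -> None:
        if root.id in self.roots:
            raise TopologyError(f"duplicate root id {root.id!r}")
        self.roots[root.id] = root

    def __len__(self) -> int:
        return len(self.roots)

    def __iter__(self) -> Iterator[Root]:
        return iter(self.roots.values())

    def __getitem__(self, root_id: str) -> Root:
        return self.roots[root_id]

    def __contains__(self, root_id: str) -> bool:
        return root_id in self.roots

    def children_map(self) -> dict[str, list[Root]]:
        """parent id -> children, in insertion order."""
        out: dict[str, list[Root]] = {rid: [] for rid in self.roots}
        for r in self:
            if r.parent_id is not None and r.parent_id in out:
                out[r.parent_id].append(r)
        return out

    def children_of(self, root_id: str) -> list[Root]:
        return [r for r in self if r.parent_id == root_id]

    def base_roots(self) -> list[Root]:
        """Roots without a parent (tree bases, plus any orphans)."""
        return [r for r in self if r.parent_id is None]

    def subtree_ids(self, root_id: str) -> list[str]:
        """ids of ``root_id`` and all its descendants (depth first)."""
        cmap = self.children_map()
        out: list[str] = []
        stack = [root_id]
        while stack:
            rid = stack.pop()
            out.append(rid)
            stack.extend(c.id for c in reversed(cmap.get(rid, [])))
        return out

    def copy(self) -> "RootSystem":
        return copy.deepcopy(self)


@dataclass
class PartialTracing:
    """A traced fragment plus its registration offset into the common frame."""

    system: RootSystem
    offset_x: float = 0.0
    offset_y: float = 0.0


# ---------------------------------------------------------------------------
# validation


@dataclass(frozen=True)
class Violation:
    code: str
    root_id: str
    message: str


def validate_system(system: RootSystem, allow_orphans: bool = False) -> list[Violation]:
    """Check the structural invariants of a root system.

    Returns a (possibly empty) list of violations; never raises. With
    ``allow_orphans`` a parentless root may carry order 2-3 or ``None`` —
    the state of a fragment whose laterals lost their parent at the split.
    """
    out: list[Violation] = []
    for r in system:
        if len(r.polyline) < 1:
            out.append(Violation("empty_polyline", r.id, "polyline has no nodes"))
            continue
        for n in r.polyline:
            if not (math.isfinite(n.x) and math.isfinite(n.y)):
                out.append(Violation("nonfinite_coordinate", r.id, f"({n.x}, {n.y})"))
                break
        if any(n.diameter < 0 for n in r.polyline):
            out.append(Violation("negative_diameter", r.id, "node diameter < 0"))
        if r.parent_id is not None and r.parent_id not in system:
            out.append(
                Violation("dangling_parent", r.id, f"parent {r.parent_id!r} not in system")
            )

    # cycles in the parent graph
    state: dict[str, int] = {}  # 0 visiting, 1 done
    for r in system:
        path = []
        rid: str | None = r.id
        while rid is not None and rid in system.roots and rid not in state:
            path.append(rid)
            state[rid] = 0
            rid = system[rid].parent_id
        if rid is not None and rid in state and state[rid] == 0 and rid in path:
            out.append(Violation("cycle", rid, "parent chain contains a cycle"))
        for p in path:
            state[p] = 1

    cyclic = {v.root_id for v in out if v.code == "cycle"}
    for r in system:
        if r.id in cyclic or len(r.polyline) < 1:
            continue
        if r.parent_id is None:
            if r.order is None or r.order != 1:
                if not allow_orphans:
                    out.append(
                        Violation("order", r.id, f"parentless root has order {r.order!r}")
                    )
                elif r.order is not None and not (1 <= r.order <= MAX_ORDER):
                    out.append(Violation("order", r.id, f"order {r.order!r} out of range"))
            if r.insertion_position is not None:
                out.append(
                    Violation("insertion", r.id, "insertion_position set without a parent")
                )
            continue
        if r.parent_id not in system:
            continue
        parent = system[r.parent_id]
        if parent.id in cyclic:
            continue
        if r.order is not None and parent.order is not None and r.order != parent.order + 1:
            out.append(
                Violation(
                    "order",
                    r.id,
                    f"order {r.order} under parent of order {parent.order}",
                )
            )
        if r.order is not None and r.order > MAX_ORDER:
            out.append(Violation("order", r.id, f"order {r.order} exceeds {MAX_ORDER}"))
        if r.insertion_position is None:
            out.append(Violation("insertion", r.id, "missing insertion_position"))
        elif len(parent.polyline) >= 1:
            plen = parent.length
            if not (-1e-9 <= r.insertion_position <= plen + 1e-9):
                out.append(
                    Violation(
                        "insertion",
                        r.id,
                        f"insertion {r.insertion_position} outside [0, {plen}]",
                    )
                )
    return out


def require_valid(system: RootSystem, allow_orphans: bool = False) -> None:
    """Raise :class:`SystemValidationError` listing all violations, if any."""
    violations = validate_system(system, allow_orphans=allow_orphans)
    if violations:
        detail = "; ".join(f"{v.code}[{v.root_id}]: {v.message}" for v in violations)
        raise SystemValidationError(detail)


# ---------------------------------------------------------------------------
# geometry kernel


def nearest_on_polyline(
    polyline: Sequence[RootNode], point: tuple[float, float]
) -> tuple[float, float]:
    """Closest point of a polyline to ``point``.

    Returns ``(arc_length, distance)`` in cm, the arc length measured from the
    first node. A single-node polyline yields arc length 0. Ties between
    segments resolve to the smallest arc length.
    """
    if len(polyline) == 0:
        raise GeometryError("empty polyline")
    p = np.asarray(point, dtype=float)
    pts = np.array([[n.x, n.y] for n in polyline], dtype=float)
    if len(pts) == 1:
        return 0.0, float(np.linalg.norm(p - pts[0]))
    a, b = pts[:-1], pts[1:]
    ab = b - a
    l2 = np.einsum("ij,ij->i", ab, ab)
    seg_len = np.sqrt(l2)
    with np.errstate(invalid="ignore", divide="ignore"):
        t = np.where(l2 > 0, np.einsum("ij,ij->i", p - a, ab) / np.where(l2 > 0, l2, 1.0), 0.0)
    t = np.clip(t, 0.0, 1.0)
    proj = a + t[:, None] * ab
    d = np.linalg.norm(p - proj, axis=1)
    i = int(np.argmin(d))  # first minimum -> smallest arc length on ties
    arc = float(np.concatenate([[0.0], np.cumsum(seg_len)])[i] + t[i] * seg_len[i])
    return arc, float(d[i])


def _subtree_height(system: RootSystem, root_id: str) -> int:
    """Levels below ``root_id`` (0 for a childless root)."""
    children = system.children_of(root_id)
    if not children:
        return 0
    return 1 + max(_subtree_height(system, c.id) for c in children)


def attach_root(system: RootSystem, child_id: str, parent_id: str) -> RootSystem:
    """Attach ``child_id`` (and its subtree) under ``parent_id``, in place.

    The insertion position is the arc length of the nearest point on the
    parent polyline to the child's first node; orders of the whole subtree are
    recomputed as ``parent.order + depth``. Raises :class:`TopologyError` if
    the attachment would create a cycle or push any order beyond 3.
    """
    if child_id not in system:
        raise TopologyError(f"unknown child id {child_id!r}")
    if parent_id not in system:
        raise TopologyError(f"unknown parent id {parent_id!r}")
    if parent_id == child_id or parent_id in system.subtree_ids(child_id):
        raise TopologyError(
            f"attaching {child_id!r} under {parent_id!r} would create a cycle"
        )
    parent = system[parent_id]
    if parent.order is None:
        raise TopologyError(f"parent {parent_id!r} has unknown order")
    height = _subtree_height(system, child_id)
    if parent.order + 1 + height > MAX_ORDER:
        raise TopologyError(
            f"attaching {child_id!r} (subtree height {height}) under order-{parent.order} "
            f"root would create order {parent.order + 1 + height} > {MAX_ORDER}"
        )
    child = system[child_id]
    first = child.polyline[0]
    arc, _ = nearest_on_polyline(parent.polyline, (first.x, first.y))
    child.parent_id = parent_id
    child.insertion_position = arc
    # recompute orders down the subtree
    stack = [(child_id, parent.order + 1)]
    while stack:
        rid, order = stack.pop()
        system[rid].order = order
        stack.extend((c.id, order + 1) for c in system.children_of(rid))
    return system


def translate_system(system: RootSystem, dx: float, dy: float) -> RootSystem:
    """Return a copy of ``system`` rigidly translated by (dx, dy) cm."""
    out = system.copy()
    for r in out:
        r.polyline = [RootNode(n.x + dx, n.y + dy, n.diameter) for n in r.polyline]
    return out


# ---------------------------------------------------------------------------
# split-and-combine merge


@dataclass(frozen=True)
class MergeRecord:
    """One re-attachment attempt: where a cross-fragment lateral ended up."""

    child_id: str
    parent_id: str | None  # None -> orphan
    distance: float
    insertion_position: float | None


@dataclass
class MergeResult:
    system: RootSystem
    report: list[MergeRecord]

    @property
    def orphans(self) -> list[str]:
        return [r.child_id for r in self.report if r.parent_id is None]

    def report_frame(self):
        """Merge report as a DataFrame (CSV-ready)."""
        import pandas as pd

        return pd.DataFrame(
            [
                {
                    "child_id": r.child_id,
                    "parent_id": r.parent_id if r.parent_id is not None else "ORPHAN",
                    "distance_cm": r.distance,
                    "insertion_position_cm": (
                        r.insertion_position if r.insertion_position is not None else ""
                    ),
                }
                for r in self.report
            ],
            columns=["child_id", "parent_id", "distance_cm", "insertion_position_cm"],
        )


def merge_tracings(
    parts: Iterable[PartialTracing], attach_tolerance: float = 0.5
) -> MergeResult:
    """Combine registered fragments into one system (split-and-combine step 3).

    Every fragment is translated by its offset into the common frame. A
    parentless root whose recorded order is not 1 (or is unknown) is a lateral
    whose parent was traced in another fragment: it is attached to the nearest
    candidate parent — order one less than the child's where known, otherwise
    any root of order < 3 — if the distance from its first node to the parent
    polyline is within ``attach_tolerance`` (cm). Laterals beyond tolerance are
    kept as orphans and listed in the report, mirroring the interactive fix-up
    of the tracing GUI. No polyline is resampled, so total length and surface
    are conserved exactly.
    """
    parts = list(parts)
    if not parts:
        raise ParameterError("merge_tracings requires at least one part")
    if attach_tolerance < 0:
        raise ParameterError("attach_tolerance must be >= 0")
    for k, part in enumerate(parts):
        violations = validate_system(part.system, allow_orphans=True)
        if violations:
            detail = "; ".join(f"{v.code}[{v.root_id}]" for v in violations)
            raise SystemValidationError(f"part {k} is invalid: {detail}")

    merged = RootSystem(label=parts[0].system.label, extent=parts[0].system.extent)
    for k, part in enumerate(parts):
        rename: dict[str, str] = {}
        for r in part.system:
            new_id = r.id
            while new_id in merged:
                new_id = f"{new_id}@{k}"
            rename[r.id] = new_id
        for r in part.system:
            moved = Root(
                id=rename[r.id],
                polyline=[
                    RootNode(n.x + part.offset_x, n.y + part.offset_y, n.diameter)
                    for n in r.polyline
                ],
                order=r.order,
                parent_id=rename.get(r.parent_id) if r.parent_id is not None else None,
                insertion_position=r.insertion_position,
            )
            merged.add(moved)

    report: list[MergeRecord] = []
    # laterals to re-attach: parentless with order != 1 (None counts as unknown)
    pending = sorted(
        (r.id for r in merged if r.parent_id is None and r.order != 1),
        key=lambda rid: (merged[rid].order if merged[rid].order is not None else MAX_ORDER, rid),
    )
    for child_id in pending:
        child = merged[child_id]
        first = child.polyline[0]
        subtree = set(merged.subtree_ids(child_id))
        if child.order is not None:
            candidates = [
                r for r in merged if r.order == child.order - 1 and r.id not in subtree
            ]
        else:
            candidates = [
                r
                for r in merged
                if r.order is not None and r.order < MAX_ORDER and r.id not in subtree
            ]
        best: tuple[float, str] | None = None
        for cand in sorted(candidates, key=lambda r: r.id):
            _, dist = nearest_on_polyline(cand.polyline, (first.x, first.y))
            if best is None or dist < best[0]:
                best = (dist, cand.id)
        if best is not None and best[0] <= attach_tolerance:
            attach_root(merged, child_id, best[1])
            report.append(
                MergeRecord(child_id, best[1], best[0], merged[child_id].insertion_position)
            )
        else:
            report.append(
                MergeRecord(child_id, None, best[0] if best else math.inf, None)
            )
    return MergeResult(system=merged, report=report)


def systems_allclose(
    a: RootSystem, b: RootSystem, tol: float = 1e-9, check_ids: bool = True
) -> bool:
    """True if two systems share topology exactly and geometry within ``tol``."""
    if check_ids and set(a.roots) != set(b.roots):
        return False
    if len(a) != len(b):
        return False
    ids = sorted(a.roots) if check_ids else None
    pairs = (
        [(a[rid], b[rid]) for rid in ids]
        if ids is not None
        else list(zip(a, b))
    )
    for ra, rb in pairs:
        if ra.order != rb.order or ra.parent_id != rb.parent_id:
            return False
        if len(ra.polyline) != len(rb.polyline):
            return False
        ia = -1.0 if ra.insertion_position is None else ra.insertion_position
        ib = -1.0 if rb.insertion_position is None else rb.insertion_position
        if abs(ia - ib) > tol:
            return False
        for na, nb in zip(ra.polyline, rb.polyline):
            if (
                abs(na.x - nb.x) > tol
                or abs(na.y - nb.y) > tol
                or abs(na.diameter - nb.diameter) > tol
            ):
                return False
    return True
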