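"""Spatial primitives: Voronoi adjacency, core/buffer split, Delaunay
triangles with incenters, and crown-disk overlap areas.

Spatial structure indexes are evaluated over *spatial structure units*: a
core reference tree together with the trees whose Voronoi cells share an
edge with its cell.  Cells are conceptually clipped to the plot disk before
adjacency is read, so two trees are neighbours only if part of their common
cell boundary lies inside the plot — adjacency "through the plot exterior"
is discarded.  Trees in the 2 m buffer ring appear as neighbours but never
as reference trees.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.spatial import Delaunay, Voronoi, QhullError

from .stand import Stand, Tree

__all__ = [
    "DegenerateGeometryError",
    "SpatialUnit",
    "TriangleRecord",
    "partition_core_buffer",
    "voronoi_adjacency",
    "voronoi_units",
    "delaunay_triangulation",
    "triangulation_from_points",
    "circle_overlap_area",
    "lens_area_vec",
]


class DegenerateGeometryError(ValueError):
    """Raised for collinear or insufficient point configurations."""


@dataclass(frozen=True)
class SpatialUnit:
    """A core reference tree and its Voronoi-adjacent neighbours.

    Neighbour ids are ordered by azimuth (clockwise from north) for
    determinism.
    """

    reference_id: int
    neighbour_ids: tuple[int, ...]

    @property
    def n(self) -> int:
        return len(self.neighbour_ids)


@dataclass(frozen=True)
class TriangleRecord:
    """One Delaunay triangle: vertex tree ids, area (m²) and incenter."""

    vertex_ids: tuple[int, int, int]
    area: float
    incenter: tuple[float, float]


def partition_core_buffer(stand: Stand) -> tuple[list[int], list[int]]:
    """Split living trees into core and buffer ids.

    A tree at distance exactly ``radius - buffer_width`` from the centre is
    core (boundary-inclusive tie rule).
    """
    if stand.buffer_width >= stand.radius:
        raise ValueError("buffer width must be smaller than the plot radius")
    core, buffer_ = [], []
    limit = stand.core_radius + 1e-9
    for t in stand.living():
        (core if t.r <= limit else buffer_).append(t.id)
    return core, buffer_


def voronoi_adjacency(points: np.ndarray, radius: float) -> list[tuple[int, int]]:
    """Index pairs whose Voronoi cells share an edge inside the plot disk.

    Unbounded ridges are extended far beyond the disk before clipping, so
    hull points keep their legitimate within-plot adjacencies.
    """
    if len(points) < 4:
        raise DegenerateGeometryError(
            "need at least 4 trees for Voronoi adjacency")
    try:
        vor = Voronoi(points)
    except QhullError as exc:  # collinear or otherwise degenerate
        raise DegenerateGeometryError(
            f"degenerate point configuration: {exc}") from exc
    center = points.mean(axis=0)
    far = 4.0 * radius + 10.0
    rp = np.asarray(vor.ridge_points)
    rv = np.asarray(vor.ridge_vertices)
    verts = vor.vertices
    m = len(rp)
    a = np.empty((m, 2))
    b = np.empty((m, 2))
    finite = (rv[:, 0] >= 0) & (rv[:, 1] >= 0)
    a[finite] = verts[rv[finite, 0]]
    b[finite] = verts[rv[finite, 1]]
    inf = ~finite
    if inf.any():
        p = points[rp[inf, 0]]
        q = points[rp[inf, 1]]
        tang = q - p
        tang = tang / np.linalg.norm(tang, axis=1, keepdims=True)
        normal = np.column_stack([-tang[:, 1], tang[:, 0]])
        mid = (p + q) / 2.0
        sign = np.sign(np.einsum("ij,ij->i", mid - center, normal))
        sign[sign == 0] = 1.0
        direction = normal * sign[:, None]
        fv = np.where(rv[inf, 0] >= 0, rv[inf, 0], rv[inf, 1])
        both = fv < 0  # ridge is a full bisector line through the midpoint
        base = np.where(both[:, None], mid, verts[np.maximum(fv, 0)])
        a[inf] = np.where(both[:, None], mid - direction * far, base)
        b[inf] = base + direction * far
    # closest approach of each segment to the origin
    ab = b - a
    denom = np.einsum("ij,ij->i", ab, ab)
    t = np.clip(-np.einsum("ij,ij->i", a, ab) / np.maximum(denom, 1e-300),
                0.0, 1.0)
    nearest = a + t[:, None] * ab
    keep = np.einsum("ij,ij->i", nearest, nearest) <= radius * radius
    return [(int(p), int(q)) for p, q in rp[keep]]


def voronoi_units(stand: Stand) -> list[SpatialUnit]:
    """Build one spatial structure unit per living core tree.

    Adjacency is computed over all living trees (core + buffer); buffer
    trees contribute only as neighbours.
    """
    living = stand.living()
    points = np.array([[t.x, t.y] for t in living])
    ids = [t.id for t in living]
    pairs = voronoi_adjacency(points, stand.radius)
    adj: dict[int, set[int]] = {i: set() for i in range(len(living))}
    for p, q in pairs:
        adj[p].add(q)
        adj[q].add(p)
    core_ids, _ = partition_core_buffer(stand)
    core_set = set(core_ids)
    units = []
    for i, t in enumerate(living):
        if t.id not in core_set:
            continue
        neigh = sorted(
            adj[i],
            key=lambda j: math.atan2(living[j].x - t.x, living[j].y - t.y)
            % (2 * math.pi),
        )
        units.append(SpatialUnit(reference_id=t.id,
                                 neighbour_ids=tuple(ids[j] for j in neigh)))
    return units


def _incenter(a: np.ndarray, b: np.ndarray, c: np.ndarray) -> tuple[float, float]:
    # side-length-weighted vertex mean; weights are the opposite side lengths
    la = np.linalg.norm(b - c)
    lb = np.linalg.norm(a - c)
    lc = np.linalg.norm(a - b)
    s = la + lb + lc
    p = (la * a + lb * b + lc * c) / s
    return float(p[0]), float(p[1])


def triangulation_from_points(points: np.ndarray,
                              ids: list[int]) -> tuple[Delaunay, list[TriangleRecord]]:
    """Delaunay triangulation with areas and incenters, area-descending."""
    if len(points) < 3:
        raise DegenerateGeometryError("need at least 3 trees to triangulate")
    try:
        tri = Delaunay(points)
    except QhullError as exc:
        raise DegenerateGeometryError(
            f"degenerate point configuration: {exc}") from exc
    if tri.nsimplex == 0:
        raise DegenerateGeometryError("triangulation produced no triangles")
    records = []
    for simplex in tri.simplices:
        a, b, c = points[simplex]
        area = 0.5 * abs((b[0] - a[0]) * (c[1] - a[1])
                         - (c[0] - a[0]) * (b[1] - a[1]))
        if area <= 0:
            continue
        records.append(TriangleRecord(
            vertex_ids=tuple(ids[v] for v in simplex),
            area=float(area), incenter=_incenter(a, b, c)))
    records.sort(key=lambda r: r.area, reverse=True)
    return tri, records


def delaunay_triangulation(stand: Stand) -> list[TriangleRecord]:
    """Delaunay triangles of all living-tree positions, largest first."""
    living = stand.living()
    points = np.array([[t.x, t.y] for t in living])
    _, records = triangulation_from_points(points, [t.id for t in living])
    return records


def lens_area_vec(r1: np.ndarray, r2: np.ndarray, d: np.ndarray,
                  no_overlap_value: float = 1.0) -> np.ndarray:
    """Vectorised two-circle intersection area with the no-overlap sentinel.

    Disjoint circles return ``no_overlap_value`` (literal published
    convention: 1.0 m²); one circle inside the other returns the smaller
    circle's area; otherwise the standard lens area.
    """
    r1 = np.asarray(r1, dtype=float)
    r2 = np.asarray(r2, dtype=float)
    d = np.asarray(d, dtype=float)
    small = np.minimum(r1, r2)
    out = np.full(np.broadcast(r1, r2, d).shape, float(no_overlap_value))
    contained = d <= np.abs(r1 - r2)
    np.copyto(out, math.pi * small ** 2, where=contained)
    overlap = (~contained) & (d < r1 + r2)
    if np.any(overlap):
        rr1, rr2, dd = (np.broadcast_to(a, out.shape)[overlap]
                        for a in (r1, r2, d))
        alpha = np.arccos(np.clip((dd**2 + rr1**2 - rr2**2) / (2 * dd * rr1),
                                  -1.0, 1.0))
        beta = np.arccos(np.clip((dd**2 + rr2**2 - rr1**2) / (2 * dd * rr2),
                                 -1.0, 1.0))
        kernel = ((-dd + rr1 + rr2) * (dd + rr1 - rr2)
                  * (dd - rr1 + rr2) * (dd + rr1 + rr2))
        lens = (rr1**2 * alpha + rr2**2 * beta
                - 0.5 * np.sqrt(np.maximum(kernel, 0.0)))
        out[overlap] = lens
    return out


def circle_overlap_area(tree_i: Tree, tree_j: Tree,
                        no_overlap_value: float = 1.0) -> float:
    """Crown-disk overlap area (m²) between two trees.

    Crown disks have radius CW/2 centred at the stems.  Disjoint crowns
    return the sentinel ``no_overlap_value``.
    """
    if tree_i.crown_width <= 0 or tree_j.crown_width <= 0:
        raise ValueError("crown widths must be positive")
    d = math.hypot(tree_i.x - tree_j.x, tree_i.y - tree_j.y)
    return float(lens_area_vec(tree_i.crown_width / 2.0,
                               tree_j.crown_width / 2.0,
                               d, no_overlap_value))
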