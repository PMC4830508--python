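"""Planar face extraction for embedded (periodic or open) rod networks.

Faces are enumerated with the standard half-edge traversal: outgoing
half-edges are sorted counter-clockwise around every node, and the
successor of a half-edge ``u -> v`` is the half-edge following the twin
``v -> u`` in clockwise order around ``v``.  On a torus every face is an
areole and the face areas tile the box exactly; on an open domain the
walk of the unbounded face comes out clockwise (negative shoelace area)
and is discarded by the callers that want areoles.

Coordinates along a face walk are *unwrapped*: each half-edge advances
the position by its true geometric vector (including periodic image
shifts), so every face is an ordinary simple polygon in the plane.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .network import VeinNetwork, rod_vectors

__all__ = ["Face", "FaceSet", "PlanarityError", "extract_faces", "check_planarity"]


class PlanarityError(ValueError):
    """Raised when two rods cross away from a shared node."""

    def __init__(self, rod_i: int, rod_j: int, message: str | None = None):
        self.rod_pair = (rod_i, rod_j)
        super().__init__(message or f"rods {rod_i} and {rod_j} cross away from a shared node")


@dataclass
class Face:
    """One face of the embedded graph.

    ``nodes`` and ``rods`` follow the counter-clockwise boundary walk;
    ``polygon`` holds the unwrapped boundary vertex coordinates (one row
    per node, not closed).  ``area`` is the signed shoelace area: it is
    positive for interior faces and negative for the outer face of an
    open network.
    """

    id: int
    nodes: list[int]
    rods: list[int]
    polygon: np.ndarray
    area: float
    centroid: tuple[float, float]


@dataclass
class FaceSet:
    faces: list[Face]
    he_face: np.ndarray  # face id of each half-edge (2*rod + direction)

    @property
    def n_faces(self) -> int:
        return len(self.faces)

    def rod_faces(self, rod: int) -> tuple[int, int]:
        """Ids of the two faces separated by a rod (may coincide for bridges)."""
        return int(self.he_face[2 * rod]), int(self.he_face[2 * rod + 1])


def _polygon_area_centroid(poly: np.ndarray) -> tuple[float, tuple[float, float]]:
    x = poly[:, 0]
    y = poly[:, 1]
    xn = np.roll(x, -1)
    yn = np.roll(y, -1)
    cross = x * yn - xn * y
    area = 0.5 * float(cross.sum())
    if abs(area) < 1e-300:
        # degenerate; fall back to vertex mean
        return area, (float(x.mean()), float(y.mean()))
    cx = float(((x + xn) * cross).sum() / (6.0 * area))
    cy = float(((y + yn) * cross).sum() / (6.0 * area))
    return area, (cx, cy)


def extract_faces(net: VeinNetwork, validate: bool = False) -> FaceSet:
    """Enumerate the faces of an embedded rod network.

    Parameters
    ----------
    net : VeinNetwork
        Planar embedded network (rods intersect only at shared nodes).
    validate : bool
        If True, run the O(m^2)-ish segment-crossing check first and
        raise :class:`PlanarityError` on the offending rod pair.
    """
    if validate:
        check_planarity(net)
    m = net.n_rods
    dx, dy = rod_vectors(net)
    # outgoing half-edges per node: he = 2j is a->b, 2j+1 is b->a
    he_origin = np.empty(2 * m, dtype=np.int64)
    he_origin[0::2] = net.rod_a
    he_origin[1::2] = net.rod_b
    he_dx = np.empty(2 * m)
    he_dy = np.empty(2 * m)
    he_dx[0::2] = dx
    he_dx[1::2] = -dx
    he_dy[0::2] = dy
    he_dy[1::2] = -dy
    angles = np.arctan2(he_dy, he_dx)

    # counter-clockwise rotation order of outgoing half-edges at each node
    order = {}  # node -> list of he, ccw by angle
    by_node: list[list[int]] = [[] for _ in range(net.n_nodes)]
    for he in range(2 * m):
        by_node[he_origin[he]].append(he)
    pos_in_order = np.empty(2 * m, dtype=np.int64)
    for v, hes in enumerate(by_node):
        hes.sort(key=lambda e: angles[e])
        order[v] = hes
        for k, e in enumerate(hes):
            pos_in_order[e] = k

    def successor(he: int) -> int:
        twin = he ^ 1
        v = he_origin[twin]
        hes = order[v]
        k = pos_in_order[twin]
        return hes[(k - 1) % len(hes)]  # previous in ccw = next in cw

    he_face = np.full(2 * m, -1, dtype=np.int64)
    faces: list[Face] = []
    for start in range(2 * m):
        if he_face[start] != -1:
            continue
        fid = len(faces)
        walk_nodes: list[int] = []
        walk_rods: list[int] = []
        pts: list[tuple[float, float]] = []
        he = start
        px = float(net.x[he_origin[he]])
        py = float(net.y[he_origin[he]])
        while True:
            he_face[he] = fid
            walk_nodes.append(int(he_origin[he]))
            walk_rods.append(he // 2)
            pts.append((px, py))
            px += he_dx[he]
            py += he_dy[he]
            he = successor(he)
            if he == start:
                break
            if he_face[he] != -1:  # pragma: no cover - malformed embedding
                raise RuntimeError("face walk collided with an already-assigned half-edge")
        poly = np.asarray(pts)
        area, centroid = _polygon_area_centroid(poly)
        faces.append(Face(fid, walk_nodes, walk_rods, poly, area, centroid))
    return FaceSet(faces, he_face)


def check_planarity(net: VeinNetwork) -> None:
    """Verify rods intersect only at shared nodes; raise PlanarityError else.

    For periodic networks each rod is tested against the 3x3 block of
    periodic images of the others.
    """
    from shapely import STRtree
    from shapely.geometry import LineString

    dx, dy = rod_vectors(net)
    x0 = net.x[net.rod_a]
    y0 = net.y[net.rod_a]
    segs = [
        LineString([(x0[j], y0[j]), (x0[j] + dx[j], y0[j] + dy[j])])
        for j in range(net.n_rods)
    ]
    tree = STRtree(segs)
    shifts = [(0, 0)]
    if net.periodic:
        shifts = [(i, k) for i in (-1, 0, 1) for k in (-1, 0, 1)]
    eps = 1e-9 * max(net.box.W, net.box.H)
    for j in range(net.n_rods):
        for (si, sk) in shifts:
            ox, oy = si * net.box.W, sk * net.box.H
            moved = LineString(
                [(x0[j] + ox, y0[j] + oy), (x0[j] + dx[j] + ox, y0[j] + dy[j] + oy)]
            )
            for i in tree.query(moved):
                i = int(i)
                if i == j and (si, sk) == (0, 0):
                    continue
                inter = moved.intersection(segs[i])
                if inter.is_empty:
                    continue
                if inter.geom_type != "Point":
                    raise PlanarityError(min(i, j), max(i, j), "rods overlap along a segment")
                # a shared endpoint is fine; anything else is a crossing
                p = np.array([inter.x, inter.y])
                ends = np.array(
                    [
                        [x0[j] + ox, y0[j] + oy],
                        [x0[j] + dx[j] + ox, y0[j] + dy[j] + oy],
                        [x0[i], y0[i]],
                        [x0[i] + dx[i], y0[i] + dy[i]],
                    ]
                )
                if np.min(np.hypot(*(ends - p).T)) > eps:
                    raise PlanarityError(
                        min(i, j),
                        max(i, j),
                        f"rods {min(i, j)} and {max(i, j)} cross at "
                        f"({inter.x:.6g}, {inter.y:.6g})",
                    )
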