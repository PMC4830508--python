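"""Serialization: VeinNet JSON snapshots, digitized-leaf edge lists,
GraphML export.

The snapshot schema (``veinnet/1``) stores absolute node coordinates in
model units (origin at the box corner), rods with their periodic image
shifts, and all mechanical parameters.  Numbers round-trip bit-exactly
(shortest-representation floats).  Unknown top-level keys are preserved
across a read/write cycle.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Union

import numpy as np
import pandas as pd

from .faces import check_planarity
from .network import PeriodicBox, VeinNetwork, rod_lengths

__all__ = [
    "SCHEMA",
    "SnapshotFormatError",
    "write_snapshot",
    "read_snapshot",
    "snapshot_dict",
    "network_from_dict",
    "import_leaf_edges",
    "export_areole_graphml",
]

SCHEMA = "veinnet/1"


class SnapshotFormatError(ValueError):
    """Malformed or unsupported snapshot file."""


def snapshot_dict(net: VeinNetwork) -> dict:
    d = {
        "schema": SCHEMA,
        "box": {
            "W": net.box.W,
            "H": net.box.H,
            "W0": net.box.W0,
            "H0": net.box.H0,
        },
        "params": {
            "mu": net.mu,
            "nu": net.nu,
            "P_tur": net.P_tur,
            "sigma_xx": net.sigma_xx,
            "sigma_yy": net.sigma_yy,
        },
        "periodic": net.periodic,
        "eta0": net.eta0,
        "nodes": [
            {"id": i, "x": float(net.x[i]), "y": float(net.y[i])}
            for i in range(net.n_nodes)
        ],
        "rods": [
            {
                "id": j,
                "a": int(net.rod_a[j]),
                "b": int(net.rod_b[j]),
                "sx": int(net.rod_sx[j]),
                "sy": int(net.rod_sy[j]),
                "h": float(net.h[j]),
                "l0": float(net.l0[j]),
            }
            for j in range(net.n_rods)
        ],
        "metadata": net.metadata,
    }
    extra = net.metadata.get("_extra_fields")
    if extra:
        d.update(extra)
    return d


def write_snapshot(net: VeinNetwork, path: Union[str, Path]) -> None:
    """Write a network to a VeinNet JSON snapshot (lossless)."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    d = snapshot_dict(net)
    path.write_text(json.dumps(d, indent=1))


def _require(d: dict, key: str, where: str):
    if key not in d:
        raise SnapshotFormatError(f"missing field {where}{key}")
    return d[key]


def network_from_dict(d: dict) -> VeinNetwork:
    schema = _require(d, "schema", "")
    if schema != SCHEMA:
        raise SnapshotFormatError(
            f"unsupported snapshot schema {schema!r}; this reader understands {SCHEMA!r}"
        )
    box_d = _require(d, "box", "")
    box = PeriodicBox(
        _require(box_d, "W", "box."),
        _require(box_d, "H", "box."),
        box_d.get("W0"),
        box_d.get("H0"),
    )
    params = _require(d, "params", "")
    nodes = _require(d, "nodes", "")
    rods = _require(d, "rods", "")
    if not nodes or not rods:
        raise SnapshotFormatError("snapshot has no nodes or no rods")
    order = np.argsort([_require(nd, "id", "nodes[].") for nd in nodes])
    nodes = [nodes[i] for i in order]
    ids = [nd["id"] for nd in nodes]
    if ids != list(range(len(nodes))):
        raise SnapshotFormatError("node ids must be 0..n-1 (after sorting)")
    known = {"schema", "box", "params", "periodic", "eta0", "nodes", "rods", "metadata"}
    metadata = dict(d.get("metadata", {}))
    extra = {k: v for k, v in d.items() if k not in known}
    if extra:
        metadata["_extra_fields"] = extra
    net = VeinNetwork(
        box,
        [_require(nd, "x", "nodes[].") for nd in nodes],
        [_require(nd, "y", "nodes[].") for nd in nodes],
        [_require(r, "a", "rods[].") for r in rods],
        [_require(r, "b", "rods[].") for r in rods],
        [r.get("sx", 0) for r in rods],
        [r.get("sy", 0) for r in rods],
        [_require(r, "h", "rods[].") for r in rods],
        [_require(r, "l0", "rods[].") for r in rods],
        mu=_require(params, "mu", "params."),
        nu=_require(params, "nu", "params."),
        P_tur=_require(params, "P_tur", "params."),
        sigma_xx=params.get("sigma_xx", 0.0),
        sigma_yy=params.get("sigma_yy", 0.0),
        periodic=d.get("periodic", True),
        metadata=metadata,
    )
    net.eta0 = d.get("eta0")
    return net


def read_snapshot(path: Union[str, Path]) -> VeinNetwork:
    """Read a VeinNet JSON snapshot; schema-validated, errors name the
    offending field.  A truncated or non-JSON file raises
    :class:`SnapshotFormatError` without producing a partial network."""
    try:
        d = json.loads(Path(path).read_text())
    except json.JSONDecodeError as e:
        raise SnapshotFormatError(f"not a valid snapshot file ({e})") from e
    if not isinstance(d, dict):
        raise SnapshotFormatError("snapshot root must be a JSON object")
    return network_from_dict(d)


# ---------------------------------------------------------------------------
# digitized leaf import
# ---------------------------------------------------------------------------


class _UnionFind:
    def __init__(self, n: int):
        self.p = list(range(n))

    def find(self, i: int) -> int:
        while self.p[i] != i:
            self.p[i] = self.p[self.p[i]]
            i = self.p[i]
        return i

    def union(self, i: int, j: int) -> None:
        self.p[self.find(i)] = self.find(j)


def import_leaf_edges(
    path: Union[str, Path], snap_tolerance: float = 1e-6
) -> VeinNetwork:
    """Build an open planar network from a digitized vein segment list.

    The CSV must have columns ``x1, y1, x2, y2`` (one vein segment per
    row) and optionally ``width``, which becomes the rod thickness.
    Endpoints closer than ``snap_tolerance`` are merged into one
    junction; duplicate segments are collapsed; the result is validated
    planar (crossing segments are reported with their coordinates).
    """
    df = pd.read_csv(path)
    for col in ("x1", "y1", "x2", "y2"):
        if col not in df.columns:
            raise ValueError(f"edge list is missing required column {col!r}")
    if df.empty:
        raise ValueError("edge list is empty")
    pts = np.concatenate(
        [df[["x1", "y1"]].to_numpy(float), df[["x2", "y2"]].to_numpy(float)]
    )
    from scipy.spatial import cKDTree

    tree = cKDTree(pts)
    uf = _UnionFind(len(pts))
    for i, j in tree.query_pairs(snap_tolerance):
        uf.union(i, j)
    root_to_node: dict[int, int] = {}
    node_pts: list[list[float]] = []
    labels = np.empty(len(pts), dtype=int)
    for i in range(len(pts)):
        r = uf.find(i)
        if r not in root_to_node:
            root_to_node[r] = len(node_pts)
            node_pts.append([0.0, 0.0, 0.0])
        labels[i] = root_to_node[r]
        node_pts[labels[i]][0] += pts[i, 0]
        node_pts[labels[i]][1] += pts[i, 1]
        node_pts[labels[i]][2] += 1.0
    coords = np.array([[sx / c, sy / c] for sx, sy, c in node_pts])

    nseg = len(df)
    widths = df["width"].to_numpy(float) if "width" in df.columns else np.ones(nseg)
    seen: dict[tuple[int, int], int] = {}
    a_l, b_l, h_l = [], [], []
    for k in range(nseg):
        a, b = int(labels[k]), int(labels[k + nseg])
        if a == b:
            continue  # zero-length after snapping
        key = (min(a, b), max(a, b))
        if key in seen:
            continue
        seen[key] = k
        a_l.append(a)
        b_l.append(b)
        h_l.append(widths[k] if widths[k] > 0 else 1.0)
    if not a_l:
        raise ValueError("no usable segments after snapping")

    span = coords.max(axis=0) - coords.min(axis=0)
    margin = 0.05 * max(span.max(), snap_tolerance)
    origin = coords.min(axis=0) - margin
    coords = coords - origin
    m = len(a_l)
    net = VeinNetwork(
        PeriodicBox(span[0] + 2 * margin, span[1] + 2 * margin),
        coords[:, 0],
        coords[:, 1],
        a_l,
        b_l,
        np.zeros(m, dtype=int),
        np.zeros(m, dtype=int),
        h_l,
        np.ones(m),
        periodic=False,
        metadata={"source": str(path)},
    )
    net.l0 = np.maximum(rod_lengths(net), 1e-12)
    check_planarity(net)  # raises PlanarityError naming the pair
    return net


def export_areole_graphml(graph, path: Union[str, Path]) -> None:
    """Write the areole adjacency graph (centroids, areas, boundary
    flags as attributes) as GraphML."""
    import networkx as nx

    G = nx.Graph()
    for ar in graph.areoles:
        G.add_node(
            ar.id,
            cx=float(ar.centroid[0]),
            cy=float(ar.centroid[1]),
            area=float(ar.area),
            boundary=bool(ar.boundary_flag),
        )
    for i, nbrs in graph.adjacency.items():
        for j in nbrs:
            if i < j:
                G.add_edge(i, j)
    nx.write_graphml(G, str(path))
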