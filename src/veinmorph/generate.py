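"""Synthetic vein-network generation.

Real dicot venation is hierarchical and reticulate: a thick primary
vein with successively thinner higher-order veins enclosing polygonal
areoles.  The generator emulates the statistics that matter downstream
— hierarchy, a dominant vein spanning the box along x, and areoles
tiling a periodic cell — with a sequential-insertion surrogate:

1. scaffold the torus with one horizontal loop (the primary vein) and
   one vertical loop, leaving a single face;
2. repeatedly pick a face with probability proportional to its area and
   insert a straight chord between two random points on its boundary,
   splitting one areole into two, until the requested count is reached;
3. assign thicknesses by creation order, h = rank^(-beta), normalized
   to unit mean;
4. relax node positions by a few thickness-weighted Laplacian smoothing
   sweeps (a Lloyd-style step) for rounder, more realistic areoles,
   rejecting any sweep that would invert or entangle a face.

Rest lengths are initialized to current lengths, so the network is
stress-free until it is equilibrated under turgor.

The default areole linear dimension (6 model units) together with unit
mean thickness, unit turgor and Young modulus 300 puts the equilibrated
rod strain near 0.02 and the mean tension per thickness near 6; see the
methods note for the calibration argument.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from shapely.geometry import LineString, Point, Polygon

from .faces import extract_faces
from .mechanics import equilibrate
from .network import PeriodicBox, VeinNetwork, rod_lengths, rod_tensions

__all__ = [
    "generate_reference_network",
    "optimize_thickness",
    "apply_thickness_noise",
    "ThicknessOptimizationError",
    "DEFAULT_GEOMETRY",
]

DEFAULT_GEOMETRY = {
    "mode": "hierarchical",  # or "grid"
    # creation-stage areole linear dimension (model units); frozen so
    # that the equilibrated mean tension per thickness comes out near 6
    # (hence typical strain near 6/mu = 0.02) via the virial relation
    # eta0 ~ 2 P W H / sum(h l) of the tiling
    "areole_size": 5.3,
    "beta": 0.25,  # thickness-vs-creation-rank exponent
    "smooth_iters": 25,
    "smooth_step": 0.3,
    "mu": 300.0,
    "nu": 1.0,
    "P_tur": 1.0,
}


class ThicknessOptimizationError(RuntimeError):
    def __init__(self, cv: float, tol: float, iterations: int):
        self.cv = cv
        super().__init__(
            f"thickness optimization did not converge in {iterations} iterations: "
            f"cv(T/h) = {cv:.4g} > tol = {tol:.4g}"
        )


@dataclass
class _Builder:
    """Mutable network-under-construction."""

    W: float
    H: float
    xs: list
    ys: list
    rods: list  # [a, b, sx, sy, rank]

    def as_network(self, **params) -> VeinNetwork:
        rods = np.asarray([r[:4] for r in self.rods], dtype=np.int64)
        net = VeinNetwork(
            PeriodicBox(self.W, self.H),
            np.asarray(self.xs),
            np.asarray(self.ys),
            rods[:, 0],
            rods[:, 1],
            rods[:, 2],
            rods[:, 3],
            np.ones(len(self.rods)),
            np.ones(len(self.rods)),
            **params,
        )
        return net

    def add_node(self, x: float, y: float) -> int:
        self.xs.append(x % self.W)
        self.ys.append(y % self.H)
        return len(self.xs) - 1

    def split_rod(self, rod_idx: int, u: int, pu: np.ndarray, p: np.ndarray) -> int:
        """Split a rod at unwrapped point ``p``; ``pu`` is the unwrapped
        position of endpoint ``u`` in the same frame.  Returns the new
        node index."""
        a, b, sx, sy, rank = self.rods[rod_idx]
        w = b if u == a else a
        # unwrapped position of the far endpoint in the same frame
        if u == a:
            pw = pu + np.array([self.xs[b] - self.xs[a] + sx * self.W,
                                self.ys[b] - self.ys[a] + sy * self.H])
        else:
            pw = pu - np.array([self.xs[b] - self.xs[a] + sx * self.W,
                                self.ys[b] - self.ys[a] + sy * self.H])
        n = self.add_node(p[0], p[1])
        s1 = self._shift(u, n, p - pu, pu)
        s2 = self._shift(n, w, pw - p, p)
        self.rods[rod_idx] = [u, n, s1[0], s1[1], rank]
        self.rods.append([n, w, s2[0], s2[1], rank])
        return n

    def _shift(self, a: int, b: int, vec: np.ndarray, _pa) -> tuple[int, int]:
        sx = round((vec[0] - (self.xs[b] - self.xs[a])) / self.W)
        sy = round((vec[1] - (self.ys[b] - self.ys[a])) / self.H)
        return int(sx), int(sy)

    def add_rod(self, a: int, b: int, vec: np.ndarray, rank: int) -> None:
        s = self._shift(a, b, vec, None)
        self.rods.append([a, b, s[0], s[1], rank])


def _grid_network(n_side: int, spacing: float, params: dict) -> VeinNetwork:
    n = n_side
    xs, ys, a, b, sx, sy = [], [], [], [], [], []
    for j in range(n):
        for i in range(n):
            xs.append(i * spacing)
            ys.append(j * spacing)
    for j in range(n):
        for i in range(n):
            v = j * n + i
            a.append(v)
            b.append(j * n + (i + 1) % n)
            sx.append(1 if i == n - 1 else 0)
            sy.append(0)
            a.append(v)
            b.append(((j + 1) % n) * n + i)
            sx.append(0)
            sy.append(1 if j == n - 1 else 0)
    m = len(a)
    net = VeinNetwork(
        PeriodicBox(n * spacing, n * spacing),
        xs, ys, a, b, sx, sy, np.ones(m), np.full(m, spacing),
        mu=params["mu"], nu=params["nu"], P_tur=params["P_tur"],
    )
    return net


def generate_reference_network(
    n_areoles: int, seed: int, geometry_params: dict | None = None
) -> VeinNetwork:
    """Create the initial rod network with ``n_areoles`` faces.

    ``geometry_params`` overrides :data:`DEFAULT_GEOMETRY`; with
    ``mode="grid"`` a square periodic lattice is produced instead of the
    hierarchical network (``n_areoles`` must then be a perfect square).
    The same seed always yields the identical network.
    """
    if n_areoles < 4:
        raise ValueError("n_areoles must be at least 4")
    params = dict(DEFAULT_GEOMETRY)
    params.update(geometry_params or {})
    mech = {k: params[k] for k in ("mu", "nu", "P_tur")}

    if params["mode"] == "grid":
        n_side = round(n_areoles**0.5)
        if n_side * n_side != n_areoles:
            raise ValueError(
                f"grid mode cannot tile {n_areoles} areoles: not a perfect square"
            )
        net = _grid_network(n_side, params["areole_size"], params)
        net.metadata.update({"seed": seed, "generator": "grid", "areole_scale": params["areole_size"]})
        return net
    if params["mode"] != "hierarchical":
        raise ValueError(f"unknown generation mode {params['mode']!r}")

    rng = np.random.default_rng(seed)
    L = params["areole_size"] * float(np.sqrt(n_areoles))
    y0 = (0.4 + 0.2 * rng.random()) * L
    x0 = (0.4 + 0.2 * rng.random()) * L
    b = _Builder(L, L, [], [], [])
    # primary vein: horizontal loop through (x0 +- L/2, y0); rank 1
    nA = b.add_node(x0 - L / 2.0, y0)
    nB = b.add_node(x0, y0)
    b.add_rod(nA, nB, np.array([L / 2.0, 0.0]), 1)
    b.add_rod(nB, nA, np.array([L / 2.0, 0.0]), 1)
    # first secondary: vertical loop through x0; rank 2
    nC = b.add_node(x0, y0 + L / 2.0)
    b.add_rod(nB, nC, np.array([0.0, L / 2.0]), 2)
    b.add_rod(nC, nB, np.array([0.0, L / 2.0]), 2)

    rank = 2
    faces_needed = n_areoles
    attempts_left = 200 * n_areoles
    while True:
        net = b.as_network(**mech)
        fset = extract_faces(net)
        if fset.n_faces >= faces_needed:
            break
        areas = np.array([f.area for f in fset.faces])
        if np.any(areas <= 0):  # pragma: no cover - construction invariant
            raise RuntimeError("face inversion during construction")
        # split the largest areole: keeps the size distribution tight,
        # as in real reticulate venation where big areoles are
        # subdivided first by new loops
        face = fset.faces[int(np.argmax(areas))]
        poly = Polygon(face.polygon)
        if not poly.is_valid:  # pragma: no cover
            raise RuntimeError("invalid face polygon during construction")
        k = len(face.nodes)
        verts = face.polygon
        nxt = np.roll(verts, -1, axis=0)
        best = None  # (quality, i, j, p1, p2, vec)
        tried = 0
        while attempts_left > 0 and (best is None or tried < 24):
            attempts_left -= 1
            tried += 1
            i, j = rng.integers(0, k, size=2)
            if i == j or face.rods[i] == face.rods[j]:
                continue
            t1, t2 = rng.uniform(0.2, 0.8, size=2)
            p1 = verts[i] + t1 * (nxt[i] - verts[i])
            p2 = verts[j] + t2 * (nxt[j] - verts[j])
            vec = p2 - p1
            seg_len = float(np.hypot(*vec))
            if seg_len < 0.15 * params["areole_size"]:
                continue
            inner = LineString([p1 + 1e-6 * vec, p2 - 1e-6 * vec])
            if not inner.within(poly):
                continue
            # chord must clear existing junctions
            if min(inner.distance(Point(v)) for v in verts) < 0.05 * params["areole_size"]:
                continue
            # score the two child faces by isoperimetric chunkiness
            # (4 pi A / P^2, 1 for a disk); slender children collapse
            # first under strong external stress
            lo, hi = (i, j) if i < j else (j, i)
            p_lo, p_hi = (p1, p2) if i < j else (p2, p1)
            child_a = np.vstack([[p_lo], verts[lo + 1 : hi + 1], [p_hi]])
            child_b = np.vstack([[p_hi], verts[hi + 1 :], verts[: lo + 1], [p_lo]])
            quality = np.inf
            for child in (child_a, child_b):
                cp = Polygon(child)
                if not cp.is_valid or cp.area <= 0:
                    quality = -1.0
                    break
                quality = min(quality, 4.0 * np.pi * cp.area / cp.length**2)
            if quality < 0.22:
                continue
            if best is None or quality > best[0]:
                best = (quality, i, j, p1, p2, vec)
        if best is None:
            raise RuntimeError(
                f"could not tile {n_areoles} areoles planarly (stuck at {fset.n_faces})"
            )
        _, i, j, p1, p2, vec = best
        rank += 1
        n1 = b.split_rod(face.rods[i], face.nodes[i], verts[i], p1)
        n2 = b.split_rod(face.rods[j], face.nodes[j], verts[j], p2)
        b.add_rod(n1, n2, vec, rank)

    # creation-order thickness hierarchy, unit mean
    ranks = np.array([r[4] for r in b.rods], dtype=float)
    h = ranks ** (-params["beta"])
    h /= h.mean()

    net = b.as_network(**mech)
    net.h = h
    # the primary vein stays straight along x: its nodes keep their y
    pin_y = np.zeros(net.n_nodes, dtype=bool)
    for (na, nb_, _sx, _sy, rk) in b.rods:
        if rk == 1:
            pin_y[na] = pin_y[nb_] = True
    _laplacian_smooth(net, n_areoles, params["smooth_iters"], params["smooth_step"], pin_y)
    net.l0 = rod_lengths(net)
    net.metadata.update({"seed": seed, "generator": "hierarchical", "areole_scale": params["areole_size"]})
    fset = extract_faces(net)
    if fset.n_faces != n_areoles:  # pragma: no cover - construction invariant
        raise RuntimeError(f"generator produced {fset.n_faces} faces, expected {n_areoles}")
    return net


def _laplacian_smooth(
    net: VeinNetwork, n_faces: int, iters: int, step: float, pin_y=None
) -> None:
    """Thickness-weighted Laplacian relaxation of node positions.

    Each sweep moves nodes toward the h-weighted mean of their
    neighbors (thick veins therefore stay straighter).  A sweep that
    would invert or entangle any face is rejected and the step halved.
    """
    from .network import rod_vectors

    a, bb = net.rod_a, net.rod_b
    for _ in range(iters):
        dx, dy = rod_vectors(net)
        wsum = np.zeros(net.n_nodes)
        px = np.zeros(net.n_nodes)
        py = np.zeros(net.n_nodes)
        np.add.at(wsum, a, net.h)
        np.add.at(wsum, bb, net.h)
        np.add.at(px, a, net.h * dx)
        np.add.at(py, a, net.h * dy)
        np.add.at(px, bb, -net.h * dx)
        np.add.at(py, bb, -net.h * dy)
        if pin_y is not None:
            py[pin_y] = 0.0
        old_x, old_y = net.x.copy(), net.y.copy()
        old_sx, old_sy = net.rod_sx.copy(), net.rod_sy.copy()
        net.x = net.x + step * px / wsum
        net.y = net.y + step * py / wsum
        net.wrap()
        fset = extract_faces(net)
        ok = fset.n_faces == n_faces and all(
            f.area > 1e-9 and Polygon(f.polygon).is_valid for f in fset.faces
        )
        if not ok:
            net.x, net.y = old_x, old_y
            net.rod_sx, net.rod_sy = old_sx, old_sy
            step *= 0.5
            if step < 0.02:
                return


def optimize_thickness(
    net: VeinNetwork, tol: float = 0.05, max_iter: int = 200
) -> VeinNetwork:
    """Iterate to the 'force model' fixed point: tension proportional to
    thickness.

    Alternates equilibration under turgor with the update
    ``h_i <- T_i * mean(h)/mean(T)`` (preserving mean thickness) until
    the coefficient of variation of T_i/h_i drops below ``tol``.  The
    bare update is unstable — tension condenses onto a backbone while
    rods left slack by the frozen rest lengths pin the residual — so
    each iteration also relaxes the rest lengths viscously toward the
    current lengths at the mean strain (the physical preparation of the
    ideal state: the rods are viscoelastic, and during the creation
    stage their rest lengths track the slowly evolving geometry).
    Topology and rod count are untouched.

    Raises
    ------
    ThicknessOptimizationError
        on non-convergence, reporting the final coefficient of
        variation.
    """
    net = net.copy()
    cv = np.inf
    for _ in range(max_iter):
        net = equilibrate(net)
        T = rod_tensions(net)
        s = T / net.h
        cv = float(np.std(s) / np.mean(s))
        if cv < tol:
            return net
        # floor keeps near-slack rods stiff enough that the embedding
        # stays planar under later deformation
        h_new = np.maximum(T, 0.02 * float(T.mean()))
        h_new *= net.h.mean() / h_new.mean()
        net.h = h_new
        l = rod_lengths(net)
        eps = float(np.mean(l / net.l0)) - 1.0
        net.l0 = l / (1.0 + eps)
    raise ThicknessOptimizationError(cv, tol, max_iter)


def apply_thickness_noise(net: VeinNetwork, r: float, seed: int) -> VeinNetwork:
    """Multiply every rod thickness by an independent U[1-r, 1+r] draw.

    The noise is frozen: positions, rest lengths and topology are
    unchanged.  ``r`` is the half-width of the uniform multiplier;
    ``r >= 1`` is rejected since thickness could become non-positive.
    """
    if not 0.0 <= r < 1.0:
        raise ValueError(f"noise half-width r must be in [0, 1), got {r}")
    out = net.copy()
    if r > 0:
        rng = np.random.default_rng(seed)
        out.h = out.h * rng.uniform(1.0 - r, 1.0 + r, size=out.n_rods)
    out.metadata["thickness_noise"] = {"r": r, "seed": seed}
    return out
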