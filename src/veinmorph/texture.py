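"""Texture-tensor morphometry and non-affinity quantification.

The areoles (regions enclosed by veins) are taken as the nodes of a
graph in which two areoles are linked when they share a vein.  For an
areole centered at r_i with N neighbors at r_k, the local texture
tensor is

    M_i = (1/N) sum_k (r_k - r_i) (x) (r_k - r_i)

a symmetric positive semi-definite 2x2 tensor whose determinant tracks
areole size, whose eigenvalue ratio defines the anisotropy (always
>= 1), and whose major eigenvector defines the orientation.  A smooth
tensor field is obtained by Gaussian averaging of the local tensors,
with the width sigma fixed by pi sigma^2 = 30 x mean areole area.

Between two times the non-affinity index of an areole compares the
growth of its local determinant with that of its smoothed neighborhood:

    q_i = [det M_i(t2) / det Mbar(r_i, t2)] / [det M_i(t1) / det Mbar(r_i, t1)]

q = 1 for every areole under any affine dilation; deviations from 1
quantify how differently an areole grew from its surroundings.  An
areal variant uses relative areal growth rates a_i = ln[S_i(t2)/S_i(t1)]
/(t2 - t1), smoothed the same way.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .faces import extract_faces
from .network import VeinNetwork, rod_vectors

__all__ = [
    "Areole",
    "AreoleGraph",
    "TextureTensor",
    "extract_areoles",
    "local_texture_tensor",
    "smoothing_width",
    "averaged_texture_tensor",
    "global_texture_tensor",
    "tensor_field",
    "non_affinity_index",
    "areal_non_affinity_index",
    "vein_orientation_histogram",
    "mean_surrounding_thickness",
    "summarize_realizations",
    "trajectory_q",
    "SMOOTHING_AREA_FACTOR",
]

#: pi sigma^2 equals this multiple of the mean areole area.
SMOOTHING_AREA_FACTOR = 30.0

#: relative eigenvalue gap below which a tensor counts as isotropic and
#: its orientation as unreliable.
ISOTROPY_RTOL = 1e-6


@dataclass(frozen=True)
class TextureTensor:
    """Symmetric 2x2 texture tensor with derived scalar descriptors."""

    M: np.ndarray

    def __post_init__(self):
        M = np.asarray(self.M, dtype=float)
        if M.shape != (2, 2) or abs(M[0, 1] - M[1, 0]) > 1e-9 * (1 + abs(M).max()):
            raise ValueError("texture tensor must be a symmetric 2x2 matrix")
        object.__setattr__(self, "M", M)

    @property
    def det(self) -> float:
        return float(np.linalg.det(self.M))

    @property
    def eigenvalues(self) -> tuple[float, float]:
        """(lambda_max, lambda_min)."""
        tr2 = 0.5 * (self.M[0, 0] + self.M[1, 1])
        disc = np.hypot(0.5 * (self.M[0, 0] - self.M[1, 1]), self.M[0, 1])
        return float(tr2 + disc), float(tr2 - disc)

    @property
    def anisotropy(self) -> float:
        """Ratio of larger to smaller eigenvalue; inf for rank-1 tensors."""
        lmax, lmin = self.eigenvalues
        if lmin <= ISOTROPY_RTOL * lmax:
            return float("inf")
        return lmax / lmin

    @property
    def orientation_deg(self) -> float:
        """Angle of the major eigenvector, degrees in [0, 180)."""
        ang = 0.5 * np.degrees(
            np.arctan2(2.0 * self.M[0, 1], self.M[0, 0] - self.M[1, 1])
        )
        return float(ang % 180.0)

    @property
    def orientation_reliable(self) -> bool:
        lmax, lmin = self.eigenvalues
        return lmax > 0 and (lmax - lmin) > ISOTROPY_RTOL * lmax


@dataclass
class Areole:
    id: int
    boundary_nodes: list[int]
    boundary_rods: list[int]
    centroid: tuple[float, float]
    area: float
    boundary_flag: bool = False  # touches the outer face (open domains)


@dataclass
class AreoleGraph:
    """Areoles of a network with their shared-vein adjacency."""

    areoles: list[Areole]
    adjacency: dict[int, list[int]]
    periodic: bool
    W: float
    H: float
    _local: Optional[np.ndarray] = field(default=None, repr=False)

    @property
    def n_areoles(self) -> int:
        return len(self.areoles)

    @property
    def centroids(self) -> np.ndarray:
        return np.array([a.centroid for a in self.areoles])

    @property
    def areas(self) -> np.ndarray:
        return np.array([a.area for a in self.areoles])

    @property
    def interior_mask(self) -> np.ndarray:
        return np.array([not a.boundary_flag for a in self.areoles])

    def separation(self, p: np.ndarray, q: np.ndarray) -> np.ndarray:
        """Displacement q - p (minimum image for periodic domains)."""
        d = np.asarray(q, dtype=float) - np.asarray(p, dtype=float)
        if self.periodic:
            d = d - np.round(d / [self.W, self.H]) * [self.W, self.H]
        return d

    def local_tensors(self) -> np.ndarray:
        """(n, 2, 2) array of local texture tensors; NaN for boundary areoles."""
        if self._local is None:
            n = self.n_areoles
            cents = self.centroids
            out = np.full((n, 2, 2), np.nan)
            for i, ar in enumerate(self.areoles):
                if ar.boundary_flag:
                    continue
                nbrs = self.adjacency[ar.id]
                d = self.separation(cents[i], cents[nbrs])
                out[i] = d.T @ d / len(nbrs)
            self._local = out
        return self._local


def extract_areoles(
    net: VeinNetwork, periodic: Optional[bool] = None, validate: bool = False
) -> AreoleGraph:
    """Enumerate the areoles of a planar embedded rod network.

    On periodic domains every face is an areole and the areas tile the
    box (checked, along with Euler's formula V - E + F = 0 on the
    torus).  On open domains the outer face is discarded and areoles
    touching it are flagged boundary (their texture tensor is
    undefined).  With ``validate=True`` crossing rods are detected first
    and reported.
    """
    if periodic is None:
        periodic = net.periodic
    fset = extract_faces(net, validate=validate)
    V, E, F = net.n_nodes, net.n_rods, fset.n_faces
    faces = fset.faces
    outer_ids: set[int] = set()
    if periodic:
        if V - E + F != 0:
            raise ValueError(
                f"Euler characteristic V-E+F = {V - E + F} != 0: not a torus embedding"
            )
        if abs(sum(f.area for f in faces) - net.box.area) > 1e-6 * net.box.area:
            raise ValueError("face areas do not tile the periodic box")
    else:
        if V - E + F != 2:
            raise ValueError(
                f"Euler characteristic V-E+F = {V - E + F} != 2: not a planar embedding"
            )
        outer = [f.id for f in faces if f.area < 0]
        if len(outer) != 1:
            raise ValueError(f"expected one outer face, found {len(outer)}")
        outer_ids = set(outer)

    # adjacency through shared rods
    neighbor_sets: dict[int, set[int]] = {f.id: set() for f in faces}
    for rod in range(net.n_rods):
        f1, f2 = fset.rod_faces(rod)
        if f1 != f2:
            neighbor_sets[f1].add(f2)
            neighbor_sets[f2].add(f1)

    areoles: list[Areole] = []
    id_map: dict[int, int] = {}
    for f in faces:
        if f.id in outer_ids:
            continue
        id_map[f.id] = len(areoles)
        W, H = net.box.W, net.box.H
        cx, cy = f.centroid
        if periodic:
            cx, cy = cx % W, cy % H
        areoles.append(
            Areole(
                id=len(areoles),
                boundary_nodes=f.nodes,
                boundary_rods=f.rods,
                centroid=(cx, cy),
                area=f.area,
                boundary_flag=bool(neighbor_sets[f.id] & outer_ids),
            )
        )
    adjacency = {
        id_map[f.id]: sorted(id_map[g] for g in neighbor_sets[f.id] if g not in outer_ids)
        for f in faces
        if f.id not in outer_ids
    }
    return AreoleGraph(areoles, adjacency, periodic, net.box.W, net.box.H)


def local_texture_tensor(graph: AreoleGraph, areole_id: int) -> TextureTensor:
    """Local texture tensor of one areole (mean outer product of
    centroid-to-neighbor vectors).

    Raises ``ValueError`` for boundary areoles of open domains, where
    the tensor is undefined.
    """
    ar = graph.areoles[areole_id]
    if ar.boundary_flag:
        raise ValueError(f"texture tensor undefined for boundary areole {areole_id}")
    return TextureTensor(graph.local_tensors()[areole_id])


def smoothing_width(graph: AreoleGraph) -> float:
    """Gaussian width sigma with pi sigma^2 = 30 x mean areole area."""
    interior = graph.interior_mask
    mean_area = float(graph.areas[interior].mean())
    return float(np.sqrt(SMOOTHING_AREA_FACTOR * mean_area / np.pi))


def _gaussian_weights(graph: AreoleGraph, point: np.ndarray, sigma: float) -> np.ndarray:
    d = graph.separation(point, graph.centroids)
    w = np.exp(-np.sum(d**2, axis=1) / (2.0 * sigma**2))
    w[~graph.interior_mask] = 0.0
    return w


def averaged_texture_tensor(
    graph: AreoleGraph, point: Sequence[float], sigma: Optional[float] = None
) -> TextureTensor:
    """Gaussian-weighted average of the local tensors, evaluated at
    ``point`` (the areole's own tensor is included at weight 1 when the
    point is its centroid)."""
    if sigma is None:
        sigma = smoothing_width(graph)
    if sigma <= 0:
        raise ValueError("sigma must be positive")
    w = _gaussian_weights(graph, np.asarray(point, dtype=float), sigma)
    if not np.any(w > 0):
        raise ValueError("no interior areole contributes at this point")
    M = np.tensordot(w, np.nan_to_num(graph.local_tensors()), axes=1) / w.sum()
    return TextureTensor(M)


def _averaged_all(graph: AreoleGraph, sigma: float) -> np.ndarray:
    """Averaged tensor evaluated at every areole centroid; (n, 2, 2)."""
    cents = graph.centroids
    local = np.nan_to_num(graph.local_tensors())
    interior = graph.interior_mask.astype(float)
    d = cents[:, None, :] - cents[None, :, :]
    if graph.periodic:
        box = np.array([graph.W, graph.H])
        d = d - np.round(d / box) * box
    w = np.exp(-np.sum(d**2, axis=2) / (2.0 * sigma**2)) * interior[None, :]
    return np.einsum("ij,jkl->ikl", w, local) / w.sum(axis=1)[:, None, None]


def global_texture_tensor(graph: AreoleGraph) -> TextureTensor:
    """Unweighted mean of all interior local tensors: the whole-network
    texture ellipse (the sigma -> infinity limit of the averaged field)."""
    local = graph.local_tensors()[graph.interior_mask]
    return TextureTensor(local.mean(axis=0))


def tensor_field(
    graph: AreoleGraph, sigma: Optional[float] = None, normalize: bool = False
) -> pd.DataFrame:
    """Per-areole scalar descriptors of the local and averaged tensors.

    Columns: areole_id, cx, cy, area, boundary_flag, det_local,
    det_avg, lambda_max, anisotropy, orientation_deg,
    orientation_reliable, anisotropy_local.  Rank-1 tensors get
    infinite anisotropy and are excluded from any mean the caller
    computes via ``np.isfinite`` masking.  With ``normalize=True``,
    det_avg and lambda_max are divided by their interior means
    (per-leaf normalization).
    """
    if sigma is None:
        sigma = smoothing_width(graph)
    avg = _averaged_all(graph, sigma)
    rows = []
    for i, ar in enumerate(graph.areoles):
        row = {
            "areole_id": ar.id,
            "cx": ar.centroid[0],
            "cy": ar.centroid[1],
            "area": ar.area,
            "boundary_flag": ar.boundary_flag,
        }
        if ar.boundary_flag:
            row.update(
                det_local=np.nan, det_avg=np.nan, lambda_max=np.nan,
                anisotropy=np.nan, orientation_deg=np.nan,
                orientation_reliable=False, anisotropy_local=np.nan,
            )
        else:
            tl = TextureTensor(graph.local_tensors()[i])
            ta = TextureTensor(avg[i])
            row.update(
                det_local=tl.det,
                det_avg=ta.det,
                lambda_max=ta.eigenvalues[0],
                anisotropy=ta.anisotropy,
                orientation_deg=ta.orientation_deg,
                orientation_reliable=ta.orientation_reliable,
                anisotropy_local=tl.anisotropy,
            )
        rows.append(row)
    df = pd.DataFrame(rows)
    if normalize:
        for col in ("det_avg", "lambda_max"):
            df[col] = df[col] / df.loc[~df.boundary_flag, col].mean()
    return df


def _check_matching(g1: AreoleGraph, g2: AreoleGraph) -> None:
    if g1.n_areoles != g2.n_areoles:
        raise ValueError(
            f"areole sets differ: {g1.n_areoles} vs {g2.n_areoles} areoles"
        )
    if g1.adjacency != g2.adjacency:
        raise ValueError("areole adjacency differs between the two times")


def non_affinity_index(graph_t1: AreoleGraph, graph_t2: AreoleGraph) -> pd.DataFrame:
    """Determinant-ratio non-affinity index q per areole between two
    time points (frozen topology).

    The smoothing width is recomputed from the mean areole area at each
    time.  Areoles where any of the four determinants is non-positive,
    and boundary areoles, carry q = NaN (excluded but reported).
    Returns a DataFrame with columns ``areole_id`` and ``q``.
    """
    _check_matching(graph_t1, graph_t2)
    q = np.full(graph_t1.n_areoles, np.nan)
    dets = []
    for g in (graph_t1, graph_t2):
        sigma = smoothing_width(g)
        d_loc = np.linalg.det(g.local_tensors())
        d_avg = np.linalg.det(_averaged_all(g, sigma))
        dets.append((d_loc, d_avg))
    (d1l, d1a), (d2l, d2a) = dets
    with np.errstate(invalid="ignore", divide="ignore"):
        valid = (
            graph_t1.interior_mask
            & (d1l > 0) & (d1a > 0) & (d2l > 0) & (d2a > 0)
        )
        q[valid] = (d2l[valid] / d2a[valid]) / (d1l[valid] / d1a[valid])
    return pd.DataFrame({"areole_id": np.arange(graph_t1.n_areoles), "q": q})


def areal_non_affinity_index(
    graph_t1: AreoleGraph, graph_t2: AreoleGraph, t1: float, t2: float
) -> pd.DataFrame:
    """Areal-growth variant of the non-affinity index.

    The relative areal growth rate a_i = ln[S_i(t2)/S_i(t1)]/(t2 - t1)
    is smoothed with the same Gaussian kernel as the texture field (on
    the t1 geometry); the index is a_i / abar(r_i).  A network with no
    growth gives 0/0, reported as NaN.
    """
    if not t2 > t1:
        raise ValueError("t2 must exceed t1")
    _check_matching(graph_t1, graph_t2)
    S1, S2 = graph_t1.areas, graph_t2.areas
    if np.any(S1[graph_t1.interior_mask] <= 0) or np.any(S2[graph_t2.interior_mask] <= 0):
        raise ValueError("areole areas must be positive")
    a = np.log(S2 / S1) / (t2 - t1)
    sigma = smoothing_width(graph_t1)
    cents = graph_t1.centroids
    interior = graph_t1.interior_mask
    abar = np.full_like(a, np.nan)
    for i in np.flatnonzero(interior):
        w = _gaussian_weights(graph_t1, cents[i], sigma)
        abar[i] = np.sum(w * np.where(interior, a, 0.0)) / w.sum()
    with np.errstate(invalid="ignore", divide="ignore"):
        idx = np.where(interior & (abar != 0), a / abar, np.nan)
    return pd.DataFrame(
        {"areole_id": np.arange(graph_t1.n_areoles), "a": a, "a_ratio": idx}
    )


def vein_orientation_histogram(
    net: VeinNetwork, weights: str = "none", bins: int = 18
) -> pd.DataFrame:
    """Histogram of rod orientations folded into [0, 180) degrees.

    ``weights``: "none" counts rods, "length" weights by current rod
    length.  Returns a DataFrame with bin edges and (normalized)
    frequencies.
    """
    if net.n_rods == 0:
        raise ValueError("network has no rods")
    if weights not in ("none", "length"):
        raise ValueError("weights must be 'none' or 'length'")
    dx, dy = rod_vectors(net)
    ang = np.degrees(np.arctan2(dy, dx)) % 180.0
    w = np.hypot(dx, dy) if weights == "length" else None
    counts, edges = np.histogram(ang, bins=bins, range=(0.0, 180.0), weights=w)
    return pd.DataFrame(
        {
            "bin_left": edges[:-1],
            "bin_right": edges[1:],
            "count": counts,
            "frequency": counts / counts.sum(),
        }
    )


def mean_surrounding_thickness(graph: AreoleGraph, net: VeinNetwork) -> np.ndarray:
    """Per-areole mean thickness of the veins on its boundary."""
    return np.array([net.h[a.boundary_rods].mean() for a in graph.areoles])


def trajectory_q(traj) -> pd.DataFrame:
    """Non-affinity between the first and last snapshots of a growth run.

    Returns the determinant-ratio index ``q``, the areal variant
    ``q_areal`` (when the run spans nonzero time), and the mean
    surrounding initial vein thickness per areole."""
    g1 = extract_areoles(traj.initial)
    g2 = extract_areoles(traj.final)
    df = non_affinity_index(g1, g2)
    t1, t2 = traj.times[0], traj.times[-1]
    if t2 > t1:
        areal = areal_non_affinity_index(g1, g2, t1, t2)
        df["q_areal"] = areal["a_ratio"]
    else:
        df["q_areal"] = np.nan
    df["mean_thickness"] = mean_surrounding_thickness(g1, traj.initial)
    return df


def _pool_check(trajs) -> None:
    laws = {(t.law.kind, t.law.eta_star) for t in trajs if t.law is not None}
    sigmas = {(t.initial.sigma_xx, t.initial.sigma_yy) for t in trajs}
    if len(laws) > 1 or len(sigmas) > 1:
        raise ValueError(
            f"mixed configurations in one pool: laws {laws}, stresses {sigmas}"
        )


def summarize_realizations(
    runs: Mapping[str, Sequence], thickness_bins: int = 5
) -> dict[str, pd.DataFrame]:
    """Summary statistics over repeated growth runs.

    ``runs`` maps a condition label to the trajectories realized under
    that condition (all with identical law and stress — mixed pools are
    rejected).  Returns four tables:

    - ``anisotropy``: mean and sd across runs of the final whole-network
      texture anisotropy and orientation, with the applied stress;
    - ``q_stats``: pooled non-affinity mean, sd and count per condition;
    - ``q_values``: the pooled per-areole q values (long format);
    - ``q_by_thickness``: q binned by mean surrounding vein thickness
      (quantile bins), with mean +/- one standard deviation bands;
    - ``orientation``: pooled per-areole texture orientations of the
      final states.
    """
    anis_rows, q_rows, qv_rows, qt_rows, or_rows = [], [], [], [], []
    for label, trajs in runs.items():
        _pool_check(trajs)
        anis, orients, qs, ths = [], [], [], []
        for traj in trajs:
            g_end = extract_areoles(traj.final)
            gt = global_texture_tensor(g_end)
            anis.append(gt.anisotropy)
            tf = tensor_field(g_end)
            or_rows.extend(
                {"condition": label, "orientation_deg": v}
                for v in tf.loc[tf.orientation_reliable, "orientation_deg"]
            )
            orients.append(gt.orientation_deg)
            dfq = trajectory_q(traj)
            qs.append(dfq["q"].to_numpy())
            ths.append(dfq["mean_thickness"].to_numpy())
        q = np.concatenate(qs)
        th = np.concatenate(ths)
        ok = np.isfinite(q)
        q, th = q[ok], th[ok]
        t0 = trajs[0].initial
        anis_rows.append(
            {
                "condition": label,
                "sigma_xx": t0.sigma_xx,
                "sigma_yy": t0.sigma_yy,
                "anisotropy_mean": float(np.mean(anis)),
                "anisotropy_sd": float(np.std(anis)),
                "orientation_mean": float(np.mean(orients)),
                "n_runs": len(trajs),
            }
        )
        q_rows.append(
            {
                "condition": label,
                "q_mean": float(q.mean()),
                "q_sd": float(q.std()),
                "n_areoles": int(q.size),
            }
        )
        qv_rows.extend({"condition": label, "q": float(v)} for v in q)
        edges = np.quantile(th, np.linspace(0, 1, thickness_bins + 1))
        which = np.clip(np.searchsorted(edges, th, side="right") - 1, 0, thickness_bins - 1)
        for bi in range(thickness_bins):
            sel = which == bi
            if not np.any(sel):
                continue
            qt_rows.append(
                {
                    "condition": label,
                    "thickness_mean": float(th[sel].mean()),
                    "q_mean": float(q[sel].mean()),
                    "q_sd": float(q[sel].std()),
                    "n": int(sel.sum()),
                }
            )
    return {
        "anisotropy": pd.DataFrame(anis_rows),
        "q_stats": pd.DataFrame(q_rows),
        "q_values": pd.DataFrame(qv_rows),
        "q_by_thickness": pd.DataFrame(qt_rows),
        "orientation": pd.DataFrame(or_rows),
    }
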