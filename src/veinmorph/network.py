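"""Core data structures: periodic box, rods, and the vein network state.

A vein network is a planar graph embedded on a torus (or, for digitized
leaves, in the plane).  Nodes are vein junctions; each edge is a straight
viscoelastic rod with a thickness ``h`` and a stress-free rest length
``l0``.  Rods may wrap around the periodic cell; the integer shifts
``(sx, sy)`` record how many box images separate the two endpoints, so a
rod's geometric vector is ``(x_b - x_a + sx*W, y_b - y_a + sy*H)``.

The network also carries the material and loading parameters: Young
modulus ``mu``, viscosity ``nu``, turgor pressure ``P_tur`` and the
external stress components ``sigma_xx`` / ``sigma_yy``.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterator, Optional

import numpy as np

__all__ = [
    "PeriodicBox",
    "Node",
    "Rod",
    "VeinNetwork",
    "rod_vectors",
    "rod_lengths",
    "rod_length",
    "rod_tensions",
    "rod_tension",
]


@dataclass
class PeriodicBox:
    """Rectangular periodic cell of dimensions W x H.

    ``W0``/``H0`` are the reference dimensions used by the anisotropic
    stress term: the equilibrium box obtained with no external stress.
    They are unset (``None``) until computed.
    """

    W: float
    H: float
    W0: Optional[float] = None
    H0: Optional[float] = None

    def __post_init__(self) -> None:
        if not (self.W > 0 and self.H > 0):
            raise ValueError(f"box dimensions must be positive, got W={self.W}, H={self.H}")
        for name in ("W0", "H0"):
            v = getattr(self, name)
            if v is not None and not v > 0:
                raise ValueError(f"{name} must be positive if set, got {v}")

    @property
    def area(self) -> float:
        return self.W * self.H

    def has_reference(self) -> bool:
        return self.W0 is not None and self.H0 is not None

    def copy(self) -> "PeriodicBox":
        return PeriodicBox(self.W, self.H, self.W0, self.H0)


@dataclass(frozen=True)
class Node:
    """Read-only record view of one node."""

    id: int
    x: float
    y: float


@dataclass(frozen=True)
class Rod:
    """Read-only record view of one rod."""

    id: int
    a: int
    b: int
    sx: int
    sy: int
    h: float
    l0: float


class VeinNetwork:
    """Mechanical state of a vein network.

    Node coordinates and rod attributes are stored as flat numpy arrays
    (struct-of-arrays) so the energy and its gradient vectorize; the
    :class:`Node` / :class:`Rod` record views are provided for
    convenience and serialization.

    Parameters
    ----------
    box : PeriodicBox
    x, y : arrays of node coordinates, wrapped into [0, W) x [0, H)
        for periodic networks.
    rod_a, rod_b : integer arrays of endpoint node indices.
    rod_sx, rod_sy : integer periodic image shifts of endpoint ``b``.
    h, l0 : rod thicknesses and rest lengths (> 0).
    mu, nu : Young modulus and viscosity of the rods.
    P_tur : turgor pressure (energy -P_tur * W * H favours expansion).
    sigma_xx, sigma_yy : external stress components.
    periodic : False for digitized open networks (shifts all zero).
    """

    def __init__(
        self,
        box: PeriodicBox,
        x: np.ndarray,
        y: np.ndarray,
        rod_a: np.ndarray,
        rod_b: np.ndarray,
        rod_sx: np.ndarray,
        rod_sy: np.ndarray,
        h: np.ndarray,
        l0: np.ndarray,
        *,
        mu: float = 300.0,
        nu: float = 1.0,
        P_tur: float = 1.0,
        sigma_xx: float = 0.0,
        sigma_yy: float = 0.0,
        periodic: bool = True,
        metadata: Optional[dict] = None,
    ) -> None:
        self.box = box
        self.x = np.asarray(x, dtype=float).copy()
        self.y = np.asarray(y, dtype=float).copy()
        self.rod_a = np.asarray(rod_a, dtype=np.int64).copy()
        self.rod_b = np.asarray(rod_b, dtype=np.int64).copy()
        self.rod_sx = np.asarray(rod_sx, dtype=np.int64).copy()
        self.rod_sy = np.asarray(rod_sy, dtype=np.int64).copy()
        self.h = np.asarray(h, dtype=float).copy()
        self.l0 = np.asarray(l0, dtype=float).copy()
        self.mu = float(mu)
        self.nu = float(nu)
        self.P_tur = float(P_tur)
        self.sigma_xx = float(sigma_xx)
        self.sigma_yy = float(sigma_yy)
        self.periodic = bool(periodic)
        self.eta0: Optional[float] = None  # mean T/h at the unstressed equilibrium
        self.metadata: dict = dict(metadata or {})
        self.validate()

    # -- basic introspection ------------------------------------------------

    @property
    def n_nodes(self) -> int:
        return self.x.size

    @property
    def n_rods(self) -> int:
        return self.rod_a.size

    def nodes(self) -> Iterator[Node]:
        for i in range(self.n_nodes):
            yield Node(i, float(self.x[i]), float(self.y[i]))

    def rods(self) -> Iterator[Rod]:
        for j in range(self.n_rods):
            yield Rod(
                j,
                int(self.rod_a[j]),
                int(self.rod_b[j]),
                int(self.rod_sx[j]),
                int(self.rod_sy[j]),
                float(self.h[j]),
                float(self.l0[j]),
            )

    def degrees(self) -> np.ndarray:
        deg = np.zeros(self.n_nodes, dtype=np.int64)
        np.add.at(deg, self.rod_a, 1)
        np.add.at(deg, self.rod_b, 1)
        return deg

    def validate(self) -> None:
        n = self.n_nodes
        if self.y.size != n:
            raise ValueError("x and y must have the same length")
        m = self.n_rods
        for arr, name in (
            (self.rod_b, "rod_b"),
            (self.rod_sx, "rod_sx"),
            (self.rod_sy, "rod_sy"),
            (self.h, "h"),
            (self.l0, "l0"),
        ):
            if arr.size != m:
                raise ValueError(f"{name} has length {arr.size}, expected {m}")
        if m:
            if self.rod_a.min() < 0 or self.rod_a.max() >= n:
                raise ValueError("rod endpoint index out of range")
            if self.rod_b.min() < 0 or self.rod_b.max() >= n:
                raise ValueError("rod endpoint index out of range")
            if not np.all(self.h > 0):
                raise ValueError("rod thicknesses must be positive")
            if not np.all(self.l0 > 0):
                raise ValueError("rod rest lengths must be positive")
        if not self.periodic and m and (np.any(self.rod_sx) or np.any(self.rod_sy)):
            raise ValueError("open (non-periodic) networks cannot have wrapping rods")

    # -- geometry -----------------------------------------------------------

    def wrap(self) -> None:
        """Wrap node coordinates back into the box (periodic networks only).

        Rod image shifts are adjusted in step, so every rod keeps its
        geometric vector exactly.
        """
        if not self.periodic:
            return
        kx = np.floor(self.x / self.box.W).astype(np.int64)
        ky = np.floor(self.y / self.box.H).astype(np.int64)
        self.x = self.x - kx * self.box.W
        self.y = self.y - ky * self.box.H
        self.rod_sx += kx[self.rod_b] - kx[self.rod_a]
        self.rod_sy += ky[self.rod_b] - ky[self.rod_a]

    def copy(self) -> "VeinNetwork":
        net = VeinNetwork(
            self.box.copy(),
            self.x,
            self.y,
            self.rod_a,
            self.rod_b,
            self.rod_sx,
            self.rod_sy,
            self.h,
            self.l0,
            mu=self.mu,
            nu=self.nu,
            P_tur=self.P_tur,
            sigma_xx=self.sigma_xx,
            sigma_yy=self.sigma_yy,
            periodic=self.periodic,
            metadata=self.metadata,
        )
        net.eta0 = self.eta0
        return net


# -- vectorized geometry helpers -------------------------------------------


def rod_vectors(net: VeinNetwork) -> tuple[np.ndarray, np.ndarray]:
    """Per-rod displacement vectors (dx, dy) from endpoint a to endpoint b,
    including the stored periodic image shifts."""
    dx = net.x[net.rod_b] - net.x[net.rod_a] + net.rod_sx * net.box.W
    dy = net.y[net.rod_b] - net.y[net.rod_a] + net.rod_sy * net.box.H
    return dx, dy


def rod_lengths(net: VeinNetwork) -> np.ndarray:
    dx, dy = rod_vectors(net)
    return np.hypot(dx, dy)


def rod_length(net: VeinNetwork, rod_index: int) -> float:
    """Current Euclidean length of one rod, using its image shifts."""
    return float(rod_lengths(net)[rod_index])


def rod_tensions(net: VeinNetwork) -> np.ndarray:
    """Tension T_i = mu * h_i * (l_i / l0_i - 1) for every rod.

    Negative values mean the rod is compressed (the rods are linear
    springs in both directions).
    """
    l = rod_lengths(net)
    return net.mu * net.h * (l / net.l0 - 1.0)


def rod_tension(net: VeinNetwork, rod_index: int) -> float:
    return float(rod_tensions(net)[rod_index])
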