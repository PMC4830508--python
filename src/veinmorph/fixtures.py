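"""Deterministic test networks with known analytic properties."""

from __future__ import annotations

import numpy as np

from .generate import generate_reference_network
from .network import PeriodicBox, VeinNetwork

__all__ = ["make_fixture", "FIXTURE_KINDS"]

FIXTURE_KINDS = ("square_lattice", "honeycomb", "hierarchical_small")


def make_fixture(kind: str, n: int, seed: int = 0, **kwargs) -> VeinNetwork:
    """Build a deterministic fixture network.

    - ``square_lattice``: n x n periodic square lattice, unit spacing by
      default (``spacing=``).  Closed-form equilibrium: the spacing a
      solves mu h (a/a0 - 1) = P a.
    - ``honeycomb``: periodic regular honeycomb of n x n rectangular
      cells (2 hexagons per cell); for ``n >= 3`` every areole has six
      distinct neighbors and its local texture tensor is isotropic by
      symmetry.
    - ``hierarchical_small``: small hierarchical generated network.
    """
    if kind == "square_lattice":
        spacing = kwargs.pop("spacing", 1.0)
        net = generate_reference_network(
            n * n, seed, {"mode": "grid", "areole_size": spacing, **kwargs}
        )
        return net
    if kind == "honeycomb":
        return _honeycomb(n, spacing=kwargs.pop("spacing", 1.0), **kwargs)
    if kind == "hierarchical_small":
        return generate_reference_network(n, seed, kwargs or None)
    raise ValueError(f"unsupported fixture kind {kind!r}; choose from {FIXTURE_KINDS}")


def _honeycomb(n: int, spacing: float = 1.0, **mech) -> VeinNetwork:
    """Periodic regular honeycomb: n x n cells of 4 nodes / 6 rods /
    2 hexagonal faces each (all edges length ``spacing``)."""
    if n < 2:
        raise ValueError("honeycomb fixture needs n >= 2 cells per side")
    s = spacing
    hw = np.sqrt(3.0) / 2.0 * s  # half hexagon width
    cw, ch = 2.0 * hw, 3.0 * s  # rectangular cell: 4 nodes, 2 hexagons
    base = [
        (0.0, 0.0),
        (hw, 0.5 * s),
        (hw, 1.5 * s),
        (0.0, 2.0 * s),
    ]
    xs, ys = [], []
    for j in range(n):
        for i in range(n):
            for bx, by in base:
                xs.append(i * cw + bx)
                ys.append(j * ch + by)
    W, H = n * cw, n * ch

    def node(i, j, k):
        return ((j % n) * n + (i % n)) * 4 + k

    a_l, b_l, sx_l, sy_l = [], [], [], []

    def add(i, j, k1, di, dj, k2):
        a_l.append(node(i, j, k1))
        b_l.append(node(i + di, j + dj, k2))
        sx_l.append(1 if i + di >= n else (-1 if i + di < 0 else 0))
        sy_l.append(1 if j + dj >= n else (-1 if j + dj < 0 else 0))

    for j in range(n):
        for i in range(n):
            add(i, j, 0, 0, 0, 1)  # up-right diagonal
            add(i, j, 1, 0, 0, 2)  # vertical
            add(i, j, 2, 0, 0, 3)  # up-left diagonal
            add(i, j, 3, 0, 1, 0)  # vertical into the next row
            add(i, j, 0, -1, 0, 1)  # up-left diagonal into previous column
            add(i, j, 3, -1, 0, 2)  # down-left diagonal into previous column
    m = len(a_l)
    net = VeinNetwork(
        PeriodicBox(W, H),
        xs,
        ys,
        a_l,
        b_l,
        sx_l,
        sy_l,
        np.ones(m),
        np.ones(m),
        **mech,
    )
    from .network import rod_lengths

    net.l0 = rod_lengths(net)
    net.metadata.update({"generator": "honeycomb", "n": n, "spacing": spacing})
    return net
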