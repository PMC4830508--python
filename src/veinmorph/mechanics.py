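"""Quasi-static mechanics and growth of periodic rod networks.

The elastic energy of the network is

    E = sum_i 1/2 mu h_i l0_i (l_i/l0_i - 1)^2  -  P_tur W H  -  E_ani
    E_ani = H0 (W - W0) sigma_xx + W0 (H - H0) sigma_yy

where the sum runs over rods, ``P_tur`` is the turgor pressure acting
through the box area, and the anisotropic term applies an external
stress relative to the reference box (W0, H0), itself defined as the
equilibrium box with no external stress.  The spring prefactor uses the
rest length ``l0`` so that dE/dl reproduces the rod tension
``T = mu h (l/l0 - 1)`` exactly.

Equilibration minimizes E jointly over all node coordinates and the box
dimensions with a quasi-Newton method (L-BFGS-B with analytic
gradients).  Internally the node coordinates are treated as fractions of
the box, so a change of (W, H) rescales the network affinely before the
nodes relax.

Growth is viscoelastoplastic: rest lengths evolve by an explicit Euler
step of the chosen growth law (rates below), and the network is
re-equilibrated after each step (quasi-static limit).  With the
threshold ("Lockhart") law, rods below the yield tension do not grow at
all, so a state with all tensions below threshold is an exact fixed
point.

Growth laws, written for the relative rate (1/l0) dl0/dt with s = T/h
and yield stress eta = eta_star * eta0:

    linear     s / nu
    threshold  max(0, s - eta) / nu
    quadratic  s^2 / (eta nu)
    maximum    s exp(1 - s/eta) / nu
    saturation s / ((1 + s/eta) nu)
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy.optimize import minimize

from .network import PeriodicBox, VeinNetwork, rod_lengths, rod_tensions

__all__ = [
    "GrowthLaw",
    "SimulationConfig",
    "Trajectory",
    "EquilibrationError",
    "GrowthStalledError",
    "elastic_energy",
    "anisotropic_energy",
    "energy_and_gradient",
    "equilibrate",
    "compute_reference_dims",
    "measure_eta0",
    "growth_rate",
    "growth_rates",
    "grow_step",
    "run_simulation",
    "GROWTH_LAW_KINDS",
]

GROWTH_LAW_KINDS = ("linear", "threshold", "quadratic", "maximum", "saturation")


class EquilibrationError(RuntimeError):
    """Energy minimization failed to reach the requested gradient tolerance."""

    def __init__(self, residual: float, tol: float):
        self.residual = residual
        self.tol = tol
        super().__init__(
            f"equilibration did not converge: max |dE/dx| = {residual:.3e} > tol = {tol:.3e}"
        )


class GrowthStalledError(RuntimeError):
    """Area growth stalled (e.g. all tensions below the yield threshold)."""

    def __init__(self, trajectory: "Trajectory", message: str):
        self.trajectory = trajectory
        super().__init__(message)


# ---------------------------------------------------------------------------
# energy
# ---------------------------------------------------------------------------


def anisotropic_energy(box: PeriodicBox, sigma_xx: float, sigma_yy: float) -> float:
    """External-stress energy H0 (W - W0) sigma_xx + W0 (H - H0) sigma_yy."""
    if sigma_xx == 0.0 and sigma_yy == 0.0:
        return 0.0
    if not box.has_reference():
        raise ValueError(
            "reference box dimensions (W0, H0) are unset; run compute_reference_dims first"
        )
    return box.H0 * (box.W - box.W0) * sigma_xx + box.W0 * (box.H - box.H0) * sigma_yy


def elastic_energy(net: VeinNetwork) -> float:
    """Total energy: spring terms minus turgor work minus anisotropic term."""
    l = rod_lengths(net)
    strain = l / net.l0 - 1.0
    spring = 0.5 * net.mu * float(np.sum(net.h * net.l0 * strain**2))
    return spring - net.P_tur * net.box.area - anisotropic_energy(
        net.box, net.sigma_xx, net.sigma_yy
    )


def energy_and_gradient(
    net: VeinNetwork,
    fx: np.ndarray,
    fy: np.ndarray,
    W: float,
    H: float,
    sigma_xx: float,
    sigma_yy: float,
) -> tuple[float, np.ndarray, np.ndarray, float, float]:
    """Energy and its analytic gradient in fractional coordinates.

    Returns (E, dE/dfx, dE/dfy, dE/dW, dE/dH).  The gradient with
    respect to a fractional coordinate is W (or H) times the physical
    force component.
    """
    a, b = net.rod_a, net.rod_b
    ux = fx[b] - fx[a] + net.rod_sx
    uy = fy[b] - fy[a] + net.rod_sy
    dx = ux * W
    dy = uy * H
    l = np.hypot(dx, dy)
    l = np.maximum(l, 1e-300)
    strain = l / net.l0 - 1.0
    T = net.mu * net.h * strain  # tension

    E = 0.5 * net.mu * float(np.sum(net.h * net.l0 * strain**2))
    E -= net.P_tur * W * H
    dW_ani = 0.0
    dH_ani = 0.0
    if sigma_xx != 0.0 or sigma_yy != 0.0:
        box = net.box
        if not box.has_reference():
            raise ValueError("reference dimensions unset with nonzero external stress")
        E -= box.H0 * (W - box.W0) * sigma_xx + box.W0 * (H - box.H0) * sigma_yy
        dW_ani = -box.H0 * sigma_xx
        dH_ani = -box.W0 * sigma_yy

    # dl/dfx_b = W dx / l ; dl/dfx_a = -W dx / l ; dl/dW = ux dx / l
    gx_rod = T * dx / l * W
    gy_rod = T * dy / l * H
    gfx = np.zeros_like(fx)
    gfy = np.zeros_like(fy)
    np.add.at(gfx, b, gx_rod)
    np.add.at(gfx, a, -gx_rod)
    np.add.at(gfy, b, gy_rod)
    np.add.at(gfy, a, -gy_rod)
    gW = float(np.sum(T * ux * dx / l)) - net.P_tur * H + dW_ani
    gH = float(np.sum(T * uy * dy / l)) - net.P_tur * W + dH_ani
    return E, gfx, gfy, gW, gH


# ---------------------------------------------------------------------------
# equilibration
# ---------------------------------------------------------------------------


def _hessian(net: VeinNetwork, fx, fy, W, H, Wg, Hg, fixed_box: bool):
    """Exact sparse Hessian of the energy in the scaled variables
    (u = fx*Wg, v = fy*Hg, W, H).

    Per rod the energy is e(l) with e'' = mu h / l0 and tension
    T = e'(l); the Hessian is e'' grad-l grad-l^T + T hess-l, assembled
    over the 6 local variables (u_a, u_b, v_a, v_b, W, H).
    """
    import scipy.sparse as sp

    n = net.n_nodes
    a, b = net.rod_a, net.rod_b
    A, B = W / Wg, H / Hg
    px = (fx[b] - fx[a]) * Wg + net.rod_sx * Wg
    py = (fy[b] - fy[a]) * Hg + net.rod_sy * Hg
    dx, dy = A * px, B * py
    l = np.maximum(np.hypot(dx, dy), 1e-300)
    k = net.mu * net.h / net.l0
    T = net.mu * net.h * (l / net.l0 - 1.0)

    nq = 4 if not fixed_box else 2
    # gradient of l wrt q = (px, py[, W, H])
    gl = np.zeros((len(l), nq))
    gl[:, 0] = A * dx / l
    gl[:, 1] = B * dy / l
    if not fixed_box:
        gl[:, 2] = px * dx / (Wg * l)
        gl[:, 3] = py * dy / (Hg * l)
    # hess of l wrt q: (1/l) Jd^T (I - nn^T) Jd + cross terms
    nx, ny = dx / l, dy / l
    Jd = np.zeros((len(l), 2, nq))
    Jd[:, 0, 0] = A
    Jd[:, 1, 1] = B
    if not fixed_box:
        Jd[:, 0, 2] = px / Wg
        Jd[:, 1, 3] = py / Hg
    # P = I - n n^T applied: rows of Jd in the transverse direction
    tx, ty = -ny, nx  # transverse unit vector
    Jt = Jd[:, 0, :] * tx[:, None] + Jd[:, 1, :] * ty[:, None]  # (m, nq)
    Hl = Jt[:, :, None] * Jt[:, None, :] / l[:, None, None]
    if not fixed_box:
        Hl[:, 0, 2] += nx / Wg
        Hl[:, 2, 0] += nx / Wg
        Hl[:, 1, 3] += ny / Hg
        Hl[:, 3, 1] += ny / Hg
    Hq = k[:, None, None] * gl[:, :, None] * gl[:, None, :] + T[:, None, None] * Hl

    # map q -> local variables [u_a, u_b, v_a, v_b, (W, H)] : px = u_b - u_a, ...
    nloc = 6 if not fixed_box else 4
    Mmap = np.zeros((nq, nloc))
    Mmap[0, 0], Mmap[0, 1] = -1.0, 1.0
    Mmap[1, 2], Mmap[1, 3] = -1.0, 1.0
    if not fixed_box:
        Mmap[2, 4] = 1.0
        Mmap[3, 5] = 1.0
    Hloc = np.einsum("qr,mqp,ps->mrs", Mmap, Hq, Mmap)

    ndof = 2 * n + (2 if not fixed_box else 0)
    iW, iH = 2 * n, 2 * n + 1
    idx = np.empty((len(l), nloc), dtype=np.int64)
    idx[:, 0] = a
    idx[:, 1] = b
    idx[:, 2] = n + a
    idx[:, 3] = n + b
    if not fixed_box:
        idx[:, 4] = iW
        idx[:, 5] = iH
    rows = np.repeat(idx[:, :, None], nloc, axis=2).ravel()
    cols = np.repeat(idx[:, None, :], nloc, axis=1).ravel()
    Hmat = sp.coo_matrix((Hloc.ravel(), (rows, cols)), shape=(ndof, ndof)).tocsc()
    if not fixed_box:
        # turgor term -P W H
        Hmat += sp.coo_matrix(
            (np.array([-net.P_tur, -net.P_tur]), ([iW, iH], [iH, iW])),
            shape=(ndof, ndof),
        ).tocsc()
    return Hmat


def _newton_refine(net, fun, z, tol: float, fixed_box: bool, Wg, Hg, max_iter: int = 60):
    """Damped Newton iterations with the exact sparse Hessian.

    Returns the refined variable vector; quadratic convergence once the
    quasi-Newton stage has found the right basin.  The two rigid
    translation modes are regularized away with a tiny diagonal shift.
    """
    import scipy.sparse as sp
    from scipy.sparse.linalg import splu

    n = net.n_nodes
    E, g = fun(z)
    lam = 0.0
    for _ in range(max_iter):
        gnorm = float(np.max(np.abs(g)))
        if gnorm < 1e-2 * tol:
            break
        fx = z[:n] / Wg
        fy = z[n : 2 * n] / Hg
        W = z[2 * n] if not fixed_box else Wg
        H = z[2 * n + 1] if not fixed_box else Hg
        Hmat = _hessian(net, fx, fy, W, H, Wg, Hg, fixed_box)
        diag_scale = float(np.abs(Hmat.diagonal()).max())
        shift = (1e-10 + lam) * diag_scale
        ok_step = False
        for _try in range(8):
            try:
                lu = splu(Hmat + shift * sp.identity(Hmat.shape[0], format="csc"))
                step = lu.solve(-g)
            except RuntimeError:
                shift = max(shift * 10.0, 1e-8 * diag_scale)
                continue
            t = 1.0
            for _bt in range(12):
                E_new, g_new = fun(z + t * step)
                if E_new < E or np.max(np.abs(g_new)) < 0.5 * gnorm:
                    z = z + t * step
                    E, g = E_new, g_new
                    ok_step = True
                    break
                t *= 0.5
            if ok_step:
                lam = lam * 0.25
                break
            shift = max(shift * 10.0, 1e-8 * diag_scale)
            lam = max(lam * 10.0, 1e-8)
        if not ok_step:
            break
    return z


def equilibrate(
    net: VeinNetwork,
    tol: float = 1e-8,
    max_iter: int = 20000,
    *,
    fixed_box: bool = False,
) -> VeinNetwork:
    """Minimize the total energy over node positions and box dimensions.

    The gradient tolerance ``tol`` applies to the physical forces
    (dE/dx in model units) and to dE/dW, dE/dH.  Returns a new network;
    node coordinates are re-wrapped into the box.

    Raises
    ------
    EquilibrationError
        if the residual force exceeds ``tol`` after ``max_iter``
        iterations (the residual is reported).
    """
    net = net.copy()
    n = net.n_nodes
    Wg, Hg = net.box.W, net.box.H
    # variables: u = fx * Wg, v = fy * Hg (length units, box-affine), W, H

    def unpack(z):
        fx = z[:n] / Wg
        fy = z[n : 2 * n] / Hg
        if fixed_box:
            return fx, fy, Wg, Hg
        return fx, fy, z[2 * n], z[2 * n + 1]

    def fun(z):
        fx, fy, W, H = unpack(z)
        E, gfx, gfy, gW, gH = energy_and_gradient(
            net, fx, fy, W, H, net.sigma_xx, net.sigma_yy
        )
        if fixed_box:
            g = np.concatenate([gfx / Wg, gfy / Hg])
        else:
            g = np.concatenate([gfx / Wg, gfy / Hg, [gW, gH]])
        return E, g

    def residual_of(z):
        fx, fy, W, H = unpack(z)
        _, gfx, gfy, gW, gH = energy_and_gradient(
            net, fx, fy, W, H, net.sigma_xx, net.sigma_yy
        )
        r = 0.0
        if n:
            r = max(float(np.max(np.abs(gfx)) / W), float(np.max(np.abs(gfy)) / H))
        if not fixed_box:
            r = max(r, abs(gW), abs(gH))
        return r

    z0 = np.concatenate([net.x, net.y, [] if fixed_box else [Wg, Hg]])
    z = z0
    r0 = residual_of(z)
    if r0 > tol:
        # the damped exact-Hessian Newton solver converges in a few
        # steps from any reasonable state; L-BFGS-B is the fallback
        # for starts far outside its basin
        z = _newton_refine(net, fun, z, tol, fixed_box, Wg, Hg)
        if residual_of(z) > tol:
            bounds = None
            if not fixed_box:
                bounds = [(None, None)] * (2 * n) + [
                    (0.05 * Wg, 20.0 * Wg),
                    (0.05 * Hg, 20.0 * Hg),
                ]
            res = minimize(
                fun,
                z,
                jac=True,
                method="L-BFGS-B",
                bounds=bounds,
                options={
                    "maxiter": min(max_iter, 3000),
                    "maxfun": 4 * min(max_iter, 3000),
                    "ftol": 1e-14,
                    "gtol": 1e-2 * tol,
                },
            )
            z = res.x
            if residual_of(z) > tol:
                z = _newton_refine(net, fun, z, tol, fixed_box, Wg, Hg)
        r = residual_of(z)
        if r > tol:
            raise EquilibrationError(r, tol)
    fx, fy, W, H = unpack(z)
    net.box.W = float(W)
    net.box.H = float(H)
    net.x = np.asarray(fx) * W
    net.y = np.asarray(fy) * H
    net.wrap()
    return net


def compute_reference_dims(net: VeinNetwork, tol: float = 1e-8) -> VeinNetwork:
    """Equilibrate with zero external stress and record (W0, H0).

    Also records ``eta0``, the mean tension per unit thickness of the
    unstressed equilibrium, which normalizes the yield threshold of the
    growth laws.  Returns the equilibrated network (sigma restored).
    """
    sx, sy = net.sigma_xx, net.sigma_yy
    ref = net.copy()
    ref.sigma_xx = 0.0
    ref.sigma_yy = 0.0
    ref = equilibrate(ref, tol=tol)
    ref.box.W0 = ref.box.W
    ref.box.H0 = ref.box.H
    ref.eta0 = measure_eta0(ref)
    ref.sigma_xx = sx
    ref.sigma_yy = sy
    return ref


def measure_eta0(net: VeinNetwork) -> float:
    """Mean T_i/h_i over rods: the reference stress of the growth laws."""
    return float(np.mean(rod_tensions(net) / net.h))


# ---------------------------------------------------------------------------
# growth
# ---------------------------------------------------------------------------


@dataclass
class GrowthLaw:
    """Rest-length evolution rule.

    ``eta_star`` is the yield threshold normalized by the reference
    stress ``eta0`` (the mean T/h at the first step of the simulation);
    the effective threshold is ``eta = eta_star * eta0``.  ``eta0`` may
    be left None, in which case it is measured from the network when the
    simulation starts.
    """

    kind: str = "threshold"
    eta_star: float = 1.0
    eta0: Optional[float] = None

    def __post_init__(self) -> None:
        if self.kind not in GROWTH_LAW_KINDS:
            raise ValueError(f"unknown growth law {self.kind!r}; choose from {GROWTH_LAW_KINDS}")
        if self.eta_star < 0:
            raise ValueError("eta_star must be >= 0")
        if self.kind != "linear" and self.eta_star > 0 and self.eta0 is not None:
            if not self.eta0 > 0:
                raise ValueError("eta0 must be positive")

    @property
    def eta(self) -> float:
        if self.eta0 is None:
            raise ValueError("eta0 is unset; it is measured at the start of a simulation")
        return self.eta_star * self.eta0

    def rates(self, T: np.ndarray, h: np.ndarray, nu: float) -> np.ndarray:
        """Relative growth rates (1/l0) dl0/dt for tensions T, thicknesses h."""
        s = T / h
        if self.kind == "linear":
            return s / nu
        eta = self.eta
        if self.kind == "threshold":
            return np.maximum(0.0, s - eta) / nu
        if eta <= 0:
            raise ValueError(f"{self.kind} law requires a positive threshold eta")
        if self.kind == "quadratic":
            return s**2 / (eta * nu)
        if self.kind == "maximum":
            return s * np.exp(1.0 - s / eta) / nu
        # saturation
        return s / ((1.0 + s / eta) * nu)


def growth_rates(net: VeinNetwork, law: GrowthLaw) -> np.ndarray:
    """Per-rod relative rest-length growth rates at the current state."""
    return law.rates(rod_tensions(net), net.h, net.nu)


def growth_rate(net: VeinNetwork, rod_index: int, law: GrowthLaw) -> float:
    return float(growth_rates(net, law)[rod_index])


def advance_rest_lengths(l0: np.ndarray, rates: np.ndarray, dt: float) -> np.ndarray:
    """One explicit Euler step of dl0/dt = l0 * rate."""
    return l0 * (1.0 + dt * rates)


def grow_step(
    net: VeinNetwork, law: GrowthLaw, dt: float, tol: float = 1e-8
) -> VeinNetwork:
    """Advance rest lengths by one Euler step of ``dt`` and re-equilibrate.

    Thicknesses are frozen (the model grows rest lengths only).  A state
    with zero growth rate on every rod is returned unchanged.
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    rates = growth_rates(net, law)
    if not np.any(rates):
        return net.copy()  # exact plastic fixed point
    out = net.copy()
    out.l0 = advance_rest_lengths(net.l0, rates, dt)
    return equilibrate(out, tol=tol)


@dataclass
class SimulationConfig:
    """Quasi-static growth run settings.

    ``dt`` is the growth time step between energy minimizations;
    the run stops once the box area reaches ``stop_area_ratio`` times
    its initial value.  ``stall_steps`` consecutive steps with relative
    area growth below ``stall_rel`` abort the run (the regime where all
    tensions sit below the yield threshold).
    """

    dt: float = 1e-5
    stop_area_ratio: float = 2.0
    minimizer_tol: float = 1e-8
    snapshot_every: int = 0  # 0: first and last only
    seed: int = 0
    max_steps: int = 2_000_000
    stall_steps: int = 50
    stall_rel: float = 1e-10

    def __post_init__(self) -> None:
        if self.dt <= 0:
            raise ValueError("dt must be positive")
        if self.stop_area_ratio <= 1:
            raise ValueError("stop_area_ratio must exceed 1")


@dataclass
class Trajectory:
    """Stored output of one growth run."""

    times: list[float] = field(default_factory=list)
    snapshots: list[VeinNetwork] = field(default_factory=list)
    snapshot_steps: list[int] = field(default_factory=list)
    diagnostics: list[dict] = field(default_factory=list)
    law: Optional[GrowthLaw] = None
    config: Optional[SimulationConfig] = None
    stalled: bool = False

    @property
    def initial(self) -> VeinNetwork:
        return self.snapshots[0]

    @property
    def final(self) -> VeinNetwork:
        return self.snapshots[-1]

    def diagnostics_table(self):
        import pandas as pd

        return pd.DataFrame(self.diagnostics)


def _diag(step: int, t: float, net: VeinNetwork, law: GrowthLaw) -> dict:
    T = rod_tensions(net)
    rates = law.rates(T, net.h, net.nu)
    return {
        "step": step,
        "time": t,
        "W": net.box.W,
        "H": net.box.H,
        "area": net.box.area,
        "E_total": elastic_energy(net),
        "mean_tension": float(T.mean()),
        "n_growing_rods": int(np.count_nonzero(rates > 0)),
    }


def run_simulation(
    net: VeinNetwork, law: GrowthLaw, config: SimulationConfig
) -> Trajectory:
    """Grow a network quasi-statically until its area has multiplied by
    ``config.stop_area_ratio``.

    The network is first equilibrated (reference dimensions are computed
    if missing, which also fixes ``eta0``).  Each step advances the rest
    lengths by an Euler increment of the growth law and re-minimizes the
    energy.  Snapshots are stored every ``snapshot_every`` steps plus
    the first and last states.

    Raises
    ------
    GrowthStalledError
        if the area stops increasing (threshold too high); the partial
        trajectory is attached to the exception.
    """
    tol = config.minimizer_tol
    if not net.box.has_reference():
        net = compute_reference_dims(net, tol=tol)
    if law.eta0 is None and law.kind != "linear":
        eta0 = net.eta0 if net.eta0 is not None else measure_eta0(net)
        law = dataclasses.replace(law, eta0=eta0)
    net = equilibrate(net, tol=tol)

    traj = Trajectory(law=law, config=config)
    t = 0.0
    area0 = net.box.area
    traj.times.append(t)
    traj.snapshots.append(net)
    traj.snapshot_steps.append(0)
    traj.diagnostics.append(_diag(0, t, net, law))

    target = config.stop_area_ratio * area0
    prev_area = area0
    stall_count = 0
    step = 0
    while net.box.area < target:
        step += 1
        if step > config.max_steps:
            raise GrowthStalledError(
                traj, f"area did not double within {config.max_steps} steps"
            )
        net = grow_step(net, law, config.dt, tol=tol)
        t += config.dt
        traj.diagnostics.append(_diag(step, t, net, law))
        if config.snapshot_every and step % config.snapshot_every == 0:
            traj.times.append(t)
            traj.snapshots.append(net)
            traj.snapshot_steps.append(step)
        if net.box.area <= prev_area * (1.0 + config.stall_rel):
            stall_count += 1
            if stall_count >= config.stall_steps:
                traj.stalled = True
                rates = growth_rates(net, law)
                raise GrowthStalledError(
                    traj,
                    "growth stalled: relative area increase below "
                    f"{config.stall_rel:g} for {config.stall_steps} steps "
                    f"({int(np.count_nonzero(rates > 0))} of {net.n_rods} rods growing)",
                )
        else:
            stall_count = 0
        prev_area = net.box.area
    if traj.snapshot_steps[-1] != step:
        traj.times.append(t)
        traj.snapshots.append(net)
        traj.snapshot_steps.append(step)
    return traj
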