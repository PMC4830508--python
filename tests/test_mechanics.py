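"""Energy, equilibration and growth-law contracts.

Closed-form oracles: for an n x n square lattice of spacing a0 under
turgor P the equilibrium spacing a solves mu h (a/a0 - 1) = P a, so for
mu=300, h=1, P=1, a0=1 the spacing is 300/299.  A rod under clamped
tension T grows as l0(t) = l0(0) exp(T t / (nu h)) under the linear law.
"""

import numpy as np
import pytest

import veinmorph as vm
from veinmorph.mechanics import (
    GrowthLaw,
    SimulationConfig,
    advance_rest_lengths,
    anisotropic_energy,
    elastic_energy,
    energy_and_gradient,
    growth_rates,
)
from veinmorph.network import rod_lengths

from conftest import make_single_rod

LATTICE_A = 300.0 / 299.0  # closed-form equilibrium spacing


# -- energy -----------------------------------------------------------------


def test_single_rod_energy():
    net = make_single_rod(l=1.02, P_tur=0.0)
    assert elastic_energy(net) == pytest.approx(0.5 * 300 * 0.02**2)


def test_energy_at_rest_is_minus_turgor_work(lattice3):
    net = lattice3.copy()
    assert elastic_energy(net) == pytest.approx(-net.P_tur * net.box.area)


def test_anisotropic_energy_cases():
    box = vm.PeriodicBox(1.1, 1.0, W0=1.0, H0=1.0)
    assert anisotropic_energy(box, 1.0, 0.0) == pytest.approx(0.1)
    assert anisotropic_energy(box, 0.0, 0.0) == 0.0
    ref = vm.PeriodicBox(1.0, 1.0, W0=1.0, H0=1.0)
    assert anisotropic_energy(ref, 3.0, 4.0) == 0.0
    # symmetry under swapping the two axes
    bx = vm.PeriodicBox(1.2, 0.9, W0=1.0, H0=0.8)
    by = vm.PeriodicBox(0.9, 1.2, W0=0.8, H0=1.0)
    assert anisotropic_energy(bx, 2.0, 5.0) == pytest.approx(
        anisotropic_energy(by, 5.0, 2.0)
    )


def test_anisotropic_energy_requires_reference():
    with pytest.raises(ValueError, match="unset"):
        anisotropic_energy(vm.PeriodicBox(1.0, 1.0), 1.0, 0.0)


def test_energy_gradient_matches_finite_differences():
    """Analytic gradient vs central differences, including (W, H)."""
    net = vm.generate_reference_network(9, seed=3, geometry_params={"mode": "grid"})
    rng = np.random.default_rng(0)
    net.x += rng.normal(0, 0.3, net.n_nodes)
    net.y += rng.normal(0, 0.3, net.n_nodes)
    net.wrap()
    net.box.W0, net.box.H0 = net.box.W, net.box.H
    net.sigma_xx, net.sigma_yy = 0.7, 0.3
    fx, fy = net.x / net.box.W, net.y / net.box.H
    W, H = net.box.W * 1.01, net.box.H * 0.99

    def energy(fx, fy, W, H):
        return energy_and_gradient(net, fx, fy, W, H, net.sigma_xx, net.sigma_yy)[0]

    E, gfx, gfy, gW, gH = energy_and_gradient(
        net, fx, fy, W, H, net.sigma_xx, net.sigma_yy
    )
    eps = 1e-6
    for i in range(net.n_nodes):
        for arr, grad in ((fx, gfx), (fy, gfy)):
            arr2 = arr.copy()
            arr2[i] += eps
            up = energy(arr2 if arr is fx else fx, arr2 if arr is fy else fy, W, H)
            arr2[i] -= 2 * eps
            dn = energy(arr2 if arr is fx else fx, arr2 if arr is fy else fy, W, H)
            fd = (up - dn) / (2 * eps)
            assert grad[i] == pytest.approx(fd, rel=1e-6, abs=1e-7)
    fdW = (energy(fx, fy, W + eps, H) - energy(fx, fy, W - eps, H)) / (2 * eps)
    fdH = (energy(fx, fy, W, H + eps) - energy(fx, fy, W, H - eps)) / (2 * eps)
    assert gW == pytest.approx(fdW, rel=1e-6)
    assert gH == pytest.approx(fdH, rel=1e-6)


# -- equilibration ----------------------------------------------------------


def test_lattice_equilibrium_matches_closed_form(lattice3):
    eq = vm.equilibrate(lattice3)
    assert eq.box.W / 3 == pytest.approx(LATTICE_A, abs=1e-6)
    assert eq.box.H / 3 == pytest.approx(LATTICE_A, abs=1e-6)
    lengths = rod_lengths(eq)
    np.testing.assert_allclose(lengths, LATTICE_A, atol=1e-6)


def test_equilibrate_descends_energy(small_net):
    before = elastic_energy(small_net)
    eq = vm.equilibrate(small_net)
    assert elastic_energy(eq) <= before + 1e-9


def test_compute_reference_dims_records_box_and_is_idempotent(lattice3):
    ref = vm.compute_reference_dims(lattice3)
    assert ref.box.W0 == pytest.approx(3 * LATTICE_A, abs=1e-6)
    assert ref.box.H0 == pytest.approx(3 * LATTICE_A, abs=1e-6)
    again = vm.compute_reference_dims(ref)
    assert again.box.W0 == pytest.approx(ref.box.W0, abs=1e-7)
    assert again.box.H0 == pytest.approx(ref.box.H0, abs=1e-7)
    # eta0 of the unit lattice: T/h = P a = 300/299
    assert ref.eta0 == pytest.approx(LATTICE_A, abs=1e-6)


def test_stress_elongates_the_pulled_axis(lattice3):
    ref = vm.compute_reference_dims(lattice3)
    ref.sigma_yy = 0.5
    eq = vm.equilibrate(ref)
    assert eq.box.H / eq.box.H0 > eq.box.W / eq.box.W0


def test_transpose_symmetry_of_equilibria():
    """Reflecting the network across the diagonal and swapping the
    stress components yields the reflected equilibrium."""
    net = vm.generate_reference_network(20, seed=5)
    net = vm.compute_reference_dims(net)
    net.sigma_xx, net.sigma_yy = 0.0, 1.0
    eq = vm.equilibrate(net)

    t = net.copy()
    t.x, t.y = net.y.copy(), net.x.copy()
    t.box.W, t.box.H = net.box.H, net.box.W
    t.box.W0, t.box.H0 = net.box.H0, net.box.W0
    t.rod_sx, t.rod_sy = net.rod_sy.copy(), net.rod_sx.copy()
    t.sigma_xx, t.sigma_yy = net.sigma_yy, net.sigma_xx
    eq_t = vm.equilibrate(t)
    assert elastic_energy(eq_t) == pytest.approx(elastic_energy(eq), rel=1e-9)
    assert eq_t.box.H == pytest.approx(eq.box.W, rel=1e-7)
    assert eq_t.box.W == pytest.approx(eq.box.H, rel=1e-7)


# -- growth laws ------------------------------------------------------------


def test_growth_law_values():
    law = GrowthLaw("threshold", eta_star=1.0, eta0=6.0)
    assert law.rates(np.array([6.0]), np.array([1.0]), 1.0)[0] == 0.0
    assert law.rates(np.array([8.0]), np.array([1.0]), 1.0)[0] == pytest.approx(2.0)
    lin = GrowthLaw("linear")
    assert lin.rates(np.array([6.0]), np.array([2.0]), 1.0)[0] == pytest.approx(3.0)


def test_growth_law_kinds_and_validation():
    with pytest.raises(ValueError, match="unknown growth law"):
        GrowthLaw("cubic")
    with pytest.raises(ValueError, match="eta_star"):
        GrowthLaw("threshold", eta_star=-1.0)
    for kind in ("quadratic", "maximum", "saturation"):
        law = GrowthLaw(kind, eta_star=1.0, eta0=6.0)
        r = law.rates(np.array([6.0]), np.array([1.0]), 1.0)[0]
        assert r > 0
    # at s = eta the three surrogates coincide with s/nu up to shape factors
    assert GrowthLaw("quadratic", 1.0, eta0=6.0).rates(
        np.array([6.0]), np.array([1.0]), 1.0
    )[0] == pytest.approx(6.0)


def test_growth_rate_on_network():
    net = make_single_rod(l=1.02)  # T = 6
    law = GrowthLaw("threshold", eta_star=0.5, eta0=6.0)  # eta = 3
    assert vm.growth_rate(net, 0, law) == pytest.approx(3.0)


def test_clamped_tension_exponential_growth():
    """Linear-law integration under constant tension reproduces
    l0(t) = l0(0) exp(T t / (nu h)) to O(dt)."""
    T, h, nu, t_end = 4.0, 2.0, 1.0, 0.5
    law = GrowthLaw("linear")
    for dt, tol in ((1e-3, 2e-3), (1e-4, 2e-4)):
        l0 = np.array([1.0])
        n = round(t_end / dt)
        for _ in range(n):
            rates = law.rates(np.array([T]), np.array([h]), nu)
            l0 = advance_rest_lengths(l0, rates, dt)
        exact = np.exp(T * t_end / (nu * h))
        assert abs(l0[0] - exact) / exact < tol


def test_grow_step_euler_increment(equilibrated_small):
    net = equilibrated_small
    law = GrowthLaw("linear")
    dt = 1e-5
    rates = growth_rates(net, law)
    stepped = vm.grow_step(net, law, dt)
    np.testing.assert_allclose(stepped.l0, net.l0 * (1 + dt * rates), rtol=1e-12)


def test_grow_step_rejects_bad_dt(equilibrated_small):
    with pytest.raises(ValueError):
        vm.grow_step(equilibrated_small, GrowthLaw("linear"), -1e-5)


def test_threshold_above_all_tensions_is_bitwise_fixed_point(equilibrated_small):
    net = equilibrated_small
    eta0 = vm.measure_eta0(net)
    law = GrowthLaw("threshold", eta_star=10.0, eta0=eta0)
    stepped = vm.grow_step(net, law, 1e-4)
    assert np.array_equal(stepped.l0, net.l0)
    assert np.array_equal(stepped.x, net.x)
    assert stepped.box.W == net.box.W


def test_two_half_steps_vs_full_step_is_second_order(equilibrated_small):
    """Richardson check: halving dt shrinks the step-splitting error
    by about 4 (explicit Euler is first-order accurate)."""
    net = equilibrated_small
    law = GrowthLaw("linear")

    def split_error(dt):
        full = vm.grow_step(net, law, dt)
        half = vm.grow_step(vm.grow_step(net, law, dt / 2), law, dt / 2)
        return np.max(np.abs(full.l0 - half.l0))

    e1 = split_error(4e-3)
    e2 = split_error(2e-3)
    assert e1 > 0
    assert 2.5 < e1 / e2 < 6.0


# -- simulation loop --------------------------------------------------------


def test_run_simulation_stops_at_area_doubling():
    net = vm.generate_reference_network(12, seed=7)
    net = vm.optimize_thickness(net)
    net = vm.compute_reference_dims(net)
    traj = vm.run_simulation(
        net, GrowthLaw("linear"), SimulationConfig(dt=1e-3, stop_area_ratio=2.0)
    )
    a0 = traj.diagnostics[0]["area"]
    a1 = traj.diagnostics[-1]["area"]
    a_prev = traj.diagnostics[-2]["area"]
    assert a1 >= 2 * a0
    assert a_prev < 2 * a0  # stopped as soon as the target was crossed
    assert traj.times[0] == 0.0
    assert traj.diagnostics[0]["E_total"] == pytest.approx(
        elastic_energy(traj.initial)
    )


def test_high_threshold_stalls_with_diagnostic():
    net = vm.generate_reference_network(12, seed=7)
    net = vm.optimize_thickness(net)
    net = vm.apply_thickness_noise(net, 0.4, seed=1)
    net = vm.compute_reference_dims(net)
    with pytest.raises(vm.GrowthStalledError, match="stalled"):
        vm.run_simulation(
            net,
            GrowthLaw("threshold", eta_star=3.0),
            SimulationConfig(dt=1e-3, stall_steps=10),
        )


def test_simulation_config_validation():
    with pytest.raises(ValueError):
        SimulationConfig(dt=-1.0)
    with pytest.raises(ValueError):
        SimulationConfig(stop_area_ratio=0.5)
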