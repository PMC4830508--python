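"""Texture tensors, Gaussian averaging and non-affinity indices."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import veinmorph as vm
from veinmorph.texture import (
    Areole,
    AreoleGraph,
    SMOOTHING_AREA_FACTOR,
    areal_non_affinity_index,
    averaged_texture_tensor,
    extract_areoles,
    local_texture_tensor,
    non_affinity_index,
    smoothing_width,
    tensor_field,
    vein_orientation_histogram,
    summarize_realizations,
)


def graph_from_points(points, adjacency, areas=None, W=1000.0, H=1000.0):
    """Hand-built areole graph (all interior)."""
    n = len(points)
    areas = areas if areas is not None else np.ones(n)
    areoles = [
        Areole(i, [], [], tuple(points[i]), float(areas[i])) for i in range(n)
    ]
    return AreoleGraph(areoles, {i: sorted(adjacency[i]) for i in range(n)},
                       periodic=False, W=W, H=H)


def star_graph(offsets):
    """Areole 0 at origin with neighbors at the given offsets."""
    pts = np.vstack([[0.0, 0.0], offsets])
    adj = {0: list(range(1, len(pts)))}
    for i in range(1, len(pts)):
        adj[i] = [0]
    return graph_from_points(pts, adj)


# -- local tensor -----------------------------------------------------------


def test_local_tensor_symmetric_cross():
    g = star_graph([(1, 0), (-1, 0), (0, 1), (0, -1)])
    t = local_texture_tensor(g, 0)
    np.testing.assert_allclose(t.M, [[0.5, 0], [0, 0.5]], atol=1e-15)
    assert t.anisotropy == pytest.approx(1.0)
    assert t.det == pytest.approx(0.25)


def test_local_tensor_two_neighbors():
    g = star_graph([(1, 0), (0, 2)])
    t = local_texture_tensor(g, 0)
    np.testing.assert_allclose(t.M, [[0.5, 0], [0, 2.0]], atol=1e-15)
    assert t.anisotropy == pytest.approx(4.0)
    assert t.orientation_deg == pytest.approx(90.0)


def test_local_tensor_uses_minimum_image(lattice3):
    g = extract_areoles(lattice3)
    for i in range(g.n_areoles):
        t = local_texture_tensor(g, i)
        np.testing.assert_allclose(t.M, [[0.5, 0], [0, 0.5]], atol=1e-12)


@settings(derandomize=True, max_examples=25)
@given(
    seed=st.integers(0, 10**6),
    a11=st.floats(0.5, 2.0),
    a12=st.floats(-0.8, 0.8),
    a21=st.floats(-0.8, 0.8),
    a22=st.floats(0.5, 2.0),
)
def test_affine_covariance(seed, a11, a12, a21, a22):
    """Any linear map A of the coordinates maps M to A M A^T exactly."""
    rng = np.random.default_rng(seed)
    pts = rng.uniform(-3, 3, (7, 2))
    adj = {0: list(range(1, 7))}
    for i in range(1, 7):
        adj[i] = [0]
    g = graph_from_points(pts, adj)
    A = np.array([[a11, a12], [a21, a22]])
    g2 = graph_from_points(pts @ A.T, adj)
    M1 = local_texture_tensor(g, 0).M
    M2 = local_texture_tensor(g2, 0).M
    np.testing.assert_allclose(M2, A @ M1 @ A.T, atol=1e-10)


def test_orientation_equivariance():
    base = np.array([(1.0, 0.0), (0.0, 2.0)])
    for theta in (10.0, 77.0, 130.0):
        c, s = np.cos(np.radians(theta)), np.sin(np.radians(theta))
        R = np.array([[c, -s], [s, c]])
        g = star_graph(base @ R.T)
        ori = local_texture_tensor(g, 0).orientation_deg
        assert ori == pytest.approx((90.0 + theta) % 180.0, abs=1e-8)


def test_degenerate_tensor_flags_infinite_anisotropy():
    g = star_graph([(1, 0), (-1, 0), (2, 0)])  # collinear neighbors
    t = local_texture_tensor(g, 0)
    assert np.isinf(t.anisotropy)
    assert t.orientation_deg == pytest.approx(0.0)  # rank-1: along x


# -- smoothing --------------------------------------------------------------


def test_smoothing_width_inversion():
    g = graph_from_points([(0, 0)], {0: []}, areas=[np.pi / SMOOTHING_AREA_FACTOR])
    assert smoothing_width(g) == pytest.approx(1.0)


def test_smoothing_width_lattice(lattice3):
    g = extract_areoles(lattice3)
    assert smoothing_width(g) == pytest.approx(np.sqrt(30 / np.pi))


def test_smoothing_width_scales_linearly(small_net):
    g1 = extract_areoles(small_net)
    scaled = small_net.copy()
    k = 2.5
    scaled.x *= k
    scaled.y *= k
    scaled.l0 *= k
    scaled.box.W *= k
    scaled.box.H *= k
    g2 = extract_areoles(scaled)
    assert smoothing_width(g2) == pytest.approx(k * smoothing_width(g1), rel=1e-9)


def test_averaged_tensor_of_constant_field_is_constant(lattice3):
    g = extract_areoles(lattice3)
    for sigma in (0.5, 3.0, 50.0):
        t = averaged_texture_tensor(g, (1.7, 0.4), sigma)
        np.testing.assert_allclose(t.M, [[0.5, 0], [0, 0.5]], atol=1e-12)


def test_averaged_tensor_delta_limit():
    g = graph_from_points(
        [(0, 0), (4, 0)], {0: [1], 1: [0]}
    )
    t = averaged_texture_tensor(g, (0, 0), sigma=0.05)
    np.testing.assert_allclose(t.M, local_texture_tensor(g, 0).M, rtol=1e-12)


def test_averaged_tensor_equidistant_point_is_arithmetic_mean():
    pts = [(0.0, 0.0), (2.0, 0.0), (1.0, 5.0)]
    adj = {0: [1, 2], 1: [0, 2], 2: [0, 1]}
    g = graph_from_points(pts, adj)
    M0 = local_texture_tensor(g, 0).M
    M1 = local_texture_tensor(g, 1).M
    M2 = local_texture_tensor(g, 2).M
    t = averaged_texture_tensor(g, (1.0, 0.0), sigma=1.3)
    w2 = np.exp(-25.0 / (2 * 1.3**2))  # areole 2 sits at distance 5
    w01 = np.exp(-1.0 / (2 * 1.3**2))  # areoles 0 and 1 both at distance 1
    expect = (w01 * (M0 + M1) + w2 * M2) / (2 * w01 + w2)
    np.testing.assert_allclose(t.M, expect, rtol=1e-12)


# -- descriptor fields ------------------------------------------------------


def test_tensor_field_isotropic_lattice(lattice3):
    df = tensor_field(extract_areoles(lattice3))
    assert np.allclose(df.anisotropy, 1.0, atol=1e-9)
    assert not df.orientation_reliable.any()


def test_tensor_field_normalization(small_net):
    df = tensor_field(extract_areoles(small_net), normalize=True)
    assert df.det_avg.mean() == pytest.approx(1.0)


def test_anisotropy_at_least_one(small_net):
    df = tensor_field(extract_areoles(small_net))
    fin = df.anisotropy[np.isfinite(df.anisotropy)]
    assert (fin >= 1.0 - 1e-12).all()
    fin_local = df.anisotropy_local[np.isfinite(df.anisotropy_local)]
    assert (fin_local >= 1.0 - 1e-12).all()


def test_boundary_areoles_excluded_on_open_domains():
    """A single open square: its only areole touches the outer face, so
    its texture tensor is undefined."""
    net = vm.VeinNetwork(
        vm.PeriodicBox(2, 2),
        [0.5, 1.5, 1.5, 0.5],
        [0.5, 0.5, 1.5, 1.5],
        [0, 1, 2, 3],
        [1, 2, 3, 0],
        [0] * 4, [0] * 4, [1.0] * 4, [1.0] * 4,
        periodic=False,
    )
    g = extract_areoles(net)
    assert g.n_areoles == 1
    assert g.areoles[0].boundary_flag
    assert g.areoles[0].area == pytest.approx(1.0)
    with pytest.raises(ValueError, match="undefined"):
        local_texture_tensor(g, 0)


# -- non-affinity -----------------------------------------------------------


def dilate(net, k):
    out = net.copy()
    out.x *= k
    out.y *= k
    out.l0 *= k
    out.box.W *= k
    out.box.H *= k
    return out


def test_q_equals_one_under_isotropic_dilation(small_net):
    g1 = extract_areoles(small_net)
    g2 = extract_areoles(dilate(small_net, 2.7))
    q = non_affinity_index(g1, g2)["q"]
    np.testing.assert_allclose(q, 1.0, atol=1e-9)


def test_q_equals_one_for_identical_graphs(small_net):
    g = extract_areoles(small_net)
    q = non_affinity_index(g, g)["q"]
    np.testing.assert_allclose(q, 1.0, atol=1e-12)


def test_q_matches_brute_force_oracle():
    """Five-areole configuration, one areole's neighbors pushed 10%
    outward; the package must match a direct evaluation of the
    determinant-ratio formula with explicit Gaussian sums."""
    pts1 = np.array([(0.0, 0.0), (2.0, 0.3), (-1.9, 0.4), (0.2, 2.1), (-0.1, -2.2)])
    adj = {0: [1, 2, 3, 4], 1: [0, 3], 2: [0, 4], 3: [0, 1], 4: [0, 2]}
    pts2 = pts1.copy()
    pts2[1:] = pts1[1:] * 1.1  # neighbors of areole 0 move radially outward
    areas1 = np.array([1.0, 1.2, 0.9, 1.1, 1.0])
    g1 = graph_from_points(pts1, adj, areas1)
    g2 = graph_from_points(pts2, adj, areas1 * 1.15)
    got = non_affinity_index(g1, g2)["q"].to_numpy()

    def brute(points, adjacency, areas):
        n = len(points)
        M = [
            sum(
                np.outer(points[k] - points[i], points[k] - points[i])
                for k in adjacency[i]
            )
            / len(adjacency[i])
            for i in range(n)
        ]
        sig = np.sqrt(30.0 * np.mean(areas) / np.pi)
        Mbar = []
        for i in range(n):
            num = np.zeros((2, 2))
            den = 0.0
            for j in range(n):
                w = np.exp(-np.sum((points[i] - points[j]) ** 2) / (2 * sig**2))
                num += w * M[j]
                den += w
            Mbar.append(num / den)
        return np.array([np.linalg.det(M[i]) / np.linalg.det(Mbar[i]) for i in range(n)])

    r1 = brute(pts1, adj, areas1)
    r2 = brute(pts2, adj, areas1 * 1.15)
    np.testing.assert_allclose(got, r2 / r1, atol=1e-12)


def test_q_rejects_mismatched_graphs(small_net, lattice3):
    g1 = extract_areoles(small_net)
    g2 = extract_areoles(lattice3)
    with pytest.raises(ValueError, match="differ"):
        non_affinity_index(g1, g2)


def test_areal_index_uniform_dilation(small_net):
    g1 = extract_areoles(small_net)
    g2 = extract_areoles(dilate(small_net, 1.8))
    df = areal_non_affinity_index(g1, g2, 0.0, 2.0)
    np.testing.assert_allclose(df["a"], np.log(1.8**2) / 2.0, rtol=1e-9)
    np.testing.assert_allclose(df["a_ratio"], 1.0, atol=1e-9)


def test_areal_index_zero_growth_is_undefined(small_net):
    g = extract_areoles(small_net)
    df = areal_non_affinity_index(g, g, 0.0, 1.0)
    assert df["a_ratio"].isna().all()
    with pytest.raises(ValueError, match="t2"):
        areal_non_affinity_index(g, g, 1.0, 1.0)


def test_areal_index_matches_direct_formula(small_net):
    g1 = extract_areoles(small_net)
    pert = small_net.copy()
    rng = np.random.default_rng(8)
    pert.x += rng.normal(0, 0.05, pert.n_nodes)
    pert.y += rng.normal(0, 0.05, pert.n_nodes)
    pert.wrap()
    g2 = extract_areoles(pert)
    df = areal_non_affinity_index(g1, g2, 0.0, 2.0)
    a = np.log(g2.areas / g1.areas) / 2.0
    sig = smoothing_width(g1)
    c = g1.centroids
    for i in (0, 5, 11):
        d = c - c[i]
        box = np.array([g1.W, g1.H])
        d = d - np.round(d / box) * box
        w = np.exp(-np.sum(d**2, axis=1) / (2 * sig**2))
        abar = np.sum(w * a) / w.sum()
        assert df["a_ratio"][i] == pytest.approx(a[i] / abar, rel=1e-9)


# -- orientation histograms & summaries -------------------------------------


def test_orientation_histogram_horizontal_rods():
    net = vm.VeinNetwork(
        vm.PeriodicBox(10, 10),
        [0, 1, 2, 3], [0, 0, 0, 0],
        [0, 1, 2], [1, 2, 3], [0] * 3, [0] * 3, [1] * 3, [1] * 3,
        periodic=False,
    )
    df = vein_orientation_histogram(net)
    assert df["count"].sum() == 3
    assert df["count"][0] == 3  # all mass in the [0, 10) degree bin


def test_orientation_histogram_square_lattice(lattice3):
    df = vein_orientation_histogram(lattice3)
    nonzero = df[df["count"] > 0]
    assert set(nonzero["bin_left"]) == {0.0, 90.0}
    assert nonzero["count"].tolist() == [9, 9]


def test_orientation_histogram_length_weighted(lattice3):
    df = vein_orientation_histogram(lattice3, weights="length")
    assert df["frequency"].sum() == pytest.approx(1.0)
    with pytest.raises(ValueError, match="weights"):
        vein_orientation_histogram(lattice3, weights="area")


def test_summarize_duplicated_runs_have_zero_spread():
    net = vm.generate_reference_network(12, seed=3)
    net = vm.optimize_thickness(net)
    net = vm.compute_reference_dims(net)
    traj = vm.run_simulation(
        net, vm.GrowthLaw("linear"), vm.SimulationConfig(dt=1e-3)
    )
    tables = summarize_realizations({"c": [traj, traj, traj]})
    assert tables["anisotropy"]["anisotropy_sd"][0] == pytest.approx(0.0, abs=1e-12)
    assert tables["q_stats"]["n_areoles"][0] == 3 * 12
    assert not tables["q_by_thickness"].empty


def test_summarize_rejects_mixed_pools():
    net = vm.generate_reference_network(12, seed=3)
    net = vm.optimize_thickness(net)
    net = vm.compute_reference_dims(net)
    t1 = vm.run_simulation(net, vm.GrowthLaw("linear"), vm.SimulationConfig(dt=1e-3))
    stressed = net.copy()
    stressed.sigma_yy = 1.0
    t2 = vm.run_simulation(
        stressed, vm.GrowthLaw("linear"), vm.SimulationConfig(dt=1e-3)
    )
    with pytest.raises(ValueError, match="mixed"):
        summarize_realizations({"c": [t1, t2]})
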