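import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.integrate import quad
from scipy.spatial.transform import Rotation

from shearmetrics.mesh import RegionMask, SurfaceMesh
from shearmetrics.metrics import (MetricMap, WSSField, area_fraction,
                                  compute_osi, compute_rrt, compute_tawss,
                                  field_from_csv, field_to_csv,
                                  regional_mean, tawss_histogram)
from shearmetrics.synthetic import planted_osi
from conftest import single_node_field


# ---------------------------------------------------------------------------
# independent oracle: adaptive quadrature on the periodic piecewise-linear
# reconstruction of the sampled field (the sampled data fully define the
# metrics; this integrates the same reconstruction by a different route)

def brute_force_metrics(times, tau, period):
    """Per-node TAWSS/OSI/RRT via scipy adaptive quadrature."""
    t = np.concatenate([times, [period]])
    n = tau.shape[0]
    out = {"TAWSS": np.zeros(n), "OSI": np.zeros(n), "RRT": np.zeros(n)}
    for i in range(n):
        comp = np.concatenate([tau[i], tau[i][:1]], axis=0)  # closure
        vec = np.array([
            quad(lambda s, c=c: np.interp(s, t, comp[:, c]), 0, period,
                 points=t, limit=400)[0] for c in range(3)])
        mags = np.linalg.norm(comp, axis=1)
        mag_int = quad(lambda s: np.interp(s, t, mags), 0, period,
                       points=t, limit=400)[0]
        tawss = mag_int / period
        osi = 0.5 * (1 - np.linalg.norm(vec) / mag_int) if mag_int > 0 else 0.0
        out["TAWSS"][i] = tawss
        out["OSI"][i] = osi
        denom = (1 - 2 * osi) * tawss
        out["RRT"][i] = 1.0 / denom if denom > 0 else np.inf
    return out


def random_field(n_nodes=6, n_times=12, seed=0, period=0.2):
    rng = np.random.default_rng(seed)
    verts = rng.uniform(size=(n_nodes + 2, 3))
    tris = [[i, i + 1, i + 2] for i in range(n_nodes)]
    mesh = SurfaceMesh(verts, tris)
    times = np.arange(n_times) * period / n_times
    tau = rng.normal(scale=2.0, size=(mesh.n_nodes, n_times, 3))
    return WSSField(mesh, times, tau, period)


# ---------------------------------------------------------------------------
# TAWSS

def test_tawss_constant_vector():
    sig = np.tile([5.0, 0.0, 0.0], (10, 1))
    m = compute_tawss(single_node_field(sig, 0.2))
    np.testing.assert_allclose(m.values, 5.0, rtol=1e-12)


def test_tawss_rectified_sinusoid():
    # mean of |sin| over a full cycle is 2/pi of the amplitude
    t = np.arange(2000) * 0.2 / 2000
    sig = np.zeros((2000, 3))
    sig[:, 0] = 3.0 * np.sin(2 * np.pi * t / 0.2)
    m = compute_tawss(single_node_field(sig, 0.2))
    np.testing.assert_allclose(m.values, 3.0 * 2 / np.pi, rtol=1e-5)


def test_tawss_zero_field_flagged():
    m = compute_tawss(single_node_field(np.zeros((8, 3)), 0.2))
    assert np.all(m.values == 0.0) and np.all(m.flags)


def test_field_needs_three_samples():
    with pytest.raises(ValueError, match="3 time samples"):
        single_node_field(np.ones((2, 3)), 0.2)


# ---------------------------------------------------------------------------
# OSI

def test_osi_constant_direction_is_zero():
    t = np.arange(50) * 0.2 / 50
    sig = np.zeros((50, 3))
    sig[:, 0] = 4.0 + 2.0 * np.cos(2 * np.pi * t / 0.2)  # never reverses
    m = compute_osi(single_node_field(sig, 0.2))
    np.testing.assert_allclose(m.values, 0.0, atol=1e-14)


def test_osi_full_reversal_is_half():
    t = np.arange(100) * 0.2 / 100
    sig = np.zeros((100, 3))
    sig[:, 0] = np.sin(2 * np.pi * t / 0.2)
    m = compute_osi(single_node_field(sig, 0.2))
    np.testing.assert_allclose(m.values, 0.5, atol=1e-12)


def test_osi_offset_sinusoid_matches_quadrature_oracle():
    t = np.arange(100) * 0.2 / 100
    sig = np.zeros((100, 3))
    sig[:, 0] = 1.0 + np.sin(2 * np.pi * t / 0.2)
    field = single_node_field(sig, 0.2)
    osi = compute_osi(field).values[0]
    oracle = brute_force_metrics(field.times, field.tau[:1], 0.2)["OSI"][0]
    assert osi == pytest.approx(oracle, abs=1e-6)


def test_osi_zero_field_degenerate_convention():
    m = compute_osi(single_node_field(np.zeros((8, 3)), 0.2))
    assert np.all(m.values == 0.0) and np.all(m.flags)


def test_metrics_match_brute_force_on_random_fields():
    """TAWSS/OSI/RRT on small random fields agree with the adaptive-
    quadrature oracle to 1e-6 relative."""
    field = random_field(n_nodes=8, n_times=16, seed=3)
    ref = brute_force_metrics(field.times, field.tau, field.period)
    tawss, osi = compute_tawss(field), compute_osi(field)
    rrt = compute_rrt(tawss, osi)
    np.testing.assert_allclose(tawss.values, ref["TAWSS"], rtol=1e-6)
    np.testing.assert_allclose(osi.values, ref["OSI"], rtol=1e-6, atol=1e-9)
    np.testing.assert_allclose(rrt.values, ref["RRT"], rtol=1e-6)


@settings(deadline=None, derandomize=True, max_examples=25)
@given(st.floats(0.01, 1000), st.integers(0, 2**31 - 1))
def test_osi_invariant_to_positive_scaling(scale, seed):
    field = random_field(seed=seed)
    base = compute_osi(field).values
    scaled = WSSField(field.mesh, field.times, field.tau * scale,
                      field.period)
    np.testing.assert_allclose(compute_osi(scaled).values, base,
                               rtol=1e-10, atol=1e-12)


def test_tawss_and_osi_invariant_under_rotation():
    field = random_field(seed=7)
    rot = Rotation.from_euler("xyz", [0.3, -1.1, 2.0]).as_matrix()
    rotated = WSSField(field.mesh, field.times,
                       field.tau @ rot.T, field.period)
    np.testing.assert_allclose(compute_tawss(rotated).values,
                               compute_tawss(field).values, rtol=1e-12)
    np.testing.assert_allclose(compute_osi(rotated).values,
                               compute_osi(field).values,
                               rtol=1e-10, atol=1e-14)


def test_osi_refinement_consistency():
    """Halving the time step shrinks the OSI discretisation error by ~4x
    (second order) on a reversing offset sinusoid."""
    a, b, T = 1.0, 2.5, 0.2
    exact = planted_osi(a, b)
    errs = []
    for n in (50, 100, 200, 400):
        t = np.arange(n) * T / n
        sig = np.zeros((n, 3))
        sig[:, 0] = a + b * np.sin(2 * np.pi * t / T)
        osi = compute_osi(single_node_field(sig, T)).values[0]
        errs.append(abs(osi - exact))
    assert errs[3] < errs[0] / 16  # aggregate second-order decay
    assert all(e2 < e1 for e1, e2 in zip(errs, errs[1:]))


# ---------------------------------------------------------------------------
# RRT

def test_rrt_formula_and_identity():
    mesh = SurfaceMesh([[0, 0, 0], [1, 0, 0], [0, 1, 0]], [[0, 1, 2]])
    tawss = MetricMap(mesh, "TAWSS", [2.0, 5.0, 1.0])
    osi = MetricMap(mesh, "OSI", [0.0, 0.25, 0.4])
    rrt = compute_rrt(tawss, osi)
    assert rrt.values[0] == pytest.approx(0.5)
    ident = rrt.values * (1 - 2 * osi.values) * tawss.values
    np.testing.assert_allclose(ident, 1.0, atol=1e-12)


def test_rrt_infinite_sentinel_at_half_osi():
    mesh = SurfaceMesh([[0, 0, 0], [1, 0, 0], [0, 1, 0]], [[0, 1, 2]])
    rrt = compute_rrt(MetricMap(mesh, "TAWSS", [2.0, 2.0, 2.0]),
                      MetricMap(mesh, "OSI", [0.5, 0.2, 0.0]))
    assert np.isinf(rrt.values[0]) and rrt.flags[0]
    assert np.isfinite(rrt.values[1:]).all()


def test_rrt_mismatched_meshes_rejected():
    m1 = SurfaceMesh([[0, 0, 0], [1, 0, 0], [0, 1, 0]], [[0, 1, 2]])
    m2 = SurfaceMesh([[0, 0, 0], [2, 0, 0], [0, 2, 0]], [[0, 1, 2]])
    with pytest.raises(ValueError, match="share a mesh"):
        compute_rrt(MetricMap(m1, "TAWSS", np.ones(3)),
                    MetricMap(m2, "OSI", np.zeros(3)))


# ---------------------------------------------------------------------------
# area statistics

def square_mesh_map(values):
    """4-node unit square (2 triangles); diagonal nodes carry more area."""
    mesh = SurfaceMesh([[0, 0, 0], [1, 0, 0], [1, 1, 0], [0, 1, 0]],
                       [[0, 1, 2], [0, 2, 3]])
    return mesh, MetricMap(mesh, "TAWSS", values)


def test_area_fraction_uniform_below():
    mesh, m = square_mesh_map([10.0] * 4)
    assert area_fraction(m, mesh.whole_wall_mask(), 20.0, "below") == 1.0
    assert area_fraction(m, mesh.whole_wall_mask(), 20.0, "above") == 0.0


def test_area_fraction_half_area_split():
    # node 0 (diagonal, 1/3) plus node 1 (corner, 1/6) carry half the area
    mesh, m = square_mesh_map([30.0, 30.0, 5.0, 5.0])
    frac = area_fraction(m, mesh.whole_wall_mask(), 20.0, "above")
    assert frac == pytest.approx(0.5, abs=1e-12)


def test_area_fraction_threshold_below_minimum():
    mesh, m = square_mesh_map([10.0, 12.0, 14.0, 16.0])
    assert area_fraction(m, mesh.whole_wall_mask(), 5.0, "below") == 0.0


def test_area_fraction_ties_do_not_qualify():
    mesh, m = square_mesh_map([20.0] * 4)
    whole = mesh.whole_wall_mask()
    assert area_fraction(m, whole, 20.0, "above") == 0.0
    assert area_fraction(m, whole, 20.0, "below") == 0.0


def test_area_fraction_infinite_counts_as_above():
    mesh = SurfaceMesh([[0, 0, 0], [1, 0, 0], [0, 1, 0]], [[0, 1, 2]])
    rrt = MetricMap(mesh, "RRT", [np.inf, 0.1, 0.1])
    frac = area_fraction(rrt, mesh.whole_wall_mask(), 0.5, "above")
    assert frac == pytest.approx(1 / 3)


def test_area_fraction_complementarity():
    field = random_field(seed=11)
    m = compute_tawss(field)
    whole = field.mesh.whole_wall_mask()
    thr = float(np.median(m.values)) + 0.01  # avoid exact ties
    above = area_fraction(m, whole, thr, "above")
    below = area_fraction(m, whole, thr, "below")
    assert above + below == pytest.approx(1.0, abs=1e-12)


def test_tawss_histogram_uniform_low_and_overflow():
    mesh, m = square_mesh_map([10.0] * 4)
    h = tawss_histogram(m, mesh.whole_wall_mask())
    np.testing.assert_allclose(h, [1, 0, 0, 0, 0, 0, 0])
    _, m2 = square_mesh_map([130.0] * 4)
    h2 = tawss_histogram(m2, mesh.whole_wall_mask())
    np.testing.assert_allclose(h2, [0, 0, 0, 0, 0, 0, 1])


def test_tawss_histogram_planted_mixture_and_normalisation():
    mesh, m = square_mesh_map([10.0, 50.0, 10.0, 125.0])
    h = tawss_histogram(m, mesh.whole_wall_mask())
    assert h.sum() == pytest.approx(1.0, abs=1e-12)
    # diagonal nodes (10 Pa) carry 1/3 each; corners (50, 125 Pa) 1/6 each
    np.testing.assert_allclose(h, [2 / 3, 0, 1 / 6, 0, 0, 0, 1 / 6])


def test_tawss_histogram_requires_tawss_map():
    mesh, _ = square_mesh_map([1.0] * 4)
    osi = MetricMap(mesh, "OSI", [0.1] * 4)
    with pytest.raises(ValueError, match="TAWSS"):
        tawss_histogram(osi, mesh.whole_wall_mask())


def test_regional_mean_uniform_and_two_node():
    mesh, m = square_mesh_map([0.0, 0.3, 0.0, 0.5])
    assert regional_mean(MetricMap(mesh, "OSI", [0.4] * 4),
                         mesh.whole_wall_mask()) == pytest.approx(0.4)
    # corner nodes 1 and 3 have equal lumped areas, values 0.3 / 0.5
    two = RegionMask("pair", [1, 3])
    assert regional_mean(m, two) == pytest.approx(0.4)


def test_regional_mean_weighted_oracle():
    field = random_field(seed=5)
    m = compute_tawss(field)
    whole = field.mesh.whole_wall_mask()
    a = field.mesh.node_areas
    expected = float((m.values * a).sum() / a.sum())
    assert regional_mean(m, whole) == pytest.approx(expected, rel=1e-12)


def test_regional_mean_all_degenerate_errors():
    mesh = SurfaceMesh([[0, 0, 0], [1, 0, 0], [0, 1, 0]], [[0, 1, 2]])
    m = MetricMap(mesh, "RRT", [np.inf] * 3)
    with pytest.raises(ValueError, match="degenerate"):
        regional_mean(m, mesh.whole_wall_mask())


# ---------------------------------------------------------------------------
# field I/O

def test_field_csv_roundtrip(tmp_path):
    field = random_field(seed=2)
    path = tmp_path / "field.csv"
    field_to_csv(field, path)
    back = field_from_csv(field.mesh, path, field.period)
    np.testing.assert_allclose(back.tau, field.tau, rtol=1e-6)
    np.testing.assert_allclose(back.times, field.times, rtol=1e-8)


def test_field_csv_incomplete_grid_rejected(tmp_path):
    field = random_field(seed=2)
    path = tmp_path / "field.csv"
    field_to_csv(field, path)
    lines = path.read_text().splitlines()
    path.write_text("\n".join(lines[:-1]) + "\n")
    with pytest.raises(ValueError, match="complete"):
        field_from_csv(field.mesh, path, field.period)
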