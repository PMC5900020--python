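"""Map extraction: threshold crossings, gradients, exceedance summaries."""

import numpy as np
import pytest

from bzsim.geometry import GeometryConfig, build_mesh, strip_mesh
from bzsim.maps import (ScalarNodeMap, activation_times, gradient_summary,
                        repolarization_gradient, repolarization_times)
from bzsim.solver import VoltageRecord


def _synthetic_record(mesh, at_ms, apd_ms, cl=500.0, out_dt=1.0):
    """Idealized record: each node rests at -85, jumps to +20 at its
    activation time and back at activation + APD (per-node arrays)."""
    t = np.arange(0.0, cl, out_dt)
    V = np.full((t.size, mesh.n_nodes), -85.0, dtype=np.float32)
    for i in range(mesh.n_nodes):
        up = t >= at_ms[i]
        V[up, i] = 20.0
        V[t >= at_ms[i] + apd_ms[i], i] = -85.0
    return VoltageRecord(time=t, V=V, beat_onsets=np.array([0.0]),
                         cycle_length=cl)


@pytest.fixture(scope="module")
def small_mesh():
    return strip_mesh(10.0, 2.0, 0.25)


def test_activation_and_repolarization_crossings(small_mesh):
    x = small_mesh.nodes[:, 0]
    at_true = 3.0 + 2.0 * x          # planar wave at 0.5 mm/ms
    apd_true = np.full_like(x, 150.0)
    rec = _synthetic_record(small_mesh, at_true, apd_true)
    at = activation_times(rec)
    rt = repolarization_times(rec)
    assert at.mask.all() and rt.mask.all()
    # square transitions land within one sampling interval
    assert np.abs(at.values - at_true).max() <= 1.0
    assert np.abs((rt.values - at.values) - 150.0).max() <= 2.0


def test_activation_slope_matches_wave_speed(small_mesh):
    x = small_mesh.nodes[:, 0]
    rec = _synthetic_record(small_mesh, 2.0 * x, np.full_like(x, 100.0))
    at = activation_times(rec)
    sel = (x > 2.5) & (x < 7.5)
    slope = np.polyfit(x[sel], at.values[sel], 1)[0]
    assert 1.0 / slope == pytest.approx(0.5, rel=0.02)


def test_never_activated_node_is_masked(small_mesh):
    x = small_mesh.nodes[:, 0]
    at_true = 5.0 + 0.0 * x
    at_true[:10] = 1e6  # never reached within the record
    rec = _synthetic_record(small_mesh, at_true, np.full_like(x, 100.0))
    at = activation_times(rec)
    assert not at.mask[:10].any()
    assert at.mask[10:].all()
    rt = repolarization_times(rec, activation=at)
    assert not rt.mask[:10].any()


def test_gradient_zero_on_constant(small_mesh):
    rt = ScalarNodeMap(values=np.full(small_mesh.n_nodes, 300.0),
                       mask=np.ones(small_mesh.n_nodes, bool), units="ms")
    g = repolarization_gradient(small_mesh, rt)
    assert np.abs(g.values[g.mask]).max() < 1e-10


def test_gradient_exact_on_linear_field(small_mesh):
    rt = ScalarNodeMap(values=3.0 * small_mesh.nodes[:, 0],
                       mask=np.ones(small_mesh.n_nodes, bool), units="ms")
    g = repolarization_gradient(small_mesh, rt)
    np.testing.assert_allclose(g.values, 3.0, atol=1e-9)
    np.testing.assert_allclose(g.element_values, 3.0, atol=1e-9)


def test_gradient_mask_propagates(small_mesh):
    vals = 3.0 * small_mesh.nodes[:, 0]
    mask = np.ones(small_mesh.n_nodes, bool)
    mask[0] = False
    g = repolarization_gradient(
        small_mesh, ScalarNodeMap(values=vals, mask=mask, units="ms"))
    touched = (small_mesh.triangles == 0).any(axis=1)
    assert not g.element_mask[touched].any()
    assert g.element_mask[~touched].all()


@pytest.fixture(scope="module")
def scar_mesh():
    return build_mesh(GeometryConfig(resolution=0.4))


def test_gradient_summary_constructed_exceedance(scar_mesh):
    """Elements set to 6 ms/mm contribute their exact area above both the
    3.2 and 5.0 ms/mm thresholds."""
    areas = scar_mesh.element_areas()
    target = np.cumsum(areas) <= 10.0
    evals = np.where(target, 6.0, 0.0)
    nvals = np.zeros(scar_mesh.n_nodes)
    nvals[np.unique(scar_mesh.triangles[target])] = 6.0
    g = ScalarNodeMap(values=nvals, mask=np.ones(scar_mesh.n_nodes, bool),
                      units="ms/mm", element_values=evals,
                      element_mask=np.ones(scar_mesh.n_elems, bool))
    s = gradient_summary(g, scar_mesh, thresholds=(3.2, 5.0))
    row = s[s.region == "all"].iloc[0]
    picked = areas[target].sum()
    assert row["area_gt_3.2"] == pytest.approx(picked, rel=1e-9)
    assert row["area_gt_5"] == pytest.approx(picked, rel=1e-9)
    assert row["max_gradient"] == pytest.approx(6.0)


def test_gradient_summary_zero_map(scar_mesh):
    g = ScalarNodeMap(values=np.zeros(scar_mesh.n_nodes),
                      mask=np.ones(scar_mesh.n_nodes, bool), units="ms/mm",
                      element_values=np.zeros(scar_mesh.n_elems),
                      element_mask=np.ones(scar_mesh.n_elems, bool))
    s = gradient_summary(g, scar_mesh)
    assert (s["max_gradient"] == 0.0).all()
    assert (s.filter(like="area_gt") == 0.0).all().all()


def test_exceedance_area_monotone_in_threshold(scar_mesh):
    rng = np.random.default_rng(5)
    evals = rng.exponential(2.0, scar_mesh.n_elems)
    g = ScalarNodeMap(values=np.zeros(scar_mesh.n_nodes),
                      mask=np.ones(scar_mesh.n_nodes, bool), units="ms/mm",
                      element_values=evals,
                      element_mask=np.ones(scar_mesh.n_elems, bool))
    thresholds = (0.5, 1.0, 2.0, 4.0, 8.0)
    s = gradient_summary(g, scar_mesh, thresholds=thresholds)
    row = s[s.region == "all"].iloc[0]
    areas = [row[f"area_gt_{t:g}"] for t in thresholds]
    assert all(a >= b for a, b in zip(areas, areas[1:]))
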