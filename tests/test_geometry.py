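"""Scar/BZ sheet generator: hole, labels, fibers, stimulus, symmetry."""

import numpy as np
import pytest

from bzsim.geometry import (BORDER_ZONE, HEALTHY, GeometryConfig, TissueMesh,
                            assign_fibers, build_mesh, mirror_permutation,
                            place_stimulus, strip_mesh)


@pytest.fixture(scope="module")
def mesh03():
    return build_mesh(GeometryConfig(resolution=0.3))


@pytest.fixture(scope="module")
def mesh005():
    """Full-resolution sheet (50 um target mean edge length)."""
    return place_stimulus(build_mesh(GeometryConfig(resolution=0.05)), 0.5)


def test_bz_annulus_area_matches_analytic(mesh03):
    """Summed BZ element area ~ pi*(7^2 - 5^2) mm^2 within 2%."""
    area = mesh03.element_areas()[mesh03.region == BORDER_ZONE].sum()
    expected = np.pi * (7.0 ** 2 - 5.0 ** 2)
    assert area == pytest.approx(expected, rel=0.02)


def test_scar_hole_is_real(mesh03):
    """No element centroid inside the scar circle; no node strictly inside
    the circle minus half an edge length."""
    c = mesh03.element_centroids()
    r = np.linalg.norm(c - mesh03.center, axis=1)
    assert (r > mesh03.scar_radius).all()
    rn = np.linalg.norm(mesh03.nodes - mesh03.center, axis=1)
    assert rn.min() > mesh03.scar_radius - mesh03.grid_pitch


def test_bz_label_geometry(mesh03):
    c = mesh03.element_centroids()
    r = np.linalg.norm(c - mesh03.center, axis=1)
    bz = mesh03.region == BORDER_ZONE
    assert np.all(r[bz] > 5.0) and np.all(r[bz] <= 7.0)
    assert np.all(r[~bz] > 7.0)
    assert set(np.unique(mesh03.region)) == {HEALTHY, BORDER_ZONE}


def test_no_scar_degenerates_to_plain_sheet():
    m = build_mesh(GeometryConfig(scar_diameter=0.0, bz_thickness=0.0,
                                  resolution=0.5))
    assert (m.region == HEALTHY).all()
    assert m.element_areas().sum() == pytest.approx(900.0, rel=1e-9)


def test_too_coarse_resolution_rejected():
    with pytest.raises(ValueError, match="too coarse"):
        build_mesh(GeometryConfig(resolution=1.0))


def test_mean_edge_length_at_50um(mesh005):
    mean_edge = mesh005.edge_lengths().mean()
    assert 0.045 <= mean_edge <= 0.055


def test_stimulus_halfdisc_at_50um(mesh005):
    sel = mesh005.stimulus_nodes
    assert sel.size > 50
    pts = mesh005.nodes[sel]
    assert (pts[:, 1] <= 0.5 + 1e-9).all()
    assert np.linalg.norm(pts - [15.0, 0.0], axis=1).max() <= 0.5 + 1e-9
    # symmetric about the vertical midline
    xs = np.sort(pts[:, 0])
    np.testing.assert_allclose(xs + xs[::-1], 30.0, atol=1e-9)


def test_stimulus_radius_below_spacing_rejected(mesh03):
    with pytest.raises(ValueError, match="radius"):
        place_stimulus(mesh03, 0.05)


def test_horizontal_fibers_all_zero(mesh03):
    m = assign_fibers(mesh03, "horizontal")
    assert (m.fiber_angle == 0.0).all()


def test_random_fibers_seeded_and_healthy_untouched(mesh03):
    m1 = assign_fibers(mesh03, "random", seed=42)
    m2 = assign_fibers(mesh03, "random", seed=42)
    m3 = assign_fibers(mesh03, "random", seed=43)
    np.testing.assert_array_equal(m1.fiber_angle, m2.fiber_angle)
    assert not np.array_equal(m1.fiber_angle, m3.fiber_angle)
    bz = m1.region == BORDER_ZONE
    assert (m1.fiber_angle[~bz] == 0.0).all()
    a = m1.fiber_angle[bz]
    assert (a >= 0.0).all() and (a < np.pi).all()


def test_random_fiber_angles_uniform(mesh03):
    """Rayleigh test on 2*theta does not reject uniformity at alpha=0.01."""
    m = assign_fibers(mesh03, "random", seed=1)
    a = 2.0 * m.fiber_angle[m.region == BORDER_ZONE]
    n = a.size
    assert n >= 1000
    rbar = np.hypot(np.cos(a).mean(), np.sin(a).mean())
    z = n * rbar ** 2
    assert z < 4.6  # p ~ exp(-z) > 0.01


def test_mirror_symmetry(mesh03):
    perm = mirror_permutation(mesh03)
    mirrored = mesh03.nodes[perm]
    np.testing.assert_allclose(mirrored[:, 0], 30.0 - mesh03.nodes[:, 0],
                               atol=1e-9)
    np.testing.assert_allclose(mirrored[:, 1], mesh03.nodes[:, 1], atol=1e-12)


def test_node_region_majority(mesh03):
    nr = mesh03.node_region()
    r = np.linalg.norm(mesh03.nodes - mesh03.center, axis=1)
    bz_nodes = nr == BORDER_ZONE
    # BZ-labeled nodes live in a band slightly wider than the annulus
    assert r[bz_nodes].min() > 5.0 - 2 * mesh03.grid_pitch
    assert r[bz_nodes].max() < 7.0 + 2 * mesh03.grid_pitch


def test_strip_mesh_stimulus_and_fibers():
    m = strip_mesh(20.0, 1.0, 0.1, fiber_angle=np.pi / 2)
    assert m.stimulus_nodes.size > 0
    assert (m.nodes[m.stimulus_nodes, 0] <= 3 * m.grid_pitch).all()
    assert (m.fiber_angle == np.pi / 2).all()
    mean_edge = m.edge_lengths().mean()
    assert 0.09 <= mean_edge <= 0.11


def test_seed_only_affects_random_fibers():
    """Horizontal-fiber meshes are bitwise identical across seeds; the seed
    enters only through random BZ fiber angles."""
    a = build_mesh(GeometryConfig(resolution=0.5, random_seed=1))
    b = build_mesh(GeometryConfig(resolution=0.5, random_seed=2))
    np.testing.assert_array_equal(a.nodes, b.nodes)
    np.testing.assert_array_equal(a.triangles, b.triangles)
    np.testing.assert_array_equal(a.fiber_angle, b.fiber_angle)
    ra = build_mesh(GeometryConfig(resolution=0.5, bz_fiber_mode="random",
                                   random_seed=1))
    rb = build_mesh(GeometryConfig(resolution=0.5, bz_fiber_mode="random",
                                   random_seed=2))
    np.testing.assert_array_equal(ra.nodes, rb.nodes)
    assert not np.array_equal(ra.fiber_angle, rb.fiber_angle)
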