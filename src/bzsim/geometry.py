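"""Synthetic tissue geometry: 2D sheet, insulating scar core, border-zone annulus.

The domain is a square sheet of myocardium triangulated with a structured
crossed-diagonal pattern (alternating diagonals), which is deterministic and
exactly mirror-symmetric about the vertical midline.  The scar core is an
insulator realized by *removing* every element whose centroid falls inside
the scar circle; the border zone (BZ) is the annulus of elements around it.
Fibers in healthy tissue run along the x axis; BZ fibers are either also
horizontal or independently uniformly random per element.

Lengths are in mm.  The sheet's lower-left corner is the origin; the scar is
centered on the sheet.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy.sparse import coo_matrix
from scipy.sparse.csgraph import connected_components

HEALTHY = 0
BORDER_ZONE = 1

# mean edge length of the crossed-diagonal pattern is (2 + sqrt(2))/3 * h,
# where h is the structured grid pitch
_EDGE_FACTOR = (2.0 + np.sqrt(2.0)) / 3.0


@dataclass
class GeometryConfig:
    """Parameters of the synthetic scar/BZ sheet.

    ``resolution`` is the target *mean edge length* of the triangulation.
    """

    sheet_size: float = 30.0      # mm
    scar_diameter: float = 10.0   # mm
    bz_thickness: float = 2.0     # mm
    resolution: float = 0.05      # mm, target mean edge length
    bz_fiber_mode: str = "horizontal"
    random_seed: int = 0

    def __post_init__(self):
        if self.resolution <= 0:
            raise ValueError("resolution must be positive")
        if self.scar_diameter < 0 or self.bz_thickness < 0:
            raise ValueError("scar_diameter and bz_thickness must be >= 0")
        if self.scar_diameter + 2.0 * self.bz_thickness >= self.sheet_size:
            raise ValueError("scar plus border zone must fit inside the sheet")
        if self.bz_fiber_mode not in ("horizontal", "random"):
            raise ValueError(f"unknown bz_fiber_mode {self.bz_fiber_mode!r}")


@dataclass
class TissueMesh:
    """Triangulated 2D tissue with region labels, fibers and a stimulus site."""

    nodes: np.ndarray             # (n_nodes, 2) mm
    triangles: np.ndarray         # (n_elems, 3) node indices
    region: np.ndarray            # (n_elems,) HEALTHY / BORDER_ZONE
    fiber_angle: np.ndarray       # (n_elems,) radians from x axis
    stimulus_nodes: np.ndarray = field(
        default_factory=lambda: np.empty(0, dtype=np.int64))
    center: np.ndarray = field(default_factory=lambda: np.zeros(2))
    scar_radius: float = 0.0
    bz_outer_radius: float = 0.0
    grid_pitch: float = 0.0       # structured-grid pitch h

    @property
    def n_nodes(self) -> int:
        return self.nodes.shape[0]

    @property
    def n_elems(self) -> int:
        return self.triangles.shape[0]

    def element_centroids(self) -> np.ndarray:
        return self.nodes[self.triangles].mean(axis=1)

    def element_areas(self) -> np.ndarray:
        p = self.nodes[self.triangles]
        d1 = p[:, 1] - p[:, 0]
        d2 = p[:, 2] - p[:, 0]
        return 0.5 * np.abs(d1[:, 0] * d2[:, 1] - d1[:, 1] * d2[:, 0])

    def edge_lengths(self) -> np.ndarray:
        """Lengths of the unique edges of the triangulation."""
        t = self.triangles
        e = np.vstack([t[:, [0, 1]], t[:, [1, 2]], t[:, [2, 0]]])
        e.sort(axis=1)
        e = np.unique(e, axis=0)
        return np.linalg.norm(self.nodes[e[:, 0]] - self.nodes[e[:, 1]], axis=1)

    def node_region(self) -> np.ndarray:
        """Per-node region by majority vote of incident elements."""
        n_bz = np.zeros(self.n_nodes)
        n_tot = np.zeros(self.n_nodes)
        is_bz = (self.region == BORDER_ZONE).astype(float)
        for k in range(3):
            np.add.at(n_bz, self.triangles[:, k], is_bz)
            np.add.at(n_tot, self.triangles[:, k], 1.0)
        return np.where(n_bz * 2 > n_tot, BORDER_ZONE, HEALTHY)


def _rect_grid(lx: float, ly: float, resolution: float):
    """Structured crossed-diagonal triangulation of an lx-by-ly rectangle.

    The grid pitch is chosen so that the realized mean edge length matches
    ``resolution``; the number of divisions along x is rounded to an even
    value so the pattern is exactly mirror-symmetric about x = lx/2.
    """
    h_target = resolution / _EDGE_FACTOR
    nx = max(2, int(round(lx / h_target / 2.0)) * 2)
    ny = max(1, int(round(ly / h_target)))
    xs = np.linspace(0.0, lx, nx + 1)
    ys = np.linspace(0.0, ly, ny + 1)
    X, Y = np.meshgrid(xs, ys, indexing="ij")
    nodes = np.column_stack([X.ravel(), Y.ravel()])

    def nid(i, j):
        return i * (ny + 1) + j

    I, J = np.meshgrid(np.arange(nx), np.arange(ny), indexing="ij")
    I = I.ravel()
    J = J.ravel()
    a = nid(I, J)
    b = nid(I + 1, J)
    c = nid(I + 1, J + 1)
    d = nid(I, J + 1)
    main = (I + J) % 2 == 0  # diagonal a-c, mirrored parity flips it
    t1 = np.where(main[:, None], np.column_stack([a, b, c]),
                  np.column_stack([a, b, d]))
    t2 = np.where(main[:, None], np.column_stack([a, c, d]),
                  np.column_stack([b, c, d]))
    tris = np.vstack([t1, t2]).astype(np.int64)
    return nodes, tris, lx / nx


def build_mesh(config: GeometryConfig) -> TissueMesh:
    """Build the sheet, carve the scar core, and label the BZ annulus.

    Elements whose centroid lies within the scar radius of the sheet center
    are removed (the hole is real, giving a no-flux internal boundary).
    Elements with centroid radius in (scar_radius, scar_radius+bz_thickness]
    are labeled border zone.  Fibers are assigned per ``bz_fiber_mode``.
    """
    nodes, tris, pitch = _rect_grid(config.sheet_size, config.sheet_size,
                                    config.resolution)
    center = np.array([config.sheet_size / 2.0, config.sheet_size / 2.0])
    scar_r = config.scar_diameter / 2.0
    bz_outer = scar_r + config.bz_thickness

    if config.bz_thickness > 0 and config.scar_diameter > 0:
        if config.bz_thickness / pitch < 3:
            raise ValueError(
                "resolution too coarse: fewer than 3 elements across the "
                "border zone; refine the mesh")

    cent = nodes[tris].mean(axis=1)
    r = np.linalg.norm(cent - center, axis=1)
    keep = r > scar_r if config.scar_diameter > 0 else np.ones(len(tris), bool)
    tris = tris[keep]
    r = r[keep]

    region = np.where((r > scar_r) & (r <= bz_outer) & (scar_r > 0),
                      BORDER_ZONE, HEALTHY).astype(np.int8)

    # drop orphan nodes and reindex
    used = np.unique(tris)
    remap = -np.ones(nodes.shape[0], dtype=np.int64)
    remap[used] = np.arange(used.size)
    nodes = nodes[used]
    tris = remap[tris]

    _check_connected(nodes.shape[0], tris)

    mesh = TissueMesh(nodes=nodes, triangles=tris, region=region,
                      fiber_angle=np.zeros(len(tris)), center=center,
                      scar_radius=scar_r, bz_outer_radius=bz_outer,
                      grid_pitch=pitch)
    return assign_fibers(mesh, config.bz_fiber_mode, config.random_seed)


def _check_connected(n_nodes: int, tris: np.ndarray) -> None:
    i = np.concatenate([tris[:, 0], tris[:, 1], tris[:, 2]])
    j = np.concatenate([tris[:, 1], tris[:, 2], tris[:, 0]])
    adj = coo_matrix((np.ones_like(i), (i, j)), shape=(n_nodes, n_nodes))
    n_comp, _ = connected_components(adj, directed=False)
    if n_comp != 1:
        raise ValueError(f"mesh is not connected ({n_comp} components)")


def assign_fibers(mesh: TissueMesh, mode: str, seed: int = 0) -> TissueMesh:
    """Assign per-element fiber angles.

    Healthy elements are always horizontal (angle 0).  BZ elements are
    horizontal or drawn independently and uniformly on [0, pi) from the
    seeded generator.
    """
    if mode not in ("horizontal", "random"):
        raise ValueError(f"unknown fiber mode {mode!r}")
    angles = np.zeros(mesh.n_elems)
    if mode == "random":
        bz = mesh.region == BORDER_ZONE
        rng = np.random.default_rng(seed)
        angles[bz] = rng.uniform(0.0, np.pi, int(bz.sum()))
    return replace(mesh, fiber_angle=angles)


def place_stimulus(mesh: TissueMesh, radius: float = 0.5) -> TissueMesh:
    """Select the stimulus node set: all nodes within ``radius`` of the
    midpoint of the bottom edge (a half-disc)."""
    lx = mesh.nodes[:, 0].max()
    site = np.array([lx / 2.0, 0.0])
    d = np.linalg.norm(mesh.nodes - site, axis=1)
    sel = np.flatnonzero(d <= radius)
    if sel.size < 3:
        raise ValueError(
            f"stimulus radius {radius} mm captures only {sel.size} node(s); "
            "increase the radius or refine the mesh")
    return replace(mesh, stimulus_nodes=sel.astype(np.int64))


def strip_mesh(length: float = 20.0, width: float = 1.0,
               resolution: float = 0.1, fiber_angle: float = 0.0) -> TissueMesh:
    """Thin homogeneous strip for conduction-velocity measurements.

    Propagation is along x; ``fiber_angle`` sets the (uniform) fiber
    direction, 0 for longitudinal and pi/2 for transverse propagation.
    """
    nodes, tris, pitch = _rect_grid(length, width, resolution)
    mesh = TissueMesh(
        nodes=nodes, triangles=tris,
        region=np.zeros(len(tris), dtype=np.int8),
        fiber_angle=np.full(len(tris), float(fiber_angle)),
        center=np.array([length / 2.0, width / 2.0]),
        grid_pitch=pitch)
    # fixed physical stimulus width so capture does not depend on resolution
    stim = np.flatnonzero(nodes[:, 0] <= max(0.25, 2 * pitch) + 1e-12)
    return replace(mesh, stimulus_nodes=stim.astype(np.int64))


def mirror_permutation(mesh: TissueMesh) -> np.ndarray:
    """Node permutation mapping each node to its mirror image about the
    vertical midline; raises if the mesh is not symmetric."""
    lx = mesh.nodes[:, 0].max()
    nx = int(round(lx / mesh.grid_pitch))
    # column index is exact on the structured grid; mirror rows share the
    # same y float bit-for-bit, so (column, y) is a safe key
    cols = np.rint(mesh.nodes[:, 0] / mesh.grid_pitch).astype(np.int64)
    key = {(c, y): idx
           for idx, (c, y) in enumerate(zip(cols, mesh.nodes[:, 1]))}
    perm = np.empty(mesh.n_nodes, dtype=np.int64)
    for idx in range(mesh.n_nodes):
        k = (nx - cols[idx], mesh.nodes[idx, 1])
        if k not in key:
            raise ValueError("mesh is not mirror-symmetric")
        perm[idx] = key[k]
    return perm
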