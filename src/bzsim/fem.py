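"""Linear-triangle finite element operators for the monodomain equation.

The stiffness operator discretizes -div(D grad V) with natural (no-flux)
boundary conditions, so the outer sheet boundary and the boundary of the
removed scar core are insulating by construction.  The mass matrix is lumped
(row sums placed on the diagonal), which keeps the diffusion solve an SPD
sparse system and permits explicit treatment of the reaction term.

Unit audit: conductivities are bulk monodomain values in S/m; the effective
diffusivity entering the discrete operator is

    D [mm^2/ms] = 0.1 * sigma [S/m] / (beta [1/um] * Cm [uF/cm^2])

(sigma 1 S/m = 1e-3 S/mm; beta 1/um = 1e3 /mm; Cm 1 uF/cm^2 = 1e-8 F/mm^2;
S/F = 1/s = 1e-3/ms; collecting powers of ten gives the 0.1 factor).
With the study defaults (beta=0.14/um, Cm=1 uF/cm^2) the normal longitudinal
conductivity 0.1890 S/m yields D = 0.135 mm^2/ms.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.sparse import coo_matrix, csr_matrix

from .geometry import TissueMesh


@dataclass
class ConductivityField:
    """Per-element longitudinal/transverse bulk conductivities (S/m).

    With the element fiber angle theta the 2x2 conductivity tensor is
    R(theta) diag(sigma_l, sigma_t) R(theta)^T.
    """

    sigma_l: np.ndarray  # (n_elems,)
    sigma_t: np.ndarray  # (n_elems,)

    def __post_init__(self):
        self.sigma_l = np.asarray(self.sigma_l, dtype=float)
        self.sigma_t = np.asarray(self.sigma_t, dtype=float)
        if np.any(self.sigma_t <= 0) or np.any(self.sigma_l <= 0):
            raise ValueError("conductivities must be positive")
        # by convention sigma_l >= sigma_t (isotropic allowed); the tensor
        # itself is well defined either way, and rotating the fibers by 90
        # degrees is equivalent to swapping the two values

    @classmethod
    def uniform(cls, n_elems: int, sigma_l: float,
                sigma_t: float) -> "ConductivityField":
        return cls(np.full(n_elems, sigma_l), np.full(n_elems, sigma_t))

    def tensors(self, fiber_angle: np.ndarray) -> np.ndarray:
        """Per-element 2x2 tensors R diag(sl, st) R^T (same units as sigma)."""
        c = np.cos(fiber_angle)
        s = np.sin(fiber_angle)
        sl, st = self.sigma_l, self.sigma_t
        t = np.empty((len(sl), 2, 2))
        t[:, 0, 0] = sl * c * c + st * s * s
        t[:, 1, 1] = sl * s * s + st * c * c
        t[:, 0, 1] = t[:, 1, 0] = (sl - st) * c * s
        return t


def sigma_to_diffusivity(sigma: np.ndarray, beta: float, cm: float):
    """Bulk conductivity (S/m) -> monodomain diffusivity (mm^2/ms)."""
    return 0.1 * sigma / (beta * cm)


def _shape_gradients(mesh: TissueMesh):
    """P1 basis gradients b (d/dx) and c (d/dy), shape (n_elems, 3), and
    signed element areas."""
    p = mesh.nodes[mesh.triangles]
    x = p[..., 0]
    y = p[..., 1]
    area2 = ((x[:, 1] - x[:, 0]) * (y[:, 2] - y[:, 0])
             - (x[:, 2] - x[:, 0]) * (y[:, 1] - y[:, 0]))
    bad = np.abs(area2) < 1e-12
    if bad.any():
        raise ValueError(
            f"degenerate (zero-area) triangle(s): elements "
            f"{np.flatnonzero(bad)[:5].tolist()}")
    b = np.stack([y[:, 1] - y[:, 2], y[:, 2] - y[:, 0],
                  y[:, 0] - y[:, 1]], axis=1) / area2[:, None]
    c = np.stack([x[:, 2] - x[:, 1], x[:, 0] - x[:, 2],
                  x[:, 1] - x[:, 0]], axis=1) / area2[:, None]
    return b, c, 0.5 * np.abs(area2)


def assemble_operators(mesh: TissueMesh, conductivity: ConductivityField,
                       beta: float = 0.14, cm: float = 1.0):
    """Assemble the diffusion stiffness matrix and lumped mass vector.

    Returns ``(K, m)`` where ``K`` (csr, mm^2/ms-weighted) discretizes
    -div(D grad .) with no-flux boundaries and ``m`` is the lumped mass
    (node areas, mm^2).  ``K`` is symmetric and its rows sum to zero.
    """
    if len(conductivity.sigma_l) != mesh.n_elems:
        raise ValueError("conductivity and mesh element counts differ")
    b, c, area = _shape_gradients(mesh)
    d_l = sigma_to_diffusivity(conductivity.sigma_l, beta, cm)
    d_t = sigma_to_diffusivity(conductivity.sigma_t, beta, cm)
    # diffusivity tensor entries, rotated by the element fiber angle
    ca = np.cos(mesh.fiber_angle)
    sa = np.sin(mesh.fiber_angle)
    dxx = d_l * ca * ca + d_t * sa * sa
    dyy = d_l * sa * sa + d_t * ca * ca
    dxy = (d_l - d_t) * ca * sa

    # Ke[i,j] = area * grad_i . D grad_j
    ke = (area[:, None, None]
          * (dxx[:, None, None] * b[:, :, None] * b[:, None, :]
             + dyy[:, None, None] * c[:, :, None] * c[:, None, :]
             + dxy[:, None, None] * (b[:, :, None] * c[:, None, :]
                                     + c[:, :, None] * b[:, None, :])))
    rows = np.repeat(mesh.triangles, 3, axis=1).ravel()
    cols = np.tile(mesh.triangles, (1, 3)).ravel()
    K = coo_matrix((ke.ravel(), (rows, cols)),
                   shape=(mesh.n_nodes, mesh.n_nodes)).tocsr()

    m = np.zeros(mesh.n_nodes)
    for k in range(3):
        np.add.at(m, mesh.triangles[:, k], area / 3.0)
    return K, m


def element_gradients(mesh: TissueMesh, u: np.ndarray) -> np.ndarray:
    """Constant per-element gradient (du/dx, du/dy) of a nodal field."""
    b, c, _ = _shape_gradients(mesh)
    ue = u[mesh.triangles]
    return np.stack([(ue * b).sum(axis=1), (ue * c).sum(axis=1)], axis=1)
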