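"""Mixed Q9/Q4 (Taylor-Hood family) quadrilateral element machinery.

Displacement is interpolated with 9-node biquadratic Lagrange shape
functions, pressure with 4-node bilinear shape functions on the corner
nodes.  This pairing is inf-sup stable, which matters here because the
instantaneous (undrained) response of a biphasic tissue is incompressible.

Local node ordering is tensor-product: ``n = 3*j + i`` with
``xi_i, eta_j in {-1, 0, +1}``; corners are local nodes (0, 2, 8, 6).
Integration uses a 3x3 Gauss rule.
"""

from __future__ import annotations

import numpy as np
import scipy.sparse as sp

# corner local ids in counter-clockwise order, matching Q4 shape functions
CORNER_LOCAL = np.array([0, 2, 8, 6])

_G = np.sqrt(3.0 / 5.0)
_W1 = np.array([5.0 / 9.0, 8.0 / 9.0, 5.0 / 9.0])
GAUSS_PTS = np.array([(x, y) for y in (-_G, 0.0, _G) for x in (-_G, 0.0, _G)])
GAUSS_WTS = np.array([_W1[i] * _W1[j] for j in range(3) for i in range(3)])


def _lag1d(x: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """1-D quadratic Lagrange values and derivatives at points x, nodes -1,0,1."""
    N = np.stack([0.5 * x * (x - 1.0), 1.0 - x * x, 0.5 * x * (x + 1.0)], axis=-1)
    dN = np.stack([x - 0.5, -2.0 * x, x + 0.5], axis=-1)
    return N, dN


def q9_shape(points: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Q9 shape functions N (npts, 9) and derivatives dN (npts, 9, 2)."""
    points = np.atleast_2d(points)
    Nx, dNx = _lag1d(points[:, 0])
    Ny, dNy = _lag1d(points[:, 1])
    N = (Ny[:, :, None] * Nx[:, None, :]).reshape(len(points), 9)
    dN = np.empty((len(points), 9, 2))
    dN[:, :, 0] = (Ny[:, :, None] * dNx[:, None, :]).reshape(len(points), 9)
    dN[:, :, 1] = (dNy[:, :, None] * Nx[:, None, :]).reshape(len(points), 9)
    return N, dN


def q4_shape(points: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Q4 shape functions on corners (0,2,8,6 order) and derivatives."""
    points = np.atleast_2d(points)
    xi, eta = points[:, 0], points[:, 1]
    signs = np.array([(-1, -1), (1, -1), (1, 1), (-1, 1)], dtype=float)
    N = 0.25 * (1 + xi[:, None] * signs[:, 0]) * (1 + eta[:, None] * signs[:, 1])
    dN = np.empty((len(points), 4, 2))
    dN[:, :, 0] = 0.25 * signs[:, 0] * (1 + eta[:, None] * signs[:, 1])
    dN[:, :, 1] = 0.25 * signs[:, 1] * (1 + xi[:, None] * signs[:, 0])
    return N, dN


class FEOperators:
    """Precomputed quadrature data and assembly routines for one mesh.

    Attributes ending in ``_`` are flat arrays sized for vectorized COO
    assembly.  Global DOF layout: displacement DOFs ``2*node + {0,1}`` for
    every mesh node, then pressure DOFs ``2*n_nodes + ip`` where ``ip``
    indexes the sorted corner-node list.
    """

    def __init__(self, mesh) -> None:
        self.mesh = mesh
        nodes, elems = mesh.nodes, mesh.elements
        ne = len(elems)
        self.n_nodes = len(nodes)
        self.pressure_nodes = mesh.pressure_nodes
        self.n_p = len(self.pressure_nodes)
        self.ndof = 2 * self.n_nodes + self.n_p
        self._pidx = -np.ones(self.n_nodes, dtype=int)
        self._pidx[self.pressure_nodes] = np.arange(self.n_p)

        Nq9, dNq9 = q9_shape(GAUSS_PTS)          # (g,9), (g,9,2)
        Nq4, dNq4 = q4_shape(GAUSS_PTS)          # (g,4), (g,4,2)
        self.N_disp = Nq9
        self.N_press = Nq4

        X = nodes[elems]                          # (e,9,2)
        # Jacobian J[e,g,a,b] = d x_a / d xi_b
        J = np.einsum("eni,gnj->egij", X, dNq9)
        detJ = J[..., 0, 0] * J[..., 1, 1] - J[..., 0, 1] * J[..., 1, 0]
        if np.any(detJ <= 0):
            bad = np.unique(np.where(detJ <= 0)[0])
            raise ValueError(f"inverted elements (non-positive Jacobian): {bad[:10]}")
        Jinv = np.empty_like(J)
        Jinv[..., 0, 0] = J[..., 1, 1] / detJ
        Jinv[..., 1, 1] = J[..., 0, 0] / detJ
        Jinv[..., 0, 1] = -J[..., 0, 1] / detJ
        Jinv[..., 1, 0] = -J[..., 1, 0] / detJ
        self.detJw = detJ * GAUSS_WTS             # (e,g)
        # physical gradients dN/dx: (e,g,n,a)
        self.gradN = np.einsum("gnb,egba->egna", dNq9, Jinv)
        self.gradNq = np.einsum("gnb,egba->egna", dNq4, Jinv)

        # element DOF maps
        self.edofs_u = np.empty((ne, 18), dtype=int)
        self.edofs_u[:, 0::2] = 2 * elems
        self.edofs_u[:, 1::2] = 2 * elems + 1
        self.edofs_p = 2 * self.n_nodes + self._pidx[elems[:, CORNER_LOCAL]]

        # strain-displacement matrices B (e,g,3,18): rows exx, eyy, gxy
        e, g = self.detJw.shape
        B = np.zeros((e, g, 3, 18))
        B[:, :, 0, 0::2] = self.gradN[..., 0]
        B[:, :, 1, 1::2] = self.gradN[..., 1]
        B[:, :, 2, 0::2] = self.gradN[..., 1]
        B[:, :, 2, 1::2] = self.gradN[..., 0]
        self.B = B
        self.div_row = B[:, :, 0, :] + B[:, :, 1, :]   # (e,g,18)

    # -- assembly -----------------------------------------------------------

    def _coo(self, ke: np.ndarray, rows_map: np.ndarray, cols_map: np.ndarray) -> sp.coo_matrix:
        ne, nr, nc = ke.shape
        rows = np.repeat(rows_map, nc, axis=1).ravel()
        cols = np.tile(cols_map, (1, nr)).ravel()
        return sp.coo_matrix((ke.ravel(), (rows, cols)), shape=(self.ndof, self.ndof))

    def stiffness_matrix(self, lam: np.ndarray, mu: np.ndarray) -> sp.csr_matrix:
        """Drained-matrix stiffness, per-element Lame constants (arrays of len ne)."""
        D = np.zeros((len(lam), 3, 3))
        D[:, 0, 0] = D[:, 1, 1] = lam + 2 * mu
        D[:, 0, 1] = D[:, 1, 0] = lam
        D[:, 2, 2] = mu
        ke = np.einsum("eg,egri,ers,egsj->eij", self.detJw, self.B, D, self.B, optimize=True)
        return self._coo(ke, self.edofs_u, self.edofs_u).tocsr()

    def coupling_matrix(self) -> sp.csr_matrix:
        """B-block: integral of N_p * div(u); rows = pressure DOFs, cols = u DOFs."""
        ke = np.einsum("eg,gq,egj->eqj", self.detJw, self.N_press, self.div_row, optimize=True)
        return self._coo(ke, self.edofs_p, self.edofs_u).tocsr()

    def permeability_matrix(self, k: np.ndarray) -> sp.csr_matrix:
        """H-block: integral of k grad(N_p) . grad(N_p)."""
        ke = np.einsum("eg,e,egqa,egra->eqr", self.detJw, k, self.gradNq, self.gradNq,
                       optimize=True)
        return self._coo(ke, self.edofs_p, self.edofs_p).tocsr()

    def strains(self, u: np.ndarray) -> np.ndarray:
        """Strain (exx, eyy, gxy) at each Gauss point: (e, g, 3)."""
        ue = u[self.edofs_u]                     # (e,18)
        return np.einsum("egri,ei->egr", self.B, ue)

    def pressures_at_gauss(self, p_dofs: np.ndarray) -> np.ndarray:
        """Pressure at Gauss points from the global pressure sub-vector."""
        pe = p_dofs[self.edofs_p - 2 * self.n_nodes]   # (e,4)
        return np.einsum("gq,eq->eg", self.N_press, pe)

    def fibril_force_tangent(self, u: np.ndarray, fibre_dir: np.ndarray,
                             E_f: np.ndarray, forced_active: np.ndarray | None = None
                             ) -> tuple[np.ndarray, sp.csr_matrix, np.ndarray]:
        """Tension-only fibril internal force and consistent tangent.

        fibre strain eps_f = a . eps with a = (dx^2, dy^2, dx*dy) and
        engineering shear; only Gauss points with eps_f > 0 contribute.
        ``forced_active`` overrides the switching set (used to damp Newton
        chattering at the tension/compression margin).  Returns (global
        force vector, tangent CSR, active Gauss-point mask).
        """
        a = np.stack([fibre_dir[:, 0] ** 2, fibre_dir[:, 1] ** 2,
                      fibre_dir[:, 0] * fibre_dir[:, 1]], axis=1)   # (e,3)
        eps = self.strains(u)                                       # (e,g,3)
        eps_f = np.einsum("er,egr->eg", a, eps)
        if forced_active is None:
            active = (eps_f > 0.0) & (E_f[:, None] > 0.0)
        else:
            active = forced_active
        f = np.zeros(self.ndof)
        if not np.any(active):
            return f, sp.csr_matrix((self.ndof, self.ndof)), active
        w = np.where(active, self.detJw * E_f[:, None], 0.0)         # (e,g)
        Ba = np.einsum("er,egri->egi", a, self.B)                    # (e,g,18)
        fe = np.einsum("eg,eg,egi->ei", w, eps_f, Ba)
        np.add.at(f, self.edofs_u, fe)
        ke = np.einsum("eg,egi,egj->eij", w, Ba, Ba, optimize=True)
        return f, self._coo(ke, self.edofs_u, self.edofs_u).tocsr(), active

    def effective_stress_at_gauss(self, u: np.ndarray, lam: np.ndarray, mu: np.ndarray,
                                  fibre_dir: np.ndarray, E_f: np.ndarray
                                  ) -> tuple[np.ndarray, np.ndarray]:
        """Effective stress (sxx, syy, sxy) and szz at Gauss points (plane strain)."""
        eps = self.strains(u)                     # (e,g,3)
        tr = eps[..., 0] + eps[..., 1]
        s = np.empty_like(eps)
        s[..., 0] = lam[:, None] * tr + 2 * mu[:, None] * eps[..., 0]
        s[..., 1] = lam[:, None] * tr + 2 * mu[:, None] * eps[..., 1]
        s[..., 2] = mu[:, None] * eps[..., 2]
        szz = lam[:, None] * tr
        a = np.stack([fibre_dir[:, 0] ** 2, fibre_dir[:, 1] ** 2,
                      fibre_dir[:, 0] * fibre_dir[:, 1]], axis=1)
        eps_f = np.einsum("er,egr->eg", a, eps)
        sf = np.where(eps_f > 0, E_f[:, None] * eps_f, 0.0)          # (e,g)
        s[..., 0] += sf * a[:, 0][:, None]
        s[..., 1] += sf * a[:, 1][:, None]
        s[..., 2] += sf * a[:, 2][:, None]
        return s, szz
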