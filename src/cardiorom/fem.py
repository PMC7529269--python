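"""Bilinear (Q1) finite element assembly on uniform structured grids.

The diffusion operator -div(sigma(x) D grad u) with homogeneous Neumann
conditions is assembled with 2x2 Gauss quadrature and an elementwise
constant conductivity tensor (nodal fields are averaged per element).
The mass matrix is lumped (row sums), which together with nodal evaluation
of the ionic terms makes the semi-discrete gating ODEs collocated at the
grid nodes.
"""

from __future__ import annotations

import numpy as np
import scipy.sparse as sp

# 2-point Gauss rule on [-1, 1]
_GP = np.array([-1.0, 1.0]) / np.sqrt(3.0)
_GW = np.array([1.0, 1.0])


def _reference_gradients() -> tuple[np.ndarray, np.ndarray]:
    """Shape-function gradients at the 4 Gauss points of the reference square.

    Local node order (xi, eta) in {(-1,-1), (1,-1), (-1,1), (1,1)} matching
    Grid2D.elements(). Returns (grads[q, a, 2], weights[q]).
    """
    pts = [(xi, eta) for eta in _GP for xi in _GP]
    wts = [wx * wy for wy in _GW for wx in _GW]
    grads = np.empty((4, 4, 2))
    for q, (xi, eta) in enumerate(pts):
        # dN/dxi, dN/deta for N_a = 1/4 (1 + xi_a xi)(1 + eta_a eta)
        sign = [(-1, -1), (1, -1), (-1, 1), (1, 1)]
        for a, (sx, sy) in enumerate(sign):
            grads[q, a, 0] = 0.25 * sx * (1 + sy * eta)
            grads[q, a, 1] = 0.25 * sy * (1 + sx * xi)
    return grads, np.asarray(wts, dtype=float)


_REF_GRADS, _REF_WTS = _reference_gradients()


def lumped_mass(grid) -> np.ndarray:
    """Diagonal of the lumped Q1 mass matrix (length N, strictly positive).

    Row-sum lumping assigns each node a quarter of the area of every
    adjacent element, so the total equals the domain area Lx * Ly.
    """
    conn = grid.elements()
    area4 = grid.hx * grid.hy / 4.0
    m = np.zeros(grid.n_nodes)
    np.add.at(m, conn.ravel(), area4)
    return m


def stiffness(grid, tensors: np.ndarray) -> sp.csr_matrix:
    """Assemble the stiffness matrix for elementwise tensors D_e.

    Parameters
    ----------
    grid : Grid2D
    tensors : (ne, 2, 2) array
        Symmetric positive conductivity tensor per element (already
        including any scalar modulation).

    Returns
    -------
    scipy.sparse.csr_matrix encoding  u -> -div(D grad u)  with natural
    (homogeneous Neumann) boundary conditions; its null space contains the
    constant vector.
    """
    conn = grid.elements()
    ne = conn.shape[0]
    tensors = np.asarray(tensors, dtype=float)
    if tensors.shape != (ne, 2, 2):
        raise ValueError(f"tensors must have shape ({ne}, 2, 2)")

    # physical gradients: d/dx = (2/hx) d/dxi, d/dy = (2/hy) d/deta
    scale = np.array([2.0 / grid.hx, 2.0 / grid.hy])
    G = _REF_GRADS * scale[None, None, :]  # (q, a, 2), same for every element
    detJ = grid.hx * grid.hy / 4.0

    # K_e[a, b] = sum_q w_q detJ * G[q,a,:] @ D_e @ G[q,b,:]
    # -> einsum over q with element-dependent D
    DG = np.einsum("nde,qbe->qnbd", tensors, G)  # (q, ne, b, 2)
    Ke = np.einsum("q,qad,qnbd->nab", _REF_WTS * detJ, G, DG)  # (ne, 4, 4)

    rows = np.repeat(conn, 4, axis=1).ravel()
    cols = np.tile(conn, (1, 4)).ravel()
    A = sp.coo_matrix(
        (Ke.ravel(), (rows, cols)), shape=(grid.n_nodes, grid.n_nodes)
    )
    return A.tocsr()


def nodal_to_element(grid, field: np.ndarray) -> np.ndarray:
    """Average a nodal scalar field onto elements (ne,)."""
    conn = grid.elements()
    return np.asarray(field, dtype=float)[conn].mean(axis=1)
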