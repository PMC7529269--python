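"""Independent, naively-coded reference implementations used as oracles.

Everything here is deliberately written loop-by-loop, without reusing the
package's assembly or stepping code, so agreement is meaningful.
"""

from __future__ import annotations

import numpy as np


def dense_q1_operators(nx, ny, Lx, Ly, tensor_fn):
    """Dense stiffness and lumped mass by per-element loops.

    ``tensor_fn(cx, cy) -> (2, 2)`` returns the conductivity tensor at the
    element center (cx, cy).  Node (i, j) has index j * nx + i.
    """
    hx = Lx / (nx - 1)
    hy = Ly / (ny - 1)
    N = nx * ny
    A = np.zeros((N, N))
    M = np.zeros(N)
    gp = [-1.0 / np.sqrt(3.0), 1.0 / np.sqrt(3.0)]
    signs = [(-1, -1), (1, -1), (-1, 1), (1, 1)]
    for j in range(ny - 1):
        for i in range(nx - 1):
            nodes = [j * nx + i, j * nx + i + 1,
                     (j + 1) * nx + i, (j + 1) * nx + i + 1]
            cx = (i + 0.5) * hx
            cy = (j + 0.5) * hy
            D = np.asarray(tensor_fn(cx, cy), dtype=float)
            Ke = np.zeros((4, 4))
            for xi in gp:
                for eta in gp:
                    grads = []
                    for sx, sy in signs:
                        gxi = 0.25 * sx * (1 + sy * eta)
                        geta = 0.25 * sy * (1 + sx * xi)
                        grads.append([gxi * 2.0 / hx, geta * 2.0 / hy])
                    grads = np.asarray(grads)
                    for a in range(4):
                        for b in range(4):
                            Ke[a, b] += grads[a] @ D @ grads[b] * (hx * hy / 4)
            for a in range(4):
                M[nodes[a]] += hx * hy / 4.0
                for b in range(4):
                    A[nodes[a], nodes[b]] += Ke[a, b]
    return M, A


def dense_semi_implicit_step(u, w, M, A, ionic, dt, iapp=None, rho=None):
    """One step of the documented scheme with dense linear algebra.

    w' = w + dt g(u, w); then (M/dt + A) u' = (M/dt) u - M rho Iion(u, w')
    + M iapp, all evaluated nodally.
    """
    K, a, b, eps0, c1, c2 = (ionic.K, ionic.a, ionic.b, ionic.eps0,
                             ionic.c1, ionic.c2)
    n = len(u)
    w_new = np.empty(n)
    iion = np.empty(n)
    for i in range(n):
        g = (eps0 + c1 * w[i] / (c2 + u[i])) * (
            -w[i] - K * u[i] * (u[i] - b - 1.0)
        )
        w_new[i] = w[i] + dt * g
        iion[i] = K * u[i] * (u[i] - a) * (u[i] - 1.0) + u[i] * w_new[i]
    if rho is not None:
        iion = rho * iion
    rhs = (M / dt) * u - M * iion
    if iapp is not None:
        rhs = rhs + M * iapp
    lhs = np.diag(M / dt) + A
    u_new = np.linalg.solve(lhs, rhs)
    return u_new, w_new
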