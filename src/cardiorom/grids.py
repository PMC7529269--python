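"""Structured 2D grids and time discretization.

All dynamics are integrated in rescaled (dimensionless) time; one rescaled
time unit equals 12.9 ms and the dimensionless potential u maps to
millivolts through u_mV = 100 u - 80 (resting state -80 mV, excited state
+20 mV).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

#: One rescaled time unit in milliseconds.
TIME_SCALE_MS = 12.9
#: Potential scale and offset: u_mV = V_SCALE_MV * u + V_REST_MV.
V_SCALE_MV = 100.0
V_REST_MV = -80.0


@dataclass(frozen=True)
class Grid2D:
    """Uniform tensor-product grid of nodes on the rectangle (0, Lx) x (0, Ly).

    Nodes are ordered lexicographically with x running fastest: the node with
    integer coordinates (i, j), located at (i * hx, j * hy), has flat index
    ``j * nx + i``.
    """

    nx: int
    ny: int
    Lx: float
    Ly: float

    def __post_init__(self) -> None:
        if self.nx < 2 or self.ny < 2:
            raise ValueError("need at least 2 nodes per axis")
        if self.Lx <= 0 or self.Ly <= 0:
            raise ValueError("side lengths must be positive")

    @property
    def n_nodes(self) -> int:
        return self.nx * self.ny

    @property
    def hx(self) -> float:
        return self.Lx / (self.nx - 1)

    @property
    def hy(self) -> float:
        return self.Ly / (self.ny - 1)

    def coords(self) -> np.ndarray:
        """(N, 2) array of node coordinates in lexicographic order."""
        x = np.linspace(0.0, self.Lx, self.nx)
        y = np.linspace(0.0, self.Ly, self.ny)
        X, Y = np.meshgrid(x, y)  # row index = j (y), column index = i (x)
        return np.column_stack([X.ravel(), Y.ravel()])

    def elements(self) -> np.ndarray:
        """(ne, 4) connectivity of bilinear quadrilateral elements.

        Local node order: (i, j), (i+1, j), (i, j+1), (i+1, j+1).
        """
        i = np.arange(self.nx - 1)
        j = np.arange(self.ny - 1)
        I, J = np.meshgrid(i, j)
        n00 = (J * self.nx + I).ravel()
        return np.column_stack([n00, n00 + 1, n00 + self.nx, n00 + self.nx + 1])


@dataclass(frozen=True)
class TimeGrid:
    """Time stepping and snapshot sampling in rescaled time.

    Parameters
    ----------
    dt : float
        Step size in rescaled units (e.g. 0.1 / 12.9 for a 0.1 ms step).
    T_ms : float
        Final time in milliseconds.
    n_snapshots : int
        Number of states sampled uniformly over the snapshot window.
    t_start_ms : float
        Start of the snapshot window (states before it are computed but not
        stored), default 0.
    """

    dt: float
    T_ms: float
    n_snapshots: int
    t_start_ms: float = 0.0

    def __post_init__(self) -> None:
        if self.dt <= 0:
            raise ValueError("dt must be positive")
        if not 0.0 <= self.t_start_ms < self.T_ms:
            raise ValueError("snapshot window must lie inside (0, T)")
        if self.n_snapshots > self.n_steps:
            raise ValueError("cannot sample more snapshots than time steps")

    @property
    def n_steps(self) -> int:
        return int(round((self.T_ms / TIME_SCALE_MS) / self.dt))

    def sample_steps(self) -> np.ndarray:
        """Indices k (state at t = k dt) of the sampled snapshots.

        The n_snapshots indices are spread uniformly over the steps whose
        times fall in [t_start_ms, T_ms].
        """
        k = np.arange(1, self.n_steps + 1)
        t_ms = k * self.dt * TIME_SCALE_MS
        window = k[t_ms >= self.t_start_ms - 1e-9]
        # anchored at the end so that n_snapshots = 1 samples the final time
        pick = np.round(np.linspace(len(window) - 1, 0, self.n_snapshots))
        steps = window[pick[::-1].astype(int)]
        if len(np.unique(steps)) != len(steps):
            raise ValueError("snapshot sampling produced duplicate steps")
        return steps

    def sample_times(self) -> np.ndarray:
        """Rescaled times of the sampled snapshots."""
        return self.sample_steps() * self.dt
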