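"""Full order model: monodomain + Aliev-Panfilov on a structured slab.

Semi-discretization is Q1 finite elements with lumped mass and nodal
(collocated) ionic terms; time integration is a one-step, first-order
semi-implicit scheme: diffusion implicit, reaction explicit, with the
gating variable advanced first (explicit Euler on the recovery rate
dw/dt = g) and the new gating value used in the ionic current of the
potential update:

    w^{k+1} = w^k + dt g(u^k, w^k)
    (M/dt + A) u^{k+1} = (M/dt) u^k - M Iion(u^k, w^{k+1}) + M Iapp(t^k)

The system matrix is time-independent for a fixed parameter, so a sparse
LU factorization is computed once and reused at every step.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla

from .fem import lumped_mass, nodal_to_element, stiffness
from .grids import Grid2D, TimeGrid, TIME_SCALE_MS
from .ionic import IonicParams, gating_rhs, ionic_current

_NAN_CHECK_EVERY = 100
#: Tolerance on stimulus-window comparisons; keeps the FOM and the reduced
#: solvers consistent when a window edge falls exactly on a time step.
_T_TOL_MS = 1e-9


@dataclass
class ConductivityModel:
    """Anisotropic conductivity  sigma(x) * (sigma_t I + (sigma_l - sigma_t) f0 f0^T).

    sigma_l / sigma_t are the conductivities along / across the fiber
    direction f0 (unit vector, constant or nodal); ``modulation`` is an
    optional scalar field in (0, 1] (e.g. the ischemic factor) applied
    multiplicatively to the whole tensor.
    """

    sigma_l: float
    sigma_t: float
    f0: np.ndarray = field(default_factory=lambda: np.array([1.0, 0.0]))
    modulation: np.ndarray | None = None

    def __post_init__(self) -> None:
        if not (self.sigma_l >= self.sigma_t > 0):
            raise ValueError("require sigma_l >= sigma_t > 0")
        self.f0 = np.asarray(self.f0, dtype=float)
        norms = np.linalg.norm(self.f0, axis=-1)
        if not np.allclose(norms, 1.0, atol=1e-10):
            raise ValueError("fiber vectors must have unit norm")
        if self.modulation is not None:
            m = np.asarray(self.modulation, dtype=float)
            if np.any(m <= 0) or np.any(m > 1 + 1e-12):
                raise ValueError("modulation must lie in (0, 1]")
            self.modulation = m

    def element_tensors(self, grid: Grid2D) -> np.ndarray:
        """(ne, 2, 2) conductivity tensors averaged per element."""
        ne = (grid.nx - 1) * (grid.ny - 1)
        if self.f0.ndim == 1:
            f = np.broadcast_to(self.f0, (ne, 2))
        else:
            conn = grid.elements()
            f = self.f0[conn].mean(axis=1)
            f = f / np.linalg.norm(f, axis=1, keepdims=True)
        D = self.sigma_t * np.eye(2)[None, :, :] + (
            self.sigma_l - self.sigma_t
        ) * np.einsum("ni,nj->nij", f, f)
        if self.modulation is not None:
            D = D * nodal_to_element(grid, self.modulation)[:, None, None]
        return D


@dataclass
class GaussianStimulus:
    """Applied current C exp(-||x - center||^2 / beta) on a time window [ms]."""

    C: float
    beta_cm2: float
    center: tuple[float, float] = (0.0, 0.0)
    t_on_ms: float = 0.0
    t_off_ms: float = 2.0

    def __post_init__(self) -> None:
        if self.t_off_ms <= self.t_on_ms:
            raise ValueError("stimulus window must have t_off > t_on")
        if self.C < 0:
            raise ValueError("stimulus profile must be nonnegative")

    def profile(self, coords: np.ndarray) -> np.ndarray:
        d2 = ((coords - np.asarray(self.center)) ** 2).sum(axis=1)
        return self.C * np.exp(-d2 / self.beta_cm2)

    def is_active(self, t_ms: float) -> bool:
        return self.t_on_ms - _T_TOL_MS <= t_ms <= self.t_off_ms + _T_TOL_MS


@dataclass
class IndicatorStimulus:
    """Applied current = amplitude on {region(x)} x [t_on, t_off] ms."""

    region: Callable[[np.ndarray], np.ndarray]
    amplitude: float = 1.0
    t_on_ms: float = 0.0
    t_off_ms: float = 5.0

    def __post_init__(self) -> None:
        if self.t_off_ms <= self.t_on_ms:
            raise ValueError("stimulus window must have t_off > t_on")
        if self.amplitude < 0:
            raise ValueError("stimulus profile must be nonnegative")

    def profile(self, coords: np.ndarray) -> np.ndarray:
        return self.amplitude * self.region(coords).astype(float)

    def is_active(self, t_ms: float) -> bool:
        return self.t_on_ms - _T_TOL_MS <= t_ms <= self.t_off_ms + _T_TOL_MS


@dataclass
class State:
    """Nodal potential u, gating w and current rescaled time t."""

    u: np.ndarray
    w: np.ndarray
    t: float = 0.0


@dataclass
class SnapshotSet:
    """Matrix of FOM states with (t, mu) column labels.

    S has shape (N, Ns) with Ns = Nt * n_params columns ordered parameter by
    parameter. ``F`` optionally stores the ionic-current vectors recorded at
    the same samples (the training data for DEIM).
    """

    S: np.ndarray
    times: np.ndarray  # (Ns,) rescaled time per column
    params: np.ndarray  # (Ns, n_mu) parameter per column
    mu_list: np.ndarray  # (n_params, n_mu) distinct parameter vectors
    n_times: int
    meta: dict = field(default_factory=dict)
    F: np.ndarray | None = None
    W: np.ndarray | None = None

    def __post_init__(self) -> None:
        if self.S.shape[1] != len(self.times) or self.S.shape[1] != len(self.params):
            raise ValueError("column labels must match snapshot count")
        if self.S.shape[1] != self.n_times * len(self.mu_list):
            raise ValueError("column count must equal Nt * n_params")
        if not np.all(np.isfinite(self.S)):
            raise ValueError("snapshot matrix contains non-finite entries")

    @property
    def n_nodes(self) -> int:
        return self.S.shape[0]

    @property
    def n_snapshots(self) -> int:
        return self.S.shape[1]

    def block(self, i: int) -> np.ndarray:
        """Trajectory (N, Nt) of the i-th parameter instance."""
        return self.S[:, i * self.n_times : (i + 1) * self.n_times]

    @staticmethod
    def concatenate(sets: Sequence["SnapshotSet"]) -> "SnapshotSet":
        first = sets[0]
        return SnapshotSet(
            S=np.concatenate([s.S for s in sets], axis=1),
            times=np.concatenate([s.times for s in sets]),
            params=np.concatenate([s.params for s in sets], axis=0),
            mu_list=np.concatenate([s.mu_list for s in sets], axis=0),
            n_times=first.n_times,
            meta=dict(first.meta),
            F=None
            if any(s.F is None for s in sets)
            else np.concatenate([s.F for s in sets], axis=1),
            W=None
            if any(s.W is None for s in sets)
            else np.concatenate([s.W for s in sets], axis=1),
        )


def assemble_operators(grid: Grid2D, cond: ConductivityModel):
    """(lumped mass diagonal, sparse stiffness) for the given conductivity."""
    return lumped_mass(grid), stiffness(grid, cond.element_tensors(grid))


class MonodomainFOM:
    """Monodomain + Aliev-Panfilov solver on one parameter instance.

    Parameters
    ----------
    grid, cond, ionic : discretization and model data.
    stimuli : list of stimulus terms (Gaussian or indicator).
    ionic_scaling : optional nodal factor rho(x) multiplying the ionic
        current (used by the ischemic scenario); default 1 everywhere.
    """

    def __init__(
        self,
        grid: Grid2D,
        cond: ConductivityModel,
        ionic: IonicParams,
        stimuli: Sequence = (),
        ionic_scaling: np.ndarray | None = None,
    ) -> None:
        self.grid = grid
        self.cond = cond
        self.ionic = ionic
        self.stimuli = list(stimuli)
        self.coords = grid.coords()
        self.mass, self.stiff = assemble_operators(grid, cond)
        if ionic_scaling is None:
            self.ionic_scaling = np.ones(grid.n_nodes)
        else:
            self.ionic_scaling = np.asarray(ionic_scaling, dtype=float)
        self._profiles = [s.profile(self.coords) for s in self.stimuli]
        self._solver = None
        self._solver_dt = None

    def applied_current(self, t: float) -> np.ndarray:
        """Nodal applied current at rescaled time t (windows given in ms)."""
        t_ms = t * TIME_SCALE_MS
        out = np.zeros(self.grid.n_nodes)
        for stim, prof in zip(self.stimuli, self._profiles):
            if stim.is_active(t_ms):
                out += prof
        return out

    def _factorize(self, dt: float) -> None:
        if self._solver is None or self._solver_dt != dt:
            system = sp.diags(self.mass / dt) + self.stiff
            self._solver = spla.splu(system.tocsc())
            self._solver_dt = dt

    def step(self, state: State, dt: float) -> State:
        """Advance one semi-implicit step."""
        self._factorize(dt)
        g = gating_rhs(state.u, state.w, self.ionic)
        w_new = state.w + dt * g
        iion = self.ionic_scaling * ionic_current(state.u, w_new, self.ionic)
        rhs = (self.mass / dt) * state.u - self.mass * iion
        iapp = self.applied_current(state.t)
        if iapp.any():
            rhs = rhs + self.mass * iapp
        u_new = self._solver.solve(rhs)
        return State(u=u_new, w=w_new, t=state.t + dt)

    def solve(
        self,
        tg: TimeGrid,
        probes: np.ndarray | None = None,
        record_ionic: bool = False,
        record_gating: bool = False,
    ) -> dict:
        """Time-march from zero initial data, sampling states at tg.

        Returns a dict with keys ``U`` (N, Nt), ``times`` (Nt,), and
        optionally ``F`` (ionic-current snapshots), ``W`` (gating
        snapshots), ``probe_traces`` (n_probes, n_steps+1) full-resolution
        traces plus ``probe_times``.
        """
        n = self.grid.n_nodes
        state = State(u=np.zeros(n), w=np.zeros(n))
        steps = tg.sample_steps()
        sample_set = {int(k): j for j, k in enumerate(steps)}
        U = np.empty((n, len(steps)))
        F = np.empty((n, len(steps))) if record_ionic else None
        Wm = np.empty((n, len(steps))) if record_gating else None
        probe_idx = None
        if probes is not None:
            probe_idx = self._nearest_nodes(np.asarray(probes, dtype=float))
            traces = np.zeros((len(probe_idx), tg.n_steps + 1))
        for k in range(1, tg.n_steps + 1):
            state = self.step(state, tg.dt)
            # recompute t from the step index so that stimulus-window tests
            # agree bit-for-bit with solvers that do not accumulate t
            state.t = k * tg.dt
            if k % _NAN_CHECK_EVERY == 0 and not np.all(np.isfinite(state.u)):
                raise FloatingPointError(f"non-finite state at step {k}")
            j = sample_set.get(k)
            if j is not None:
                U[:, j] = state.u
                if F is not None:
                    F[:, j] = self.ionic_scaling * ionic_current(
                        state.u, state.w, self.ionic
                    )
                if Wm is not None:
                    Wm[:, j] = state.w
            if probe_idx is not None:
                traces[:, k] = state.u[probe_idx]
        if not np.all(np.isfinite(state.u)):
            raise FloatingPointError("non-finite state at final step")
        out = {"U": U, "times": steps * tg.dt}
        if F is not None:
            out["F"] = F
        if Wm is not None:
            out["W"] = Wm
        if probe_idx is not None:
            out["probe_traces"] = traces
            out["probe_times"] = np.arange(tg.n_steps + 1) * tg.dt
        return out

    def _nearest_nodes(self, points: np.ndarray) -> np.ndarray:
        d2 = ((self.coords[None, :, :] - points[:, None, :]) ** 2).sum(axis=2)
        return d2.argmin(axis=1)


def solve_fom(
    scenario,
    mu: np.ndarray,
    tg: TimeGrid | None = None,
    probes: np.ndarray | None = None,
    record_ionic: bool = True,
    allow_outside_box: bool = False,
) -> SnapshotSet:
    """Run the FOM for one parameter instance of a scenario.

    Returns a single-instance SnapshotSet (with ionic snapshots attached
    when ``record_ionic``); probe traces, if requested, are stored in
    ``meta['probe_traces']`` at full time resolution.
    """
    mu = np.atleast_1d(np.asarray(mu, dtype=float))
    if not allow_outside_box and not scenario.contains(mu):
        raise ValueError(f"mu {mu} outside parameter box {scenario.param_box}")
    tg = tg or scenario.time
    fom = scenario.instantiate(mu)
    res = fom.solve(tg, probes=probes, record_ionic=record_ionic,
                    record_gating=record_ionic)
    nt = res["U"].shape[1]
    meta = {"scenario": scenario.name}
    if "probe_traces" in res:
        meta["probe_traces"] = res["probe_traces"]
        meta["probe_times"] = res["probe_times"]
    return SnapshotSet(
        S=res["U"],
        times=res["times"],
        params=np.tile(mu, (nt, 1)),
        mu_list=mu[None, :],
        n_times=nt,
        meta=meta,
        F=res.get("F"),
        W=res.get("W"),
    )
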