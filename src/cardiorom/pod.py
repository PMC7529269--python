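"""Projection-based baseline: POD, DEIM hyper-reduction, local bases.

The linear ROM approximates u(t; mu) ~ V u_n(t; mu) with V the leading
left singular vectors of the snapshot matrix, and closes the gating/ionic
terms by interpolating them at a few DEIM-selected nodes, so that the
online system never touches N-sized arrays except for on-demand
reconstruction.  Optionally the snapshots are first split into k-means
clusters and one basis/DEIM pair is built per cluster (local bases).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.linalg as la
from sklearn.base import BaseEstimator
from sklearn.cluster import KMeans

from .fom import SnapshotSet
from .grids import TimeGrid, TIME_SCALE_MS
from .ionic import gating_rhs, ionic_current


@dataclass
class PODBasis:
    """Orthonormal POD modes with the full singular spectrum retained."""

    V: np.ndarray
    singular_values: np.ndarray
    eps_pod: float | None
    n: int

    def __post_init__(self) -> None:
        if self.V.shape[1] != self.n:
            raise ValueError("retained dimension must match V")


def _fix_mode_signs(V: np.ndarray) -> np.ndarray:
    """Make the first nonzero entry of each mode positive (reproducibility)."""
    V = V.copy()
    for j in range(V.shape[1]):
        col = V[:, j]
        nz = np.nonzero(np.abs(col) > 1e-12 * np.abs(col).max())[0]
        if len(nz) and col[nz[0]] < 0:
            V[:, j] = -col
    return V


def energy_rank(singular_values: np.ndarray, eps_pod: float) -> int:
    """Smallest n with sum_{i<=n} s_i^2 / sum s_i^2 > 1 - eps_pod^2."""
    if not 0.0 < eps_pod < 1.0:
        raise ValueError("eps_pod must lie in (0, 1)")
    s2 = np.asarray(singular_values, dtype=float) ** 2
    frac = np.cumsum(s2) / s2.sum()
    n = int(np.searchsorted(frac > 1.0 - eps_pod**2, True)) + 1
    return min(n, len(s2))


def pod_basis(
    S: np.ndarray, eps_pod: float | None = None, n_fixed: int | None = None
) -> PODBasis:
    """Thin SVD of the snapshot matrix, truncated by the energy criterion.

    Exactly one of ``eps_pod`` (energy tolerance) or ``n_fixed`` (fixed
    dimension) must be given.  Mode signs follow a fixed convention (first
    nonzero entry positive).
    """
    S = np.asarray(S, dtype=float)
    if S.size == 0:
        raise ValueError("empty snapshot matrix")
    if (eps_pod is None) == (n_fixed is None):
        raise ValueError("give exactly one of eps_pod or n_fixed")
    U, s, _ = la.svd(S, full_matrices=False, lapack_driver="gesdd")
    if n_fixed is not None:
        n = min(int(n_fixed), len(s))
    else:
        n = energy_rank(s, eps_pod)
    return PODBasis(V=_fix_mode_signs(U[:, :n]), singular_values=s,
                    eps_pod=eps_pod, n=n)


def cluster_snapshots(
    S: np.ndarray, n_clusters: int, seed: int = 0, retries: int = 3
):
    """k-means over snapshot columns in state space.

    Returns (labels, centroids) with centroids of shape (Nc, N).  A single
    cluster is returned trivially for n_clusters = 1.
    """
    S = np.asarray(S, dtype=float)
    ns = S.shape[1]
    if not 1 <= n_clusters <= ns:
        raise ValueError("need 1 <= n_clusters <= number of snapshots")
    if n_clusters == 1:
        return np.zeros(ns, dtype=int), S.mean(axis=1)[None, :]
    for attempt in range(retries):
        km = KMeans(n_clusters=n_clusters, init="k-means++", n_init=10,
                    random_state=seed + attempt)
        labels = km.fit_predict(S.T)
        if len(np.unique(labels)) == n_clusters:
            return labels, km.cluster_centers_
    raise RuntimeError("k-means produced an empty cluster after retries")


@dataclass
class DEIMModel:
    """Nonlinear-term basis Phi and greedy-selected interpolation nodes."""

    Phi: np.ndarray
    indices: np.ndarray
    m: int

    def __post_init__(self) -> None:
        if len(np.unique(self.indices)) != self.m:
            raise ValueError("DEIM indices must be distinct")

    def interpolate(self, f: np.ndarray) -> np.ndarray:
        """Full-field DEIM interpolation Phi (P^T Phi)^-1 P^T f (diagnostics)."""
        c = la.solve(self.Phi[self.indices, :], f[self.indices])
        return self.Phi @ c


def deim(
    F_snapshots: np.ndarray,
    m: int | None = None,
    eps_deim: float | None = None,
) -> DEIMModel:
    """Discrete empirical interpolation of a nonlinear-term snapshot set.

    POD of the nonlinear snapshots gives Phi; the interpolation nodes are
    selected by the standard greedy residual-maximization sweep.
    """
    F = np.asarray(F_snapshots, dtype=float)
    U, s, _ = la.svd(F, full_matrices=False, lapack_driver="gesdd")
    rank = int((s > s[0] * 1e-12).sum()) if s.size else 0
    if rank == 0:
        raise ValueError("nonlinear snapshots are identically zero")
    if m is None:
        m = energy_rank(s, eps_deim) if eps_deim is not None else rank
    m = min(int(m), rank)
    Phi = _fix_mode_signs(U[:, :m])
    idx = [int(np.argmax(np.abs(Phi[:, 0])))]
    for j in range(1, m):
        c = la.solve(Phi[np.asarray(idx), :j], Phi[np.asarray(idx), j])
        r = Phi[:, j] - Phi[:, :j] @ c
        idx.append(int(np.argmax(np.abs(r))))
    return DEIMModel(Phi=Phi, indices=np.asarray(idx, dtype=int), m=m)


@dataclass
class _ClusterOps:
    """Per-cluster reduced operators prepared offline."""

    basis: PODBasis
    deim: DEIMModel
    Mr: np.ndarray  # V^T M V
    Ar: np.ndarray  # V^T A V
    W: np.ndarray  # V^T M Phi (P^T Phi)^-1   (n x m)
    B: np.ndarray  # P^T V                    (m x n)
    f_stim: list[np.ndarray]  # V^T (M * profile) per stimulus term
    rho_deim: np.ndarray  # ionic scaling at DEIM nodes
    lu: tuple = None  # factorization of (Mr/dt + Ar), set per run


@dataclass
class ROMTrajectory:
    """Reduced trajectory with on-demand reconstruction."""

    times: np.ndarray
    coords_reduced: list  # per-sample (cluster id, u_n)
    U: np.ndarray  # reconstructed states at sample times (N, Nt)
    cluster_path: np.ndarray  # active cluster per step


class PODGalerkinROM(BaseEstimator):
    """POD-Galerkin ROM with DEIM hyper-reduction and local bases.

    Follows the scikit-learn estimator protocol: hyperparameters in
    ``__init__``, data-dependent state (bases, operators) created by
    ``fit`` with trailing underscores, trajectories produced by
    ``predict``.

    Parameters
    ----------
    eps_pod : energy tolerance for the state basis (ignored if n_modes set).
    n_modes : fixed basis dimension, overrides eps_pod.
    deim_modes : DEIM dimension (None = full rank of the ionic snapshots).
    eps_deim : energy tolerance for DEIM (used when deim_modes is None).
    n_clusters : number of local bases (1 = global basis).
    cluster_stride : steps between nearest-centroid checks online.
    seed : k-means seed.
    """

    def __init__(
        self,
        eps_pod: float = 1e-3,
        n_modes: int | None = None,
        deim_modes: int | None = None,
        eps_deim: float | None = None,
        n_clusters: int = 1,
        cluster_stride: int = 1,
        seed: int = 0,
    ) -> None:
        self.eps_pod = eps_pod
        self.n_modes = n_modes
        self.deim_modes = deim_modes
        self.eps_deim = eps_deim
        self.n_clusters = n_clusters
        self.cluster_stride = cluster_stride
        self.seed = seed

    # -- offline ----------------------------------------------------------
    def fit(self, snapshots: SnapshotSet, scenario=None, mu_ref=None):
        """Build bases and reduced operators from a snapshot set.

        ``scenario`` is needed to assemble the reduced operators (mass,
        stiffness, stimulus loads); by default the operators are assembled
        at ``mu_ref`` (defaults to the box center), consistent with the
        conductivities being parameter-independent in the scenarios where
        this baseline is exercised.
        """
        if snapshots.F is None:
            raise ValueError("snapshot set must carry ionic-current snapshots")
        if scenario is None:
            raise ValueError("scenario is required to assemble reduced operators")
        self.scenario_ = scenario
        if mu_ref is None:
            mu_ref = snapshots.mu_list[0]
        fom = scenario.instantiate(np.asarray(mu_ref, dtype=float))
        labels, centroids = cluster_snapshots(
            snapshots.S, self.n_clusters, seed=self.seed
        )
        self.labels_ = labels
        self.centroids_ = centroids
        self.clusters_ = []
        M, A = fom.mass, fom.stiff
        for c in range(self.n_clusters):
            cols = labels == c
            basis = (
                pod_basis(snapshots.S[:, cols], n_fixed=self.n_modes)
                if self.n_modes is not None
                else pod_basis(snapshots.S[:, cols], eps_pod=self.eps_pod)
            )
            dm = deim(snapshots.F[:, cols], m=self.deim_modes,
                      eps_deim=self.eps_deim)
            V = basis.V
            PtPhi = dm.Phi[dm.indices, :]
            W = (V.T * M) @ dm.Phi @ la.inv(PtPhi)
            ops = _ClusterOps(
                basis=basis,
                deim=dm,
                Mr=(V.T * M) @ V,
                Ar=V.T @ (A @ V),
                W=W,
                B=V[dm.indices, :],
                f_stim=[V.T @ (M * p) for p in fom._profiles],
                rho_deim=fom.ionic_scaling[dm.indices],
            )
            self.clusters_.append(ops)
        self._stimuli_ = fom.stimuli
        self._ionic_ = fom.ionic
        self.n_nodes_ = snapshots.n_nodes
        return self

    # -- online -----------------------------------------------------------
    def _prepare_online(self, mu: np.ndarray, dt: float) -> dict:
        """Per-parameter online setup (the only N-sized work of a solve).

        The fitted bases and DEIM spaces are parameter-independent, but the
        stiffness, the ionic parameters/scaling and the stimulus loads may
        depend on mu, so they are (re)assembled and projected here, once per
        parameter instance.
        """
        from scipy.linalg import lu_factor

        fom = self.scenario_.instantiate(mu)
        prep = {"stimuli": fom.stimuli, "ionic": fom.ionic, "clusters": []}
        for ops in self.clusters_:
            V = ops.basis.V
            Ar = V.T @ (fom.stiff @ V)
            prep["clusters"].append(
                {
                    "lu": lu_factor(ops.Mr / dt + Ar),
                    "f_stim": [V.T @ (fom.mass * p) for p in fom._profiles],
                    "rho_deim": fom.ionic_scaling[ops.deim.indices],
                }
            )
        return prep

    def predict(self, mu: np.ndarray, tg: TimeGrid | None = None) -> ROMTrajectory:
        """Time-march the reduced system for one parameter instance.

        The scheme mirrors the FOM: explicit gating (advanced only at the
        active cluster's DEIM nodes, a full-length gating vector being kept
        lazily for cluster switches), implicit diffusion in the reduced
        coordinates, nodal ionic current interpolated through DEIM.  After
        the per-mu setup, each step touches only n- and m-sized arrays;
        full states are reconstructed at sample times and (with local
        bases) at cluster-switch checks.
        """
        from scipy.linalg import lu_solve

        if not hasattr(self, "clusters_"):
            raise RuntimeError("fit must be called before predict")
        scenario = self.scenario_
        mu = np.atleast_1d(np.asarray(mu, dtype=float))
        tg = tg or scenario.time
        dt = tg.dt
        prep = self._prepare_online(mu, dt)
        stimuli = prep["stimuli"]
        ionic = prep["ionic"]

        active = 0
        un = np.zeros(self.clusters_[active].basis.n)
        w_full = np.zeros(self.n_nodes_)
        steps = tg.sample_steps()
        sample_set = {int(k): j for j, k in enumerate(steps)}
        U = np.empty((self.n_nodes_, len(steps)))
        coords_reduced = [None] * len(steps)
        cluster_path = np.empty(tg.n_steps, dtype=int)

        for k in range(1, tg.n_steps + 1):
            ops = self.clusters_[active]
            onl = prep["clusters"][active]
            t_ms = (k - 1) * dt * TIME_SCALE_MS
            u_d = ops.B @ un
            w_d = w_full[ops.deim.indices]
            w_d = w_d + dt * gating_rhs(u_d, w_d, ionic)
            w_full[ops.deim.indices] = w_d
            iion = onl["rho_deim"] * ionic_current(u_d, w_d, ionic)
            rhs = (ops.Mr / dt) @ un - ops.W @ iion
            for stim, fr in zip(stimuli, onl["f_stim"]):
                if stim.is_active(t_ms):
                    rhs = rhs + fr
            un = lu_solve(onl["lu"], rhs)
            if not np.all(np.isfinite(un)):
                raise FloatingPointError(f"reduced solve diverged at step {k}")
            cluster_path[k - 1] = active
            j = sample_set.get(k)
            need_switch = self.n_clusters > 1 and (k % self.cluster_stride == 0)
            if j is not None or need_switch:
                x = ops.basis.V @ un
                if j is not None:
                    U[:, j] = x
                    coords_reduced[j] = (active, un.copy())
                if need_switch:
                    d2 = ((self.centroids_ - x[None, :]) ** 2).sum(axis=1)
                    new = int(d2.argmin())
                    if new != active:
                        active = new
                        un = self.clusters_[active].basis.V.T @ x
        return ROMTrajectory(
            times=steps * dt,
            coords_reduced=coords_reduced,
            U=U,
            cluster_path=cluster_path,
        )

    # -- persistence -------------------------------------------------------
    def save(self, path) -> None:
        """Archive bases, DEIM data and reduced operators to HDF5.

        The scenario itself is stored as its config; ``load`` rebuilds it
        through the preset registry.
        """
        import json

        import h5py

        with h5py.File(path, "w") as f:
            for k, ops in enumerate(self.clusters_):
                grp = f.create_group(f"clusters/{k}")
                grp.create_dataset("V", data=ops.basis.V)
                grp.create_dataset("singular_values",
                                   data=ops.basis.singular_values)
                grp.create_dataset("Phi", data=ops.deim.Phi)
                grp.create_dataset("indices", data=ops.deim.indices)
                red = grp.create_group("reduced_ops")
                red.create_dataset("Mr", data=ops.Mr)
                red.create_dataset("Ar", data=ops.Ar)
                red.create_dataset("W", data=ops.W)
                red.create_dataset("B", data=ops.B)
                for i, fs in enumerate(ops.f_stim):
                    red.create_dataset(f"f_stim_{i}", data=fs)
                red.create_dataset("rho_deim", data=ops.rho_deim)
            f.create_dataset("centroids", data=self.centroids_)
            f.create_dataset("labels", data=self.labels_)
            f.attrs["meta"] = json.dumps(
                {
                    "params": self.get_params(),
                    "scenario_config": self.scenario_.to_config(),
                    "n_nodes": self.n_nodes_,
                }
            )

    @classmethod
    def load(cls, path) -> "PODGalerkinROM":
        import json

        import h5py

        from .scenarios import get_scenario

        with h5py.File(path, "r") as f:
            meta = json.loads(f.attrs["meta"])
            rom = cls(**meta["params"])
            sc_cfg = meta["scenario_config"]
            scenario = get_scenario(sc_cfg["preset"],
                                    **sc_cfg.get("overrides", {}))
            rom.scenario_ = scenario
            rom.centroids_ = f["centroids"][...]
            rom.labels_ = f["labels"][...]
            rom.n_nodes_ = meta["n_nodes"]
            rom.clusters_ = []
            for k in range(len(f["clusters"])):
                grp = f[f"clusters/{k}"]
                V = grp["V"][...]
                s = grp["singular_values"][...]
                indices = grp["indices"][...]
                red = grp["reduced_ops"]
                n_stim = sum(1 for key in red if key.startswith("f_stim_"))
                ops = _ClusterOps(
                    basis=PODBasis(V=V, singular_values=s,
                                   eps_pod=rom.eps_pod, n=V.shape[1]),
                    deim=DEIMModel(Phi=grp["Phi"][...], indices=indices,
                                   m=len(indices)),
                    Mr=red["Mr"][...],
                    Ar=red["Ar"][...],
                    W=red["W"][...],
                    B=red["B"][...],
                    f_stim=[red[f"f_stim_{i}"][...] for i in range(n_stim)],
                    rho_deim=red["rho_deim"][...],
                )
                rom.clusters_.append(ops)
        return rom
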