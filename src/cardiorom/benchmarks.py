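"""Desk-scale benchmark studies.

These are the package's standard self-checks, shared by the test suite and
the acceptance script: each runs in minutes on one CPU by construction
(coarsened grids, shortened windows, reduced epoch budgets), while keeping
the physics and the algorithms identical to the full presets.

Problem sizes used here:

* dt self-convergence: 17 x 17 ischemic slab, T = 30 ms, dt in
  {0.4, 0.2, 0.1, 0.05} / 12.9;
* conduction-velocity anisotropy: 97 x 97 slab, planar waves along and
  across the fibers, probes 4 cm apart on the centerline;
* POD reproduction/tolerance sweep: 32 x 32 ischemic slab, T = 100 ms,
  every step stored (1000 snapshots);
* toy manifold: separable field u(t; mu) = sin(pi t) mu phi(x) on a
  16 x 16 grid, latent dimension 2 (= number of parameters + time);
* mini comparison: the ``test1-mini`` preset (32 x 32, 9 training / 4
  testing scar locations, 200 stored snapshots) with latent dimension 3
  for both ROMs.
"""

from __future__ import annotations

import numpy as np

from .config import generate_snapshots
from .dlrom import DLROM
from .fom import ConductivityModel, IndicatorStimulus, MonodomainFOM, SnapshotSet
from .grids import Grid2D, TimeGrid
from .ionic import IonicParams
from .metrics import activation_map, eps_rel
from .pod import PODGalerkinROM
from .scenarios import get_scenario

_TEST1_IONIC = IonicParams(K=8.0, a=0.01, b=0.15, eps0=0.002, c1=0.2, c2=0.3)


def dt_convergence_order(
    dts: tuple[float, ...] = (0.2 / 12.9, 0.1 / 12.9, 0.05 / 12.9,
                              0.025 / 12.9),
    T_ms: float = 30.0,
    nx: int = 17,
) -> float:
    """Observed order of the time stepper from successive refinements.

    Runs the ischemic mini slab at a sequence of halved steps and fits the
    log-log slope of || u(dt_i) - u(dt_{i+1}) || at the final time against
    dt_i; the scheme is first order, so the slope should be near 1.  A
    broad stimulus (beta = 2 cm^2) is used so the excitation is resolved
    on the coarse grid and the asymptotic-in-dt regime is reached; a
    near-point source on a 17 x 17 grid sits at the propagation threshold,
    where the front position responds discontinuously to dt.
    """
    sc = get_scenario("test1-mini", nx=nx, ny=nx, T_ms=T_ms, n_snapshots=10,
                      beta_cm2=2.0, C=50.0)
    mu = np.array([5.0, 5.0])
    finals = []
    for dt in dts:
        tg = TimeGrid(dt=dt, T_ms=T_ms, n_snapshots=1)
        finals.append(solve_final(sc, mu, tg))
    errs = [np.linalg.norm(a - b) for a, b in zip(finals[:-1], finals[1:])]
    slope, _ = np.polyfit(np.log(dts[:-1]), np.log(errs), 1)
    return float(slope)


def solve_final(scenario, mu, tg) -> np.ndarray:
    from .fom import solve_fom

    return solve_fom(scenario, mu, tg=tg, record_ionic=False).S[:, -1]


def planar_wave_speed(direction: str, n: int = 97, sigma_l: float = 12.9 * 0.2,
                      sigma_t: float = 12.9 * 0.1) -> float:
    """Conduction velocity (cm/ms) of a planar wave along x or y.

    A strip stimulus on one edge launches a planar front; the velocity is
    measured from linearly-interpolated activation times at two probes
    4 cm apart on the centerline, away from boundary and stimulus
    transients.
    """
    grid = Grid2D(n, n, 10.0, 10.0)
    cond = ConductivityModel(sigma_l=sigma_l, sigma_t=sigma_t,
                             f0=np.array([1.0, 0.0]))
    axis = 0 if direction == "x" else 1
    stim = IndicatorStimulus(
        region=lambda xy: xy[:, axis] <= 0.3,
        amplitude=50.0, t_on_ms=0.0, t_off_ms=2.0,
    )
    fom = MonodomainFOM(grid, cond, _TEST1_IONIC, [stim])
    tg = TimeGrid(dt=0.1 / 12.9, T_ms=40.0, n_snapshots=200)
    res = fom.solve(tg)
    act = activation_map(res["U"], res["times"])
    coords = grid.coords()
    other = 1 - axis
    t_probe = []
    for pos in (3.0, 7.0):
        idx = np.argmin((coords[:, axis] - pos) ** 2
                        + (coords[:, other] - 5.0) ** 2)
        t_probe.append(act.times_ms[idx])
    if not np.all(np.isfinite(t_probe)):
        raise RuntimeError("wave did not reach the probes")
    return 4.0 / (t_probe[1] - t_probe[0])


def anisotropy_ratio(n: int = 97) -> float:
    """CV along fibers / CV across fibers; ~ sqrt(sigma_l / sigma_t)."""
    return planar_wave_speed("x", n) / planar_wave_speed("y", n)


def pod_reproduction_snapshots() -> tuple:
    """Dense-in-time single-run snapshots for the reproduction study."""
    sc = get_scenario("test1-mini", T_ms=100.0, n_snapshots=1000)
    mu = np.array([5.0, 5.0])
    from .fom import solve_fom

    return sc, mu, solve_fom(sc, mu)


def pod_reproduction_error(sc=None, mu=None, snaps=None,
                           eps_pod: float = 1e-6) -> float:
    """Relative error of the POD-Galerkin ROM on its own training run.

    With a near-lossless basis (every visited state stored and eps_pod
    small) the online trajectory must reproduce the FOM to well below
    1e-3; this exercises the whole offline/online chain.
    """
    if snaps is None:
        sc, mu, snaps = pod_reproduction_snapshots()
    rom = PODGalerkinROM(eps_pod=eps_pod)
    rom.fit(snaps, scenario=sc)
    traj = rom.predict(mu, sc.time)
    return eps_rel(snaps.S, traj.U)


def pod_tolerance_sweep(
    eps_values: tuple[float, ...] = (1e-2, 1e-3, 1e-4),
    sc=None, mu=None, snaps=None,
) -> dict[float, float]:
    """eps_rel of the POD ROM at a sequence of energy tolerances."""
    if snaps is None:
        sc, mu, snaps = pod_reproduction_snapshots()
    out = {}
    for ep in eps_values:
        rom = PODGalerkinROM(eps_pod=ep)
        rom.fit(snaps, scenario=sc)
        out[ep] = eps_rel(snaps.S, rom.predict(mu, sc.time).U)
    return out


def toy_manifold_snapshots(
    mus: tuple[float, ...] = (1.0, 1.25, 1.5, 1.75, 2.0),
    n_times: int = 50,
    side: int = 16,
) -> tuple[SnapshotSet, np.ndarray, np.ndarray]:
    """Separable two-parameter field u(t; mu) = sin(pi t) mu phi(x).

    The solution manifold has intrinsic dimension 2 (time + one
    parameter), so a latent dimension n = 2 suffices for the DL-ROM.
    Returns (snapshots, times, phi).
    """
    x = np.linspace(0.0, 1.0, side)
    X, Y = np.meshgrid(x, x)
    phi = np.exp(-((X - 0.5) ** 2 + (Y - 0.5) ** 2) / 0.1).ravel()
    times = np.linspace(0.0, 1.0, n_times)
    cols, tl, pl = [], [], []
    for mu in mus:
        for t in times:
            cols.append(np.sin(np.pi * t) * mu * phi)
            tl.append(t)
            pl.append([mu])
    snaps = SnapshotSet(
        S=np.array(cols).T,
        times=np.array(tl),
        params=np.array(pl),
        mu_list=np.asarray(mus)[:, None],
        n_times=n_times,
        meta={"scenario": "toy-manifold"},
    )
    return snaps, times, phi


def toy_dlrom_benchmark(seed: int = 1, max_epochs: int = 400) -> dict:
    """Train an n=2 DL-ROM on the toy manifold and test on held-out mu.

    Returns the trained estimator and the test-set eps_rel; the latent
    dimension equals the intrinsic dimension of the manifold.
    """
    snaps, times, phi = toy_manifold_snapshots()
    test_mus = (1.125, 1.375, 1.625, 1.875)
    est = DLROM(
        n=2, conv_channels=(4, 8), kernel=5, stride=2,
        dfnn_hidden=(50, 50, 50), lr=1e-3, batch_size=32,
        max_epochs=max_epochs, patience=max_epochs, seed=seed,
    )
    est.fit(snaps)
    truth = [np.outer(phi, np.sin(np.pi * times) * mu) for mu in test_mus]
    preds = [est.predict(times, np.array([mu])).T for mu in test_mus]
    return {"eps_rel": eps_rel(truth, preds), "estimator": est,
            "times": times, "test_mus": test_mus}


def mini_comparison(seed: int = 1, max_epochs: int = 150,
                    snaps=None, truth=None) -> dict:
    """DL-ROM vs equal-dimension POD-Galerkin ROM on ``test1-mini``.

    Both reduced models use dimension n = 3 (= n_mu + 1, the intrinsic
    dimension of the ischemic scenario); the expected outcome is the
    accuracy ordering DL-ROM << POD at equal n, since travelling fronts
    are poorly captured by three linear modes.
    """
    sc = get_scenario("test1-mini")
    pg = sc.parameter_grid()
    if snaps is None:
        snaps = generate_snapshots(sc, pg.train)
    if truth is None:
        from .fom import solve_fom

        truth = [solve_fom(sc, mu, record_ionic=False).S for mu in pg.test]
    pod = PODGalerkinROM(n_modes=3, deim_modes=60)
    pod.fit(snaps, scenario=sc)
    pod_preds = [pod.predict(mu).U for mu in pg.test]
    est = DLROM(
        n=3, conv_channels=(4, 8, 16), kernel=5, stride=2,
        dfnn_hidden=(50, 50, 50, 50), lr=1e-3, batch_size=40,
        max_epochs=max_epochs, patience=max_epochs, seed=seed,
    )
    est.fit(snaps)
    times = sc.time.sample_times()
    dl_preds = [est.predict(times, mu).T for mu in pg.test]
    return {
        "pod_eps_rel": eps_rel(truth, pod_preds),
        "dlrom_eps_rel": eps_rel(truth, dl_preds),
        "scenario": sc,
        "snapshots": snaps,
        "truth": truth,
        "estimator": est,
    }
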