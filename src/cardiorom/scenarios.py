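"""Parametrized study scenarios on 2D tissue slabs.

Three families are provided, each as a preset with desk-scale "mini"
variants (coarser grid, fewer parameter instances, fewer stored
snapshots) for quick experiments:

* ``test1``  — 10 cm slab with a smooth non-conductive (ischemic) region
  whose center (mu1, mu2) is the parameter; Gaussian stimulus at the
  origin.
* ``test2``  — 2 cm slab where an S1-S2 stimulation protocol elicits a
  figure-of-eight re-entry; the parameter is the y-coordinate of the S2
  disk.  Variants: ``full`` (re-entry and non-re-entry, mu in [0.5, 1.1])
  and ``reentry_only`` (mu in [0.8, 1.1]).
* ``test4``  — 10 cm slab with parametrized longitudinal/transversal
  conductivities (mu1, mu2) and restitution coefficient mu3 replacing c1
  in the gating rate.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np

from .fom import ConductivityModel, GaussianStimulus, IndicatorStimulus, MonodomainFOM
from .grids import Grid2D, TimeGrid
from .ionic import IonicParams


def ischemic_modulation(
    x: np.ndarray, mu: Sequence[float], alpha: float = 7.0, sigma0: float = 1e-4
):
    """Smooth scar factor of the ischemic slab.

    rho(x; mu) = 1 - exp(-((x1-mu1)^4 + (x2-mu2)^4) / (2 alpha^2)) vanishes
    at the scar center and tends to 1 in healthy tissue; the conductivity
    factor sigma = rho + sigma0 (1 - rho) floors at sigma0 so the scar core
    is non-conductive but the operator stays definite.  rho also multiplies
    the ionic current (no active kinetics inside the scar).

    Returns (rho, sigma); x may be (2,) or (N, 2).
    """
    if alpha <= 0:
        raise ValueError("alpha must be positive")
    x = np.asarray(x, dtype=float)
    mu1, mu2 = float(mu[0]), float(mu[1])
    x1 = x[..., 0]
    x2 = x[..., 1]
    rho = 1.0 - np.exp(-((x1 - mu1) ** 4 + (x2 - mu2) ** 4) / (2.0 * alpha**2))
    sigma = rho + sigma0 * (1.0 - rho)
    return rho, sigma


@dataclass
class ParameterGrid:
    """Training and testing parameter instances (disjoint, inside the box)."""

    train: np.ndarray
    test: np.ndarray

    def __post_init__(self) -> None:
        self.train = np.atleast_2d(np.asarray(self.train, dtype=float))
        self.test = np.atleast_2d(np.asarray(self.test, dtype=float))
        for a in self.train:
            for b in self.test:
                if np.allclose(a, b):
                    raise ValueError("train and test parameter sets overlap")


def _lattice(starts, steps, counts) -> np.ndarray:
    axes = [s0 + st * np.arange(c) for s0, st, c in zip(starts, steps, counts)]
    mesh = np.meshgrid(*axes, indexing="ij")
    return np.column_stack([m.ravel() for m in mesh])


def make_parameter_grid(box: np.ndarray, spec: dict) -> np.ndarray:
    """Deterministic parameter sets inside an axis-aligned box.

    ``spec`` selects the construction:
      - {"kind": "lattice", "starts": [...], "steps": [...], "counts": [...]}
      - {"kind": "uniform", "n": int}          (uniformly spaced, 1D box)
      - {"kind": "midpoints", "of": points}    (midpoints of consecutive rows)
      - {"kind": "random", "n": int, "seed": int}
    """
    box = np.atleast_2d(np.asarray(box, dtype=float))
    kind = spec["kind"]
    if kind == "lattice":
        pts = _lattice(spec["starts"], spec["steps"], spec["counts"])
    elif kind == "uniform":
        if box.shape[0] != 1:
            raise ValueError("uniform spacing spec is for 1D parameter boxes")
        pts = np.linspace(box[0, 0], box[0, 1], spec["n"])[:, None]
    elif kind == "midpoints":
        of = np.atleast_2d(np.asarray(spec["of"], dtype=float))
        pts = 0.5 * (of[:-1] + of[1:])
    elif kind == "random":
        rng = np.random.default_rng(spec["seed"])
        pts = box[:, 0] + (box[:, 1] - box[:, 0]) * rng.random(
            (spec["n"], box.shape[0])
        )
    else:
        raise ValueError(f"unknown parameter grid kind {kind!r}")
    inside = np.all((pts >= box[:, 0] - 1e-9) & (pts <= box[:, 1] + 1e-9), axis=1)
    if not inside.all():
        raise ValueError("parameter grid contains points outside the box")
    return pts


@dataclass
class Scenario:
    """Bundle of grid, time grid, parameter box and mu-dependent builders."""

    name: str
    grid: Grid2D
    time: TimeGrid
    param_box: np.ndarray
    ionic_builder: Callable[[np.ndarray], IonicParams]
    conductivity_builder: Callable[[np.ndarray, Grid2D], ConductivityModel]
    stimulus_builder: Callable[[np.ndarray], list]
    ionic_scaling_builder: Callable[[np.ndarray, Grid2D], np.ndarray | None] = (
        lambda mu, grid: None
    )
    train_params: np.ndarray | None = None
    test_params: np.ndarray | None = None
    config: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.param_box = np.atleast_2d(np.asarray(self.param_box, dtype=float))

    @property
    def n_mu(self) -> int:
        return self.param_box.shape[0]

    def contains(self, mu: np.ndarray) -> bool:
        mu = np.atleast_1d(np.asarray(mu, dtype=float))
        return bool(
            np.all(mu >= self.param_box[:, 0] - 1e-9)
            and np.all(mu <= self.param_box[:, 1] + 1e-9)
        )

    def instantiate(self, mu: np.ndarray) -> MonodomainFOM:
        mu = np.atleast_1d(np.asarray(mu, dtype=float))
        return MonodomainFOM(
            grid=self.grid,
            cond=self.conductivity_builder(mu, self.grid),
            ionic=self.ionic_builder(mu),
            stimuli=self.stimulus_builder(mu),
            ionic_scaling=self.ionic_scaling_builder(mu, self.grid),
        )

    def parameter_grid(self) -> ParameterGrid:
        if self.train_params is None or self.test_params is None:
            raise ValueError(f"scenario {self.name} has no default parameter grids")
        return ParameterGrid(train=self.train_params, test=self.test_params)

    def to_config(self) -> dict:
        return copy.deepcopy(self.config)


# --------------------------------------------------------------------------
# Test 1: ischemic slab
# --------------------------------------------------------------------------

_TEST1_IONIC = dict(K=8.0, a=0.01, b=0.15, eps0=0.002, c1=0.2, c2=0.3)
_TEST1_DEFAULTS = dict(
    nx=64,
    ny=64,
    L=10.0,
    dt=0.1 / 12.9,
    T_ms=400.0,
    n_snapshots=1000,
    sigma_l=12.9 * 0.2,
    sigma_t=12.9 * 0.1,
    alpha=7.0,
    sigma0=1e-4,
    C=100.0,
    beta_cm2=0.02,
    t_stim_ms=2.0,
    box=[[3.5, 6.5], [3.5, 6.5]],
    train_spec={"kind": "lattice", "starts": [3.5, 3.5], "steps": [0.5, 0.5],
                "counts": [7, 7]},
    test_spec={"kind": "lattice", "starts": [3.75, 3.75], "steps": [0.5, 0.5],
               "counts": [6, 6]},
)
_TEST1_MINI = dict(
    nx=32,
    ny=32,
    n_snapshots=200,
    train_spec={"kind": "lattice", "starts": [3.5, 3.5], "steps": [1.5, 1.5],
                "counts": [3, 3]},
    test_spec={"kind": "lattice", "starts": [4.25, 4.25], "steps": [1.5, 1.5],
               "counts": [2, 2]},
)


def build_test1(**overrides) -> Scenario:
    """Ischemic-slab scenario; ``overrides`` replace any default entry."""
    cfg = {**_TEST1_DEFAULTS, **overrides}
    grid = Grid2D(cfg["nx"], cfg["ny"], cfg["L"], cfg["L"])
    tg = TimeGrid(dt=cfg["dt"], T_ms=cfg["T_ms"], n_snapshots=cfg["n_snapshots"])
    box = np.asarray(cfg["box"], dtype=float)
    ionic = IonicParams(**_TEST1_IONIC)

    def cond_builder(mu, grid):
        _, sigma = ischemic_modulation(grid.coords(), mu, cfg["alpha"], cfg["sigma0"])
        return ConductivityModel(
            sigma_l=cfg["sigma_l"], sigma_t=cfg["sigma_t"],
            f0=np.array([1.0, 0.0]), modulation=sigma,
        )

    def scaling_builder(mu, grid):
        rho, _ = ischemic_modulation(grid.coords(), mu, cfg["alpha"], cfg["sigma0"])
        return rho

    def stim_builder(mu):
        return [GaussianStimulus(C=cfg["C"], beta_cm2=cfg["beta_cm2"],
                                 center=(0.0, 0.0), t_on_ms=0.0,
                                 t_off_ms=cfg["t_stim_ms"])]

    return Scenario(
        name=cfg.get("name", "test1"),
        grid=grid,
        time=tg,
        param_box=box,
        ionic_builder=lambda mu: ionic,
        conductivity_builder=cond_builder,
        stimulus_builder=stim_builder,
        ionic_scaling_builder=scaling_builder,
        train_params=make_parameter_grid(box, cfg["train_spec"]),
        test_params=make_parameter_grid(box, cfg["test_spec"]),
        config={"preset": cfg.get("name", "test1"), "overrides": {k: v for k, v in overrides.items() if k != "name"}},
    )


# --------------------------------------------------------------------------
# Test 2: S1-S2 re-entry
# --------------------------------------------------------------------------

_TEST2_IONIC = dict(K=8.0, a=0.1, b=0.1, eps0=0.01, c1=0.14, c2=0.3)
_TEST2_DEFAULTS = dict(
    nx=256,
    ny=256,
    L=2.0,
    dt=0.2 / 12.9,
    T_ms=175.0,
    t_start_ms=95.0,
    n_snapshots=400,
    sigma_l=2e-3,
    sigma_t=3.1e-4,
    s1_width=0.1,
    s1_window=(0.0, 5.0),
    s2_center_x=1.0,
    s2_radius=0.2,
    s2_window=(70.0, 75.0),
    n_train=13,
)
_TEST2_MINI = dict(nx=64, ny=64, n_snapshots=100, n_train=5)


def build_test2(variant: str = "full", **overrides) -> Scenario:
    """S1-S2 re-entry scenario.

    ``variant`` selects the parameter space: "full" spans re-entry and
    non-re-entry dynamics (mu in [0.5, 1.1] cm), "reentry_only" restricts
    to [0.8, 1.1] cm.
    """
    if variant not in ("full", "reentry_only"):
        raise ValueError("variant must be 'full' or 'reentry_only'")
    cfg = {**_TEST2_DEFAULTS, **overrides}
    box = np.array([[0.5, 1.1]]) if variant == "full" else np.array([[0.8, 1.1]])
    if "box" in cfg:
        box = np.atleast_2d(np.asarray(cfg["box"], dtype=float))
    grid = Grid2D(cfg["nx"], cfg["ny"], cfg["L"], cfg["L"])
    tg = TimeGrid(dt=cfg["dt"], T_ms=cfg["T_ms"], n_snapshots=cfg["n_snapshots"],
                  t_start_ms=cfg["t_start_ms"])
    ionic = IonicParams(**_TEST2_IONIC)
    cond = ConductivityModel(sigma_l=cfg["sigma_l"], sigma_t=cfg["sigma_t"],
                             f0=np.array([1.0, 0.0]))

    def stim_builder(mu):
        mu0 = float(np.atleast_1d(mu)[0])
        s1 = IndicatorStimulus(
            region=lambda xy: xy[:, 1] <= cfg["s1_width"] + 1e-12,
            amplitude=1.0,
            t_on_ms=cfg["s1_window"][0],
            t_off_ms=cfg["s1_window"][1],
        )
        cx, r = cfg["s2_center_x"], cfg["s2_radius"]
        s2 = IndicatorStimulus(
            region=lambda xy: (xy[:, 0] - cx) ** 2 + (xy[:, 1] - mu0) ** 2
            <= r**2 + 1e-12,
            amplitude=1.0,
            t_on_ms=cfg["s2_window"][0],
            t_off_ms=cfg["s2_window"][1],
        )
        return [s1, s2]

    train = make_parameter_grid(box, {"kind": "uniform", "n": cfg["n_train"]})
    test = make_parameter_grid(box, {"kind": "midpoints", "of": train})
    name = cfg.get("name", "test2-full" if variant == "full" else "test2-reentry")
    return Scenario(
        name=name,
        grid=grid,
        time=tg,
        param_box=box,
        ionic_builder=lambda mu: ionic,
        conductivity_builder=lambda mu, grid: cond,
        stimulus_builder=stim_builder,
        train_params=train,
        test_params=test,
        config={"preset": name, "variant": variant, "overrides": {k: v for k, v in overrides.items() if k != "name"}},
    )


# --------------------------------------------------------------------------
# Test 4: conductivity + restitution variability
# --------------------------------------------------------------------------

_TEST4_DEFAULTS = dict(
    nx=64,
    ny=64,
    L=10.0,
    dt=0.1 / 12.9,
    T_ms=400.0,
    n_snapshots=1000,
    C=100.0,
    beta_cm2=0.02,
    t_stim_ms=2.0,
    n_test=16,
)
_TEST4_MINI = dict(
    nx=32,
    ny=32,
    n_snapshots=200,
    train_counts=[2, 2, 2],
    n_test=4,
)


def build_test4(**overrides) -> Scenario:
    """Slab with parametrized conductivities (mu1, mu2) and restitution mu3.

    The tensor is D = mu2 I + (mu1 - mu2) f0 f0^T with fibers along x, and
    mu3 replaces the restitution coefficient c1 in the gating rate.  The
    printed test lattice enumerates 4 x 4 x 4 = 64 points while the study
    uses 16 test instances; the first ``n_test`` lattice points in
    lexicographic order are taken (configurable).
    """
    cfg = {**_TEST4_DEFAULTS, **overrides}
    grid = Grid2D(cfg["nx"], cfg["ny"], cfg["L"], cfg["L"])
    tg = TimeGrid(dt=cfg["dt"], T_ms=cfg["T_ms"], n_snapshots=cfg["n_snapshots"])
    box = np.array(
        [
            [12.9 * 0.06, 12.9 * 0.2],
            [12.9 * 0.03, 12.9 * 0.1],
            [0.15, 0.25],
        ]
    )
    base = dict(K=8.0, a=0.01, b=0.15, eps0=0.002, c1=0.2, c2=0.3)

    def ionic_builder(mu):
        return IonicParams(**{**base, "c1": float(mu[2])})

    def cond_builder(mu, grid):
        m1, m2 = float(mu[0]), float(mu[1])
        # D = m2 I + (m1 - m2) f0 f0^T.  When m1 < m2 the same tensor is
        # sigma_l = m2 across x, i.e. fibers rotated 90 degrees, which keeps
        # the sigma_l >= sigma_t representation exact.
        if m1 >= m2:
            return ConductivityModel(sigma_l=m1, sigma_t=m2,
                                     f0=np.array([1.0, 0.0]))
        return ConductivityModel(sigma_l=m2, sigma_t=m1, f0=np.array([0.0, 1.0]))

    def stim_builder(mu):
        return [GaussianStimulus(C=cfg["C"], beta_cm2=cfg["beta_cm2"],
                                 center=(0.0, 0.0), t_on_ms=0.0,
                                 t_off_ms=cfg["t_stim_ms"])]

    counts = cfg.get("train_counts", [5, 5, 5])
    steps = [(box[d, 1] - box[d, 0]) / (c - 1) if c > 1 else 0.0
             for d, c in enumerate(counts)]
    train = make_parameter_grid(
        box, {"kind": "lattice", "starts": box[:, 0], "steps": steps,
              "counts": counts}
    )
    test_full = _lattice(
        starts=[12.9 * 0.0775, 12.9 * 0.0387, 0.1625],
        steps=[12.9 * 0.035, 12.9 * 0.0175, 0.025],
        counts=[4, 4, 4],
    )
    test = test_full[: cfg["n_test"]]
    return Scenario(
        name=cfg.get("name", "test4"),
        grid=grid,
        time=tg,
        param_box=box,
        ionic_builder=ionic_builder,
        conductivity_builder=cond_builder,
        stimulus_builder=stim_builder,
        train_params=train,
        test_params=test,
        config={"preset": cfg.get("name", "test4"), "overrides": {k: v for k, v in overrides.items() if k != "name"}},
    )


PRESETS: dict[str, Callable[..., Scenario]] = {
    "test1": lambda **ov: build_test1(**ov),
    "test1-mini": lambda **ov: build_test1(**{**_TEST1_MINI, "name": "test1-mini",
                                              **ov}),
    "test2-full": lambda **ov: build_test2("full", **ov),
    "test2-reentry": lambda **ov: build_test2("reentry_only", **ov),
    "test2-mini": lambda **ov: build_test2(
        "reentry_only", **{**_TEST2_MINI, "name": "test2-mini", **ov}
    ),
    "test4": lambda **ov: build_test4(**ov),
    "test4-mini": lambda **ov: build_test4(**{**_TEST4_MINI, "name": "test4-mini",
                                              **ov}),
}


def get_scenario(name: str, **overrides) -> Scenario:
    """Build a preset scenario by name, applying overrides."""
    if name not in PRESETS:
        raise KeyError(
            f"unknown scenario {name!r}; available presets: {sorted(PRESETS)}"
        )
    return PRESETS[name](**overrides)
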