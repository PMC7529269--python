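"""Aliev-Panfilov ionic model.

The two-variable phenomenological model couples the dimensionless
transmembrane potential u with a recovery (gating) variable w:

    I_ion(u, w) = K u (u - a)(u - 1) + u w
    g(u, w)     = (eps0 + c1 w / (c2 + u)) (-w - K u (u - b - 1))

Sign convention (stated here once, used consistently by the solvers and
asserted in the tests): the gating variable evolves as  dw/dt = g(u, w)
with g as written above.  This is the classical Aliev-Panfilov recovery
law: w decays at rest (dw/dt = -eps w for u = 0) and rises during the
plateau, which is what produces repolarization and refractoriness.  The
opposite sign would freeze the tissue in the excited state and no
re-entry could be sustained.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .grids import TIME_SCALE_MS, V_REST_MV, V_SCALE_MV

#: Smallest allowed magnitude of c2 + u before the gating rate is considered
#: singular. The guard exists because c2 + u appears in a denominator.
_DENOM_GUARD = 1e-8


@dataclass(frozen=True)
class IonicParams:
    """Dimensionless Aliev-Panfilov constants.

    a is the excitation threshold; c1 and c2 shape the restitution
    behaviour through the weighting factor eps0 + c1 w / (c2 + u).
    """

    K: float
    a: float
    b: float
    eps0: float
    c1: float
    c2: float

    def __post_init__(self) -> None:
        vals = (self.K, self.a, self.b, self.eps0, self.c1, self.c2)
        if not all(np.isfinite(v) for v in vals):
            raise ValueError("ionic parameters must be finite")
        if self.K <= 0:
            raise ValueError("K must be positive")


def ionic_current(u: np.ndarray, w: np.ndarray, p: IonicParams) -> np.ndarray:
    """Elementwise ionic current K u (u - a)(u - 1) + u w."""
    u = np.asarray(u, dtype=float)
    w = np.asarray(w, dtype=float)
    if u.shape != w.shape:
        raise ValueError(f"shape mismatch: u {u.shape} vs w {w.shape}")
    return p.K * u * (u - p.a) * (u - 1.0) + u * w


def gating_rhs(u: np.ndarray, w: np.ndarray, p: IonicParams) -> np.ndarray:
    """Elementwise recovery rate g(u, w); the gating ODE is dw/dt = g(u, w)."""
    u = np.asarray(u, dtype=float)
    w = np.asarray(w, dtype=float)
    if u.shape != w.shape:
        raise ValueError(f"shape mismatch: u {u.shape} vs w {w.shape}")
    denom = p.c2 + u
    if np.any(np.abs(denom) < _DENOM_GUARD):
        raise FloatingPointError("c2 + u too close to zero in gating rate")
    return (p.eps0 + p.c1 * w / denom) * (-w - p.K * u * (u - p.b - 1.0))


def to_dimensional(u: np.ndarray | float, t: np.ndarray | float):
    """Map dimensionless (u, t) to (u in mV, t in ms)."""
    return V_SCALE_MV * np.asarray(u) + V_REST_MV, TIME_SCALE_MS * np.asarray(t)


def potential_to_mv(u: np.ndarray | float) -> np.ndarray:
    return V_SCALE_MV * np.asarray(u) + V_REST_MV


def time_to_ms(t: np.ndarray | float) -> np.ndarray:
    return TIME_SCALE_MS * np.asarray(t)
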