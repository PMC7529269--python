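"""Error indicators and clinical outputs (activation maps, APD).

Three indicators are used to compare ROM against FOM trajectories:

* ``eps_rel``  — scalar: mean over test instances of
  sqrt(sum_k ||u^k - u~^k||^2 / sum_k ||u^k||^2);
* ``eps_k``    — per-node field at time k:
  |u^k - u~^k| / ((1/Nt) sum_k ||u^k||_2);
* ``eps_ks``   — per-node percent field at time k:
  |u^k - u~^k| / ||u^k||_1 * 100.

Activation time is the first upward threshold crossing of u (linearly
interpolated between samples, reported in ms); APD is the total
dimensional time spent above the threshold.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .grids import TIME_SCALE_MS

#: Default dimensionless threshold for activation/APD (~ -30 mV).
DEFAULT_THRESHOLD = 0.5
#: Sentinel for nodes that never cross the threshold.
UNACTIVATED = np.nan


@dataclass
class ErrorReport:
    """Summary of the scalar indicator over a test set."""

    eps_rel: float
    per_instance: np.ndarray
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.eps_rel < 0 or np.any(self.per_instance < 0):
            raise ValueError("error indicators must be nonnegative")


def eps_rel(
    U_true: Sequence[np.ndarray] | np.ndarray,
    U_pred: Sequence[np.ndarray] | np.ndarray,
) -> float:
    """Mean over instances of the time-aggregated relative 2-norm error.

    Inputs are per-instance trajectories of shape (N, Nt); a single
    (N, Nt) array is treated as one instance.
    """
    if isinstance(U_true, np.ndarray) and U_true.ndim == 2:
        U_true, U_pred = [U_true], [U_pred]
    vals = []
    for ut, up in zip(U_true, U_pred, strict=True):
        ut = np.asarray(ut, dtype=float)
        up = np.asarray(up, dtype=float)
        if ut.shape != up.shape:
            raise ValueError("trajectory shapes differ")
        denom = (ut**2).sum()
        if denom == 0:
            raise ZeroDivisionError("zero-norm truth trajectory")
        vals.append(np.sqrt(((ut - up) ** 2).sum() / denom))
    return float(np.mean(vals))


def error_report(U_true, U_pred, **meta) -> ErrorReport:
    if isinstance(U_true, np.ndarray) and U_true.ndim == 2:
        U_true, U_pred = [U_true], [U_pred]
    per = np.array([eps_rel(ut, up) for ut, up in zip(U_true, U_pred)])
    return ErrorReport(eps_rel=float(per.mean()), per_instance=per, meta=meta)


def eps_k(u_k: np.ndarray, u_pred_k: np.ndarray,
          U_true: np.ndarray) -> np.ndarray:
    """Per-node field |u^k - u~^k| normalized by the time-mean truth norm.

    ``U_true`` is the full truth trajectory (N, Nt) providing the
    normalization (1/Nt) sum_k ||u^k||_2.
    """
    denom = np.linalg.norm(np.asarray(U_true, dtype=float), axis=0).mean()
    if denom <= 0:
        raise ZeroDivisionError("zero time-mean truth norm")
    return np.abs(np.asarray(u_k) - np.asarray(u_pred_k)) / denom


def eps_ks(u_k: np.ndarray, u_pred_k: np.ndarray) -> np.ndarray:
    """Per-node percent field |u^k - u~^k| / ||u^k||_1 * 100."""
    denom = np.abs(np.asarray(u_k, dtype=float)).sum()
    if denom <= 0:
        raise ZeroDivisionError("zero 1-norm truth state")
    return np.abs(np.asarray(u_k) - np.asarray(u_pred_k)) / denom * 100.0


def eps_ks_summary(U_true: np.ndarray, U_pred: np.ndarray) -> dict:
    """Mean/median/quartiles over nodes of eps_ks, per time sample."""
    nt = U_true.shape[1]
    fields = np.stack([eps_ks(U_true[:, k], U_pred[:, k]) for k in range(nt)])
    return {
        "mean": fields.mean(axis=1),
        "median": np.median(fields, axis=1),
        "q1": np.percentile(fields, 25, axis=1),
        "q3": np.percentile(fields, 75, axis=1),
        "min": fields.min(axis=1),
    }


def _crossing_times_ms(trace: np.ndarray, times: np.ndarray,
                       threshold: float) -> float:
    """First upward crossing time (ms), linearly interpolated; NaN if none."""
    above = trace >= threshold
    if above[0]:
        return float(times[0] * TIME_SCALE_MS)
    idx = np.nonzero(~above[:-1] & above[1:])[0]
    if len(idx) == 0:
        return UNACTIVATED
    i = idx[0]
    frac = (threshold - trace[i]) / (trace[i + 1] - trace[i])
    t = times[i] + frac * (times[i + 1] - times[i])
    return float(t * TIME_SCALE_MS)


@dataclass
class ActivationMap:
    """Per-node activation time in ms (NaN = never activated)."""

    times_ms: np.ndarray
    threshold: float

    @property
    def activated(self) -> np.ndarray:
        return np.isfinite(self.times_ms)


def activation_map(U: np.ndarray, times: np.ndarray,
                   threshold: float = DEFAULT_THRESHOLD) -> ActivationMap:
    """Activation times of a trajectory (N, Nt) sampled at rescaled times."""
    U = np.asarray(U, dtype=float)
    times = np.asarray(times, dtype=float)
    if U.size == 0 or len(times) == 0:
        raise ValueError("empty trajectory")
    if np.any(np.diff(times) <= 0):
        raise ValueError("trajectory must be time-sorted")
    out = np.array(
        [_crossing_times_ms(U[i], times, threshold) for i in range(U.shape[0])]
    )
    return ActivationMap(times_ms=out, threshold=threshold)


def apd_map(U: np.ndarray, times: np.ndarray,
            threshold: float = DEFAULT_THRESHOLD) -> np.ndarray:
    """Per-node action potential duration: total time (ms) with u above
    threshold, summed over supra-threshold intervals with linear
    interpolation at the crossings."""
    U = np.asarray(U, dtype=float)
    times = np.asarray(times, dtype=float) * TIME_SCALE_MS
    if U.size == 0 or len(times) == 0:
        raise ValueError("empty trajectory")
    above = U >= threshold
    apd = np.zeros(U.shape[0])
    dt = np.diff(times)
    for k in range(U.shape[1] - 1):
        a0, a1 = above[:, k], above[:, k + 1]
        du = U[:, k + 1] - U[:, k]
        with np.errstate(divide="ignore", invalid="ignore"):
            frac = np.where(du != 0, (threshold - U[:, k]) / du, 0.0)
        frac = np.clip(frac, 0.0, 1.0)
        seg = np.zeros(U.shape[0])
        seg[a0 & a1] = dt[k]
        rising = ~a0 & a1
        seg[rising] = (1.0 - frac[rising]) * dt[k]
        falling = a0 & ~a1
        seg[falling] = frac[falling] * dt[k]
        apd += seg
    return apd
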