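"""Parametric extrapolation of digitized Kaplan-Meier curves.

Digitized survival points from published trial arms are pooled by sample
size, fitted with a Weibull model by two classical methods — the log-log
linearization ``ln(-ln S) = shape·ln t − shape·ln scale`` and direct least
squares on the survival scale — and converted into per-cycle transition
probabilities for a monthly state-transition model.

The Weibull family is used throughout: the log-log regression is linear
exactly when survival is Weibull, and the exponential model is recovered as
the shape = 1 special case.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
from scipy import optimize, stats

log = logging.getLogger(__name__)

__all__ = [
    "SurvivalCurve",
    "WeibullModel",
    "AveragedSurvival",
    "TransitionSchedule",
    "pool_curves",
    "fit_regression",
    "fit_least_squares",
    "average_models",
    "to_transition_schedule",
]


@dataclass(frozen=True)
class SurvivalCurve:
    """Empirical survival function of one trial arm (or a pooled set).

    Parameters
    ----------
    label : str
        Identifier of the trial arm or model branch.
    points : sequence of (float, float)
        ``(t, s)`` pairs, time in months, survival probability. Times must
        be strictly increasing and survival non-increasing in ``(0, 1]``.
        A leading ``(0, 1)`` anchor is prepended when absent.
    n : int
        Trial sample size; used as the pooling weight.
    """

    label: str
    points: tuple[tuple[float, float], ...]
    n: int

    def __init__(self, label: str, points: Sequence[tuple[float, float]], n: int):
        pts = [(float(t), float(s)) for t, s in points]
        if not pts:
            raise ValueError(f"curve {label!r}: no points")
        if pts[0][0] != 0.0:
            pts.insert(0, (0.0, 1.0))
        elif pts[0][1] != 1.0:
            raise ValueError(f"curve {label!r}: survival at t=0 must be 1")
        times = [t for t, _ in pts]
        surv = [s for _, s in pts]
        if any(t2 <= t1 for t1, t2 in zip(times, times[1:])):
            raise ValueError(f"curve {label!r}: times not strictly increasing")
        if any(s2 > s1 + 1e-12 for s1, s2 in zip(surv, surv[1:])):
            raise ValueError(f"curve {label!r}: survival not non-increasing")
        if any(not (0.0 < s <= 1.0) for s in surv):
            raise ValueError(f"curve {label!r}: survival outside (0, 1]")
        if int(n) < 1:
            raise ValueError(f"curve {label!r}: sample size must be positive")
        object.__setattr__(self, "label", label)
        object.__setattr__(self, "points", tuple(pts))
        object.__setattr__(self, "n", int(n))

    @property
    def times(self) -> np.ndarray:
        return np.array([t for t, _ in self.points])

    @property
    def survival(self) -> np.ndarray:
        return np.array([s for _, s in self.points])

    def step_at(self, t: float) -> float:
        """Right-continuous step interpolation, matching K-M semantics."""
        idx = int(np.searchsorted(self.times, t, side="right")) - 1
        return float(self.survival[max(idx, 0)])


@dataclass(frozen=True)
class WeibullModel:
    """Two-parameter Weibull survival model S(t) = exp(−(t/scale)^shape)."""

    shape: float
    scale: float

    def __post_init__(self) -> None:
        if not (self.shape > 0 and self.scale > 0):
            raise ValueError("Weibull shape and scale must be positive")

    def survival(self, t) -> np.ndarray:
        t = np.asarray(t, dtype=float)
        return np.exp(-((t / self.scale) ** self.shape))

    def __call__(self, t):
        return self.survival(t)


@dataclass(frozen=True)
class AveragedSurvival:
    """Pointwise mean of two fitted survival functions.

    The base-case extrapolation averages the two fitting methods on the
    survival-probability scale, not on the parameter scale: the mean of two
    Weibull curves is generally not Weibull, so parameter averaging would
    not represent the intended mean curve.
    """

    model_a: WeibullModel
    model_b: WeibullModel

    def survival(self, t) -> np.ndarray:
        return 0.5 * (self.model_a.survival(t) + self.model_b.survival(t))

    def __call__(self, t):
        return self.survival(t)


@dataclass(frozen=True)
class TransitionSchedule:
    """Per-cycle conditional event probabilities p_t for cycles 0..H−1.

    The defining identity is ``∏_{u<t} (1 − p_u) = S(t)`` at every cycle
    boundary, so the schedule reproduces the survival function it was built
    from.
    """

    probs: tuple[float, ...]
    horizon: int = field(default=0)

    def __post_init__(self) -> None:
        probs = tuple(float(p) for p in self.probs)
        if any(not (0.0 <= p <= 1.0) for p in probs):
            raise ValueError("transition probabilities must lie in [0, 1]")
        object.__setattr__(self, "probs", probs)
        object.__setattr__(self, "horizon", len(probs))

    def __len__(self) -> int:
        return self.horizon

    def __getitem__(self, i: int) -> float:
        return self.probs[i]

    def survival_at_boundaries(self) -> np.ndarray:
        """S(0..H) implied by the schedule."""
        return np.concatenate([[1.0], np.cumprod(1.0 - np.array(self.probs))])


def pool_curves(curves: Sequence[SurvivalCurve], label: str | None = None) -> SurvivalCurve:
    """Sample-size-weighted average of several trial-arm curves.

    Each input is step-interpolated onto the union of all time grids and the
    pooled survival at each time is ``Σ n_i·s_i(t) / Σ n_i``; the pooled
    sample size is ``Σ n_i``. With a single input the curve is returned
    unchanged.
    """
    if not curves:
        raise ValueError("no curves")
    if len(curves) == 1:
        return curves[0]
    grid = np.unique(np.concatenate([c.times for c in curves]))
    weights = np.array([c.n for c in curves], dtype=float)
    values = np.array([[c.step_at(t) for t in grid] for c in curves])
    pooled = weights @ values / weights.sum()
    # enforce monotonicity against step-interpolation rounding
    pooled = np.minimum.accumulate(pooled)
    name = label or "+".join(c.label for c in curves)
    return SurvivalCurve(name, list(zip(grid, pooled)), n=int(weights.sum()))


def _regression_points(curve: SurvivalCurve) -> tuple[np.ndarray, np.ndarray]:
    # s = 1 or t = 0 make the ln(−ln s) / ln t transform undefined; such
    # points are dropped here but kept for the survival-scale objective.
    pts = [(t, s) for t, s in curve.points if t > 0 and 0 < s < 1]
    t = np.array([p[0] for p in pts])
    s = np.array([p[1] for p in pts])
    return t, s


def fit_regression(curve: SurvivalCurve) -> WeibullModel:
    """Weibull fit via OLS of ln(−ln S(t)) on ln t.

    Under a Weibull model the transform is exactly linear with slope equal
    to the shape and intercept −shape·ln(scale); the fit is ordinary least
    squares on the transformed scale.
    """
    t, s = _regression_points(curve)
    if len(t) < 2:
        raise ValueError(f"curve {curve.label!r}: need ≥2 points with 0<s<1, t>0")
    res = stats.linregress(np.log(t), np.log(-np.log(s)))
    if res.slope <= 0:
        raise ValueError(f"curve {curve.label!r}: non-Weibull-compatible curve (slope ≤ 0)")
    shape = float(res.slope)
    scale = float(np.exp(-res.intercept / res.slope))
    model = WeibullModel(shape, scale)
    log.info("fit_regression %s: shape=%.6g scale=%.6g sse=%.4g",
             curve.label, shape, scale, sse(model, curve))
    return model


def sse(model: Callable[[np.ndarray], np.ndarray], curve: SurvivalCurve) -> float:
    """Sum of squared errors on the survival scale over all curve points."""
    return float(np.sum((curve.survival - model(curve.times)) ** 2))


def fit_least_squares(curve: SurvivalCurve) -> WeibullModel:
    """Weibull fit minimizing Σ (s_i − S(t_i))² on the survival scale.

    Deterministic multi-start Nelder-Mead: the log-log regression solution
    (when obtainable) plus a fixed lattice of starting values, optimized in
    log-parameter space. All digitized points are weighted equally.
    """
    if len(curve.points) < 2:
        raise ValueError(f"curve {curve.label!r}: need ≥2 points")

    def objective(logp: np.ndarray) -> float:
        return sse(WeibullModel(math.exp(logp[0]), math.exp(logp[1])), curve)

    starts = []
    try:
        reg = fit_regression(curve)
        starts.append((reg.shape, reg.scale))
    except ValueError:
        pass
    starts += [(0.5, 3.0), (1.0, 6.0), (1.5, 12.0), (2.5, 24.0), (4.0, 48.0)]

    best = None
    for shape0, scale0 in starts:
        res = optimize.minimize(
            objective, np.log([shape0, scale0]), method="Nelder-Mead",
            options={"xatol": 1e-12, "fatol": 1e-14, "maxiter": 4000},
        )
        if best is None or res.fun < best.fun:
            best = res
    if best is None or not np.all(np.isfinite(best.x)):
        raise RuntimeError(f"curve {curve.label!r}: least-squares fit failed: {best}")
    model = WeibullModel(float(np.exp(best.x[0])), float(np.exp(best.x[1])))
    log.info("fit_least_squares %s: shape=%.6g scale=%.6g sse=%.4g",
             curve.label, model.shape, model.scale, best.fun)
    return model


def average_models(a: WeibullModel, b: WeibullModel) -> AveragedSurvival:
    """Base-case extrapolation: pointwise mean of the two fitted curves."""
    return AveragedSurvival(a, b)


def to_transition_schedule(model: Callable, horizon: int) -> TransitionSchedule:
    """Convert a survival function to per-cycle conditional probabilities.

    ``p_t = 1 − S(t+1)/S(t)`` for monthly cycles t = 0..horizon−1. If the
    survival function reaches zero before the horizon the remaining cycles
    are absorbing (p_t = 1).
    """
    if horizon < 1:
        raise ValueError("horizon must be ≥ 1")
    t = np.arange(horizon + 1, dtype=float)
    s = np.asarray(model(t), dtype=float)
    probs = np.empty(horizon)
    for i in range(horizon):
        if s[i] <= 0.0:
            probs[i:] = 1.0
            log.warning("survival reached 0 at cycle %d; remaining cycles absorbing", i)
            break
        probs[i] = min(max(1.0 - s[i + 1] / s[i], 0.0), 1.0)
    return TransitionSchedule(tuple(probs))
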