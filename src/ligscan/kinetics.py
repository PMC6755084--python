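"""Ligation kinetics: single-exponential time-course fitting and comparison.

Under excess ribozyme over substrate, the fraction ligated follows
pseudo-first-order saturation kinetics

    FL(t) = F_max * (1 - exp(-k_obs * t))

with an observed rate constant ``k_obs`` and a plateau ``F_max`` below 1
(incomplete folding, substrate heterogeneity). Fits are bounded nonlinear
least squares (k_obs ≥ 0, 0 < F_max ≤ 1) over the pooled replicates;
``k_obs`` carries its time unit so constructs measured on different time
scales (minutes vs hours) compare correctly.

``k_obs`` here is a single-condition observed rate, not a true k_cat: it is
measured at one ribozyme/substrate ratio, temperature and Mg2+ level.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import least_squares

_MINUTES_PER_UNIT = {"min": 1.0, "h": 60.0, "s": 1.0 / 60.0}


@dataclass
class TimeCourse:
    """Pooled (time, FL) observations, optionally over several replicates."""

    times: np.ndarray
    fl_obs: np.ndarray
    unit: str = "min"
    replicate: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.fl_obs = np.asarray(self.fl_obs, dtype=float)
        if self.unit not in _MINUTES_PER_UNIT:
            raise ValueError(f"unknown time unit {self.unit!r}")
        if self.times.shape != self.fl_obs.shape:
            raise ValueError("times and fl_obs must have the same shape")
        if (self.times < 0).any():
            raise ValueError("times must be non-negative")
        if ((self.fl_obs < 0) | (self.fl_obs > 1)).any():
            raise ValueError("FL observations must lie in [0, 1]")
        if self.replicate is None:
            self.replicate = np.zeros_like(self.times, dtype=int)
        else:
            self.replicate = np.asarray(self.replicate)

    def in_minutes(self) -> "TimeCourse":
        factor = _MINUTES_PER_UNIT[self.unit]
        return TimeCourse(self.times * factor, self.fl_obs, "min", self.replicate)


@dataclass
class KineticFit:
    """Fitted exponential-saturation parameters with their time unit."""

    k_obs: float
    f_max: float
    unit: str
    residual_sum: float
    converged: bool
    degenerate: bool = False
    n_obs: int = 0

    @property
    def k_per_minute(self) -> float:
        return self.k_obs / _MINUTES_PER_UNIT[self.unit] if self.unit != "min" else self.k_obs


def exponential_fl(t: np.ndarray, k_obs: float, f_max: float) -> np.ndarray:
    """Model curve FL(t) = F_max (1 - e^{-k t})."""
    return f_max * (1.0 - np.exp(-k_obs * np.asarray(t, dtype=float)))


def _initial_guess(t: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """F_max from the largest observation, k from the early log-linear slope.

    1 - FL/F_max = e^{-kt}, so log(1 - FL/F0) against t is linear with slope
    -k; the two earliest informative time points estimate it.
    """
    f0 = float(np.clip(y.max(), 1e-6, 1.0))
    order = np.argsort(t)
    ts, ys = t[order], y[order]
    mask = (ts > 0) & (ys < f0 * (1 - 1e-9))
    k0 = None
    if mask.sum() >= 1:
        with np.errstate(divide="ignore"):
            logs = np.log1p(-np.clip(ys[mask] / f0, 0, 1 - 1e-12))
        k0 = float(-logs[0] / ts[mask][0])
    if not k0 or not np.isfinite(k0) or k0 <= 0:
        positive = ts[ts > 0]
        k0 = 1.0 / float(np.median(positive)) if positive.size else 1.0
    return k0, f0


def fit_ligation_timecourse(tc: TimeCourse) -> KineticFit:
    """Bounded least-squares fit of (k_obs, F_max) to a pooled time course.

    Requires at least 3 distinct time points. All-zero observations give the
    degenerate fit k_obs = 0 (no detectable ligation). The result is
    deterministic: initialization is a fixed function of the data.
    """
    t, y = tc.times, tc.fl_obs
    if np.unique(t).size < 3:
        raise ValueError("need at least 3 distinct time points to fit")
    if not y.any():
        return KineticFit(0.0, 1.0, tc.unit, 0.0, True, degenerate=True, n_obs=y.size)
    k0, f0 = _initial_guess(t, y)
    result = least_squares(
        lambda p: exponential_fl(t, p[0], p[1]) - y,
        x0=[k0, min(f0, 1.0)],
        bounds=([0.0, 1e-9], [np.inf, 1.0]),
    )
    k, f = result.x
    return KineticFit(
        k_obs=float(k),
        f_max=float(f),
        unit=tc.unit,
        residual_sum=float(2 * result.cost),
        converged=bool(result.status > 0),
        n_obs=y.size,
    )


def fold_difference(fit_a: KineticFit, fit_b: KineticFit) -> float:
    """Unit-aware rate ratio k_a / k_b, both converted to min⁻¹."""
    ka, kb = fit_a.k_per_minute, fit_b.k_per_minute
    if kb == 0:
        raise ZeroDivisionError("denominator rate constant is zero")
    return ka / kb


def rate_fold(k_a: float, unit_a: str, k_b: float, unit_b: str) -> float:
    """Fold ratio between two raw rate constants with explicit units."""
    if unit_a not in _MINUTES_PER_UNIT or unit_b not in _MINUTES_PER_UNIT:
        raise ValueError("units must be one of 's', 'min', 'h'")
    ka = k_a / _MINUTES_PER_UNIT[unit_a]
    kb = k_b / _MINUTES_PER_UNIT[unit_b]
    if kb == 0:
        raise ZeroDivisionError("denominator rate constant is zero")
    return ka / kb
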