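"""Periodic waveforms and the scalar functionals of protein turnover.

Everything here follows from the balance equation for a protein with
periodic concentration x(t) = x(t+T),

    dx/dt = g(t) - r(t) x(t),        g(t) >= 0,  r(t) >= 0,

whose periodicity forces <g> = <r x> over one period: the proteosynthetic
cost.  Because g >= 0, any feasible degradation rate satisfies the
pointwise floor r(t) >= max(-x'(t)/x(t), 0); a *constant* rate must sit at
the peak of that floor, so the constant-rate cost is bounded below by

    cg = max_t[-x'(t)/x(t)] * <x>_t .

A rhythmic r(t) that peaks only during the falling phase can undercut cg.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from scipy.interpolate import CubicSpline
from scipy.optimize import minimize_scalar

__all__ = [
    "PeriodicProfile",
    "RateSeries",
    "CostSummary",
    "log_decline_rate",
    "min_constant_rate",
    "degradation_floor",
    "cg",
    "synthesis_cost",
    "alpha_D",
    "similarity_S",
    "synthesis_from_balance",
    "half_life",
    "atp_payoff_fraction",
]

#: default dense evaluation step in hours for extremum searches
DENSE_STEP_H = 0.01


class PeriodicProfile:
    """Strictly positive T-periodic concentration profile x(t).

    Evaluation at any real t reduces t modulo the period.  Profiles built
    from samples are backed by a periodic cubic spline, so value and first
    derivative are continuous across the wrap point.

    Parameters
    ----------
    fun : callable
        Value x(t) on [0, T].
    dfun : callable
        Derivative x'(t) on [0, T].
    period : float
        Oscillation period T in hours (default 24).
    """

    def __init__(self, fun: Callable, dfun: Callable, period: float = 24.0):
        if period <= 0:
            raise ValueError(f"period must be positive, got {period}")
        self.period = float(period)
        self._fun = fun
        self._dfun = dfun
        self._validate()

    def _validate(self) -> None:
        tt = np.linspace(0.0, self.period, 481)
        vals = self._fun(tt)
        if not np.all(np.isfinite(vals)):
            raise ValueError("profile takes non-finite values")
        if np.any(vals <= 0):
            raise ValueError("profile must be strictly positive everywhere")

    # -- construction -------------------------------------------------

    @classmethod
    def from_samples(
        cls,
        times: Sequence[float],
        values: Sequence[float],
        period: float = 24.0,
    ) -> "PeriodicProfile":
        """Periodic cubic spline through samples on one period.

        The wrap point is appended automatically; if both endpoints are
        present they must agree.
        """
        t = np.asarray(times, dtype=float)
        v = np.asarray(values, dtype=float)
        if t.ndim != 1 or t.shape != v.shape:
            raise ValueError("times and values must be matching 1-d arrays")
        order = np.argsort(t)
        t, v = t[order], v[order]
        t = np.mod(t, period) if t[-1] > period else t
        order = np.argsort(t)
        t, v = t[order], v[order]
        if np.any(np.diff(t) <= 0):
            raise ValueError("duplicate time points in profile samples")
        if math.isclose(t[0], 0.0) and math.isclose(t[-1], period):
            if not math.isclose(v[0], v[-1], rel_tol=1e-9):
                raise ValueError("endpoint values disagree for periodic spline")
        else:
            t = np.append(t, t[0] + period)
            v = np.append(v, v[0])
        spl = CubicSpline(t, v, bc_type="periodic")
        dspl = spl.derivative()
        return cls(spl, dspl, period=period)

    @classmethod
    def from_callable(
        cls,
        fun: Callable,
        period: float = 24.0,
        dfun: Callable | None = None,
        n_grid: int = 2401,
    ) -> "PeriodicProfile":
        """Wrap an analytic T-periodic function.

        If no analytic derivative is supplied, the function is resampled
        onto a dense periodic spline (n_grid points per period) to obtain
        one.
        """
        if dfun is not None:
            return cls(fun, dfun, period=period)
        tt = np.linspace(0.0, period, n_grid)
        return cls.from_samples(tt[:-1], np.asarray(fun(tt[:-1]), dtype=float), period)

    @classmethod
    def constant(cls, value: float, period: float = 24.0) -> "PeriodicProfile":
        if value <= 0:
            raise ValueError("constant profile must be positive")
        return cls(
            lambda t: np.full_like(np.asarray(t, dtype=float), value),
            lambda t: np.zeros_like(np.asarray(t, dtype=float)),
            period=period,
        )

    # -- evaluation ---------------------------------------------------

    def __call__(self, t):
        return self._fun(np.mod(np.asarray(t, dtype=float), self.period))

    def derivative(self, t):
        return self._dfun(np.mod(np.asarray(t, dtype=float), self.period))

    def grid(self, step: float = DENSE_STEP_H) -> np.ndarray:
        """Dense regular grid covering one period (endpoint excluded)."""
        n = max(int(round(self.period / step)), 16)
        return np.linspace(0.0, self.period, n, endpoint=False)

    def mean(self) -> float:
        """Time average <x>_t by trapezoidal quadrature on a dense grid."""
        tt = np.linspace(0.0, self.period, 2401)
        return float(np.trapezoid(self(tt), tt) / self.period)

    def scaled(self, factor: float) -> "PeriodicProfile":
        if factor <= 0:
            raise ValueError("scale factor must be positive")
        return PeriodicProfile(
            lambda t: factor * self._fun(t),
            lambda t: factor * self._dfun(t),
            period=self.period,
        )

    # -- serialization ------------------------------------------------

    def to_csv(self, path, step: float = 0.1) -> None:
        tt = self.grid(step)
        pd.DataFrame({"time_h": tt, "value": self(tt)}).to_csv(path, index=False)

    @classmethod
    def read_csv(cls, path, period: float = 24.0) -> "PeriodicProfile":
        df = pd.read_csv(path, comment="#")
        if not {"time_h", "value"}.issubset(df.columns):
            raise ValueError(f"{path}: expected columns time_h,value")
        return cls.from_samples(df["time_h"].to_numpy(), df["value"].to_numpy(), period)


@dataclass
class RateSeries:
    """Non-negative T-periodic rate samples r(t) in h^-1.

    Values between samples are obtained by periodic linear interpolation;
    evaluation at any real t reduces t modulo the period.
    """

    times: np.ndarray
    rates: np.ndarray
    period: float = 24.0

    def __post_init__(self):
        self.times = np.asarray(self.times, dtype=float)
        self.rates = np.asarray(self.rates, dtype=float)
        if self.times.shape != self.rates.shape or self.times.ndim != 1:
            raise ValueError("times and rates must be matching 1-d arrays")
        order = np.argsort(self.times)
        self.times = self.times[order]
        self.rates = self.rates[order]
        if np.any(self.rates < 0):
            raise ValueError("rates must be non-negative")

    @classmethod
    def constant(cls, rate: float, period: float = 24.0, n: int = 49) -> "RateSeries":
        tt = np.linspace(0.0, period, n, endpoint=False)
        return cls(tt, np.full(n, float(rate)), period)

    @classmethod
    def from_callable(cls, fun: Callable, period: float = 24.0, n: int = 481) -> "RateSeries":
        tt = np.linspace(0.0, period, n, endpoint=False)
        return cls(tt, np.asarray(fun(tt), dtype=float), period)

    def __call__(self, t):
        # wrap-around linear interpolation
        tmod = np.mod(np.asarray(t, dtype=float), self.period)
        tp = np.concatenate([self.times, [self.times[0] + self.period]])
        rp = np.concatenate([self.rates, [self.rates[0]]])
        return np.interp(tmod, tp, rp)

    def max(self) -> float:
        return float(np.max(self.rates))

    def min(self) -> float:
        return float(np.min(self.rates))

    def to_csv(self, path) -> None:
        pd.DataFrame({"time_h": self.times, "value": self.rates}).to_csv(path, index=False)

    @classmethod
    def read_csv(cls, path, period: float = 24.0) -> "RateSeries":
        df = pd.read_csv(path, comment="#")
        if not {"time_h", "value"}.issubset(df.columns):
            raise ValueError(f"{path}: expected columns time_h,value")
        return cls(df["time_h"].to_numpy(), df["value"].to_numpy(), period)


@dataclass
class CostSummary:
    """Period-averaged synthesis and degradation of one protein."""

    mean_synthesis: float  # <g>, conc h^-1
    mean_degradation: float  # <r x>, conc h^-1
    per_period_amount: float  # Delta x = T <g>, conc
    cg: float  # constant-rate cost bound, conc h^-1
    feasible: bool = True  # False when g(t) < 0 somewhere
    min_g: float = field(default=float("nan"))


# ----------------------------------------------------------------------
# scalar functionals


def log_decline_rate(profile: PeriodicProfile, t) -> float:
    """Instantaneous decline rate of the log abundance, -x'(t)/x(t).

    Positive during the falling phase of the oscillation.
    """
    x = profile(t)
    dx = profile.derivative(t)
    out = -dx / x
    if not np.all(np.isfinite(out)):
        raise ValueError("non-finite log decline rate")
    return out if np.ndim(out) else float(out)


def degradation_floor(profile: PeriodicProfile, t):
    """Pointwise lower bound max(-x'/x, 0) of any feasible r(t)."""
    return np.maximum(log_decline_rate(profile, t), 0.0)


def min_constant_rate(profile: PeriodicProfile, step: float = DENSE_STEP_H) -> float:
    """max_t[-x'(t)/x(t)]: the smallest admissible constant degradation rate.

    Dense-grid search with bounded local refinement around the argmax.
    """
    tt = profile.grid(step)
    vals = log_decline_rate(profile, tt)
    i = int(np.argmax(vals))
    lo = tt[i] - 2 * step
    hi = tt[i] + 2 * step
    res = minimize_scalar(
        lambda t: -log_decline_rate(profile, t),
        bounds=(lo, hi),
        method="bounded",
        options={"xatol": 1e-8},
    )
    return float(max(vals[i], -res.fun))


def argmax_decline(profile: PeriodicProfile, step: float = DENSE_STEP_H) -> float:
    """Time (mod T) of the steepest logarithmic decline."""
    tt = profile.grid(step)
    vals = log_decline_rate(profile, tt)
    i = int(np.argmax(vals))
    res = minimize_scalar(
        lambda t: -log_decline_rate(profile, t),
        bounds=(tt[i] - 2 * step, tt[i] + 2 * step),
        method="bounded",
        options={"xatol": 1e-8},
    )
    t_star = res.x if -res.fun >= vals[i] else tt[i]
    return float(np.mod(t_star, profile.period))


def cg(profile: PeriodicProfile) -> float:
    """Constant-rate cost bound cg = max_t[-x'/x] * <x>_t."""
    return min_constant_rate(profile) * profile.mean()


def synthesis_from_balance(profile: PeriodicProfile, rates: RateSeries) -> RateSeries:
    """Synthesis profile g(t) = x'(t) + r(t) x(t) implied by the balance.

    Negative g is reported as-is (interpreted downstream as infeasible),
    so the returned object is a plain sampled series that may dip below
    zero; it deliberately bypasses RateSeries' non-negativity check.
    """
    tt = np.linspace(0.0, profile.period, 2401, endpoint=False)
    g = profile.derivative(tt) + rates(tt) * profile(tt)
    out = RateSeries.__new__(RateSeries)
    out.times = tt
    out.rates = g
    out.period = profile.period
    return out


def synthesis_cost(profile: PeriodicProfile, rates: RateSeries) -> CostSummary:
    """Period-averaged cost <r x> (= <g> for a periodic solution)."""
    tt = np.linspace(0.0, profile.period, 2401)
    x = profile(tt)
    r = rates(tt)
    g = profile.derivative(tt) + r * x
    mean_deg = float(np.trapezoid(r * x, tt) / profile.period)
    mean_syn = float(np.trapezoid(g, tt) / profile.period)
    return CostSummary(
        mean_synthesis=mean_syn,
        mean_degradation=mean_deg,
        per_period_amount=profile.period * mean_syn,
        cg=cg(profile),
        feasible=bool(np.min(g) >= -1e-12 * max(np.max(np.abs(g)), 1.0)),
        min_g=float(np.min(g)),
    )


def alpha_D(rates: RateSeries) -> float:
    """Degradation rhythmicity alpha_D = (max r - min r) / max r, in [0, 1)."""
    rmax = rates.max()
    if rmax <= 0:
        raise ValueError("alpha_D undefined for an all-zero degradation rate")
    return (rmax - rates.min()) / rmax


def similarity_S(r: RateSeries, rE: RateSeries, step: float = 0.05) -> float:
    """Overlap similarity S = int min(r, rE) dt / int max(r, rE) dt.

    S is 1 only for identical trajectories and decreases toward 0 as the
    two profiles separate; it is symmetric and invariant under a common
    rescaling of both arguments.
    """
    if not math.isclose(r.period, rE.period):
        raise ValueError("similarity requires a common period")
    tt = np.arange(0.0, r.period, step)
    a = r(tt)
    b = rE(tt)
    hi = np.trapezoid(np.maximum(a, b), tt)
    if hi <= 0:
        raise ValueError("similarity undefined for two identically-zero series")
    return float(np.trapezoid(np.minimum(a, b), tt) / hi)


def half_life(rate: float) -> float:
    """Half-life ln 2 / r in hours for a degradation rate r > 0."""
    if rate <= 0:
        raise ValueError(f"half-life requires a positive rate, got {rate}")
    return math.log(2.0) / rate


def atp_payoff_fraction(n: int, N: int) -> float:
    """Minimum fractional synthesis reduction paying off phosphorylation ATP.

    Each peptide bond costs >= 4 phosphoryl groups (ATP+GTP), so attaching
    n phosphates to an N-residue protein is energetically neutral once the
    phospho-dependent route cuts synthesis by n/(4N).
    """
    if N < 1:
        raise ValueError("protein length N must be >= 1")
    if n < 0:
        raise ValueError("phosphorylation count n must be >= 0")
    return n / (4.0 * N)
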