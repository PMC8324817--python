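"""Empirical fitting stages: ingestion, smoothing, rate profiles, scans.

The empirical workflow mirrors how sparse circadian measurements are
turned into model inputs:

1. replicated abundance time courses are normalized, smoothed and
   splined into a strictly positive periodic profile x(t);
2. sparse degradation-rate measurements are extended into an empirical
   profile rE(t) clamped from below by the balance floor max(-x'/x, 0)
   and by the smallest observed rate;
3. kinetic parameter sets are uniform-sampled from physiological ranges,
   pushed through the profile-constrained simulation, and compared to
   rE(t) with the overlap similarity S;
4. a derivative-free simplex search refines the best sets.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.interpolate import splev, splrep
from scipy.optimize import minimize
from scipy.stats import spearmanr

from rhythmdeg.constrained import constrained_simulate
from rhythmdeg.params import PhosphoParams, UbParams
from rhythmdeg.waveform import (
    PeriodicProfile,
    RateSeries,
    argmax_decline,
    degradation_floor,
    log_decline_rate,
    similarity_S,
)

__all__ = [
    "EmpiricalSeries",
    "ScanRecord",
    "read_timeseries",
    "moving_average",
    "fit_profile_spline",
    "normalize_series",
    "tim_stage",
    "build_empirical_rate_profile",
    "sample_parameters",
    "params_from_sample",
    "scan",
    "optimize_parameters",
    "cost_similarity_association",
]


@dataclass
class EmpiricalSeries:
    """Time-stamped replicated measurements over (part of) a cycle.

    ``kind`` tags what was measured (abundance, rate, ubiquitinated
    fraction); CT and ZT hour labels are treated identically.
    """

    times: np.ndarray
    values: np.ndarray
    replicates: np.ndarray
    kind: str = "abundance"
    period: float = 24.0
    periodic: bool = False

    def __post_init__(self):
        self.times = np.asarray(self.times, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        self.replicates = np.asarray(self.replicates)
        if not (self.times.shape == self.values.shape == self.replicates.shape):
            raise ValueError("times, values, replicates must have equal length")
        if len(np.unique(self.times)) < 2:
            raise ValueError("a series needs at least 2 distinct time points")
        order = np.lexsort((self.replicates, self.times))
        self.times = self.times[order]
        self.values = self.values[order]
        self.replicates = self.replicates[order]

    @property
    def n_points(self) -> int:
        return len(self.times)

    def replicate_means(self) -> tuple[np.ndarray, np.ndarray]:
        """Unique times and per-time replicate-mean values."""
        ut = np.unique(self.times)
        mv = np.array([self.values[self.times == t].mean() for t in ut])
        return ut, mv

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"time_h": self.times, "value": self.values,
                             "replicate": self.replicates})


def read_timeseries(path, kind: str = "abundance", period: float = 24.0,
                    periodic: bool = False) -> EmpiricalSeries:
    """Read a CSV with columns time_h, value[, replicate].

    Rows are sorted by time; duplicate (time, replicate) pairs are
    rejected with their line numbers.
    """
    df = pd.read_csv(path, comment="#")
    if df.empty:
        raise ValueError(f"{path}: empty time series file")
    if not {"time_h", "value"}.issubset(df.columns):
        raise ValueError(f"{path}: expected columns time_h,value[,replicate]")
    if "replicate" not in df.columns:
        df["replicate"] = 1
    for col in ("time_h", "value"):
        bad = pd.to_numeric(df[col], errors="coerce").isna() & df[col].notna()
        if bad.any():
            lines = (df.index[bad] + 2).tolist()
            raise ValueError(f"{path}: unparseable {col} at line(s) {lines}")
        df[col] = pd.to_numeric(df[col])
    dup = df.duplicated(subset=["time_h", "replicate"], keep=False)
    if dup.any():
        lines = (df.index[dup] + 2).tolist()
        raise ValueError(f"{path}: duplicate (time, replicate) rows at line(s) {lines}")
    return EmpiricalSeries(df["time_h"].to_numpy(), df["value"].to_numpy(),
                           df["replicate"].to_numpy(), kind=kind,
                           period=period, periodic=periodic)


def moving_average(series: EmpiricalSeries, window_hours: float) -> EmpiricalSeries:
    """Centered moving-window average of the replicate-mean values.

    Endpoints are inclusive (|t_j - t_i| <= window/2 contributes).  When
    the series is flagged periodic, distances wrap at the period.
    """
    if window_hours <= 0:
        raise ValueError("window must be positive")
    ut, mv = series.replicate_means()
    span = (ut[-1] - ut[0]) if not series.periodic else series.period
    if window_hours > span:
        raise ValueError(f"window {window_hours} h exceeds series span {span} h")
    half = window_hours / 2.0
    out = np.empty_like(mv)
    for i, t in enumerate(ut):
        d = np.abs(ut - t)
        if series.periodic:
            d = np.minimum(d, series.period - d)
        sel = d <= half + 1e-12
        out[i] = mv[sel].mean()
    return EmpiricalSeries(ut, out, np.ones(len(ut), dtype=int),
                           kind=series.kind, period=series.period,
                           periodic=series.periodic)


def fit_profile_spline(series: EmpiricalSeries, degree: int = 3,
                       smoothing: float = 5.0,
                       positivity_eps: float = 1e-3) -> PeriodicProfile:
    """Periodic smoothing spline of the replicate means.

    Uses a degree-``degree`` smoothing spline (smoothing condition ``s``)
    with periodic boundary handling, then resamples onto the package's
    periodic cubic representation.  Values are floored at
    ``positivity_eps * mean`` with a warning so the result is a valid
    strictly positive profile.
    """
    ut, mv = series.replicate_means()
    if len(ut) < degree + 1:
        raise ValueError(f"need at least {degree + 1} distinct time points")
    if np.ptp(ut) == 0:
        raise ValueError("all time points are equal")
    t = np.append(ut, ut[0] + series.period)
    v = np.append(mv, mv[0])
    tck = splrep(t, v, k=degree, s=smoothing, per=1)
    dense_t = np.linspace(ut[0], ut[0] + series.period, 961, endpoint=False)
    dense_v = splev(dense_t, tck)
    floor = positivity_eps * max(float(np.mean(np.abs(dense_v))), 1e-300)
    if np.any(dense_v < floor):
        warnings.warn("spline dipped non-positive; flooring at eps*mean")
        dense_v = np.maximum(dense_v, floor)
    return PeriodicProfile.from_samples(np.mod(dense_t, series.period), dense_v,
                                        period=series.period)


def normalize_series(series: EmpiricalSeries, mode: str,
                     reference: float) -> EmpiricalSeries:
    """Normalize values by a reference-time replicate average or a constant.

    ``mode='at_time'`` divides by the replicate average at the reference
    time (which must be sampled); ``mode='to_value'`` divides by the
    given number.
    """
    if mode == "at_time":
        at = np.isclose(series.times, reference)
        if not at.any():
            raise ValueError(f"reference time {reference} h not present in series")
        ref = float(series.values[at].mean())
    elif mode == "to_value":
        ref = float(reference)
    else:
        raise ValueError(f"unknown normalization mode {mode!r}")
    if ref == 0:
        raise ValueError("zero reference average; cannot normalize")
    return replace(series, values=series.values / ref)


def tim_stage(abundance: EmpiricalSeries, ubiq: EmpiricalSeries,
              config: dict | None = None) -> dict:
    """Abundance -> spline -> log-decline profile, plus rescaled ubiquitination.

    The abundance series is normalized by its replicate average at
    ``abundance_reference`` (default CT 18 h), splined (degree 3,
    smoothing condition configurable, default 5), and differentiated to
    -x'(t)/x(t); its peak phase (mod 24 h) is the predicted peak time of
    the ubiquitinated fraction.  The ubiquitinated-fraction series is
    rescaled so its replicate average at ``ubiq_reference`` (default CT
    0 h) is 1.
    """
    cfg = {"abundance_reference": 18.0, "ubiq_reference": 0.0,
           "smoothing": 5.0, "degree": 3}
    cfg.update(config or {})
    norm = normalize_series(abundance, "at_time", cfg["abundance_reference"])
    profile = fit_profile_spline(norm, degree=cfg["degree"],
                                 smoothing=cfg["smoothing"])
    tt = profile.grid(0.05)
    decline = np.asarray(log_decline_rate(profile, tt))
    degenerate = bool(np.ptp(decline) < 1e-9)
    peak = float("nan") if degenerate else argmax_decline(profile)
    ref = float(ubiq.values[np.isclose(ubiq.times, cfg["ubiq_reference"])].mean())
    if not np.isfinite(ref) or ref == 0:
        raise ValueError("ubiquitination reference average unavailable or zero")
    return {
        "profile": profile,
        "decline_times": tt,
        "decline": decline,
        "peak_phase_h": peak,
        "degenerate": degenerate,
        "ubiq_rescaled": replace(ubiq, values=ubiq.values / ref),
    }


def build_empirical_rate_profile(
    rate_points: EmpiricalSeries,
    x_profile: PeriodicProfile,
    smooth_decline_window: float | None = None,
    step: float = 0.05,
) -> RateSeries:
    """Empirical degradation-rate profile rE(t) from sparse measurements.

    At each dense-grid time the larger of (a) the linear inter-/
    extrapolation of the measured rates (terminal segments continued
    beyond the sampled span) and (b) the balance floor max(-x'/x, 0) is
    taken, and the whole profile is clamped from below by the smallest
    measured rate.  Optionally the -x'/x curve is pre-smoothed with a
    centered moving window (the order is smooth, then floor, then
    clamp).
    """
    ut, mv = rate_points.replicate_means()
    if len(ut) < 2:
        raise ValueError("need at least two rate measurements")
    tt = np.arange(0.0, x_profile.period, step)

    # piecewise-linear with terminal-segment extrapolation
    interp = np.interp(tt, ut, mv)
    left_slope = (mv[1] - mv[0]) / (ut[1] - ut[0])
    right_slope = (mv[-1] - mv[-2]) / (ut[-1] - ut[-2])
    interp = np.where(tt < ut[0], mv[0] + left_slope * (tt - ut[0]), interp)
    interp = np.where(tt > ut[-1], mv[-1] + right_slope * (tt - ut[-1]), interp)

    decline = np.asarray(log_decline_rate(x_profile, tt))
    if smooth_decline_window is not None:
        half = smooth_decline_window / 2.0
        sm = np.empty_like(decline)
        for i, t in enumerate(tt):
            d = np.abs(tt - t)
            d = np.minimum(d, x_profile.period - d)
            sm[i] = decline[d <= half + 1e-12].mean()
        decline = sm
    floor = np.maximum(decline, 0.0)

    rE = np.maximum.reduce([interp, floor, np.full_like(tt, float(np.min(mv)))])
    return RateSeries(tt, rE, x_profile.period)


# ----------------------------------------------------------------------
# parameter scans


@dataclass
class ScanRecord:
    """One constrained-simulation outcome within a parameter scan."""

    index: int
    sample: dict
    feasible: bool
    S: float | None = None
    cost: float | None = None
    alpha_D: float | None = None
    reason: str = "feasible"
    seed: int | None = None


def sample_parameters(ranges: dict, count: int, seed: int) -> list[dict]:
    """Reproducible uniform draws, one dict per sample.

    ``ranges`` maps parameter name to {low, high, scale} with scale
    'linear' or 'log'; log-scaled parameters are drawn uniformly in
    log10.
    """
    if count < 1:
        raise ValueError("count must be >= 1")
    rng = np.random.default_rng(seed)
    for name, spec in ranges.items():
        if spec["low"] > spec["high"]:
            raise ValueError(f"invalid range for {name}: low > high")
        if spec.get("scale", "linear") == "log" and spec["low"] <= 0:
            raise ValueError(f"log-scaled range for {name} must be positive")
    out = []
    for i in range(count):
        draw = {}
        for name, spec in ranges.items():
            lo, hi = spec["low"], spec["high"]
            if spec.get("scale", "linear") == "log":
                draw[name] = 10 ** rng.uniform(math.log10(lo), math.log10(hi))
            else:
                draw[name] = rng.uniform(lo, hi)
        draw["_index"] = i
        draw["_seed"] = seed
        out.append(draw)
    return out


#: sample keys consumed by the phospho-independent kinetic block
_UB_KEYS = ("u_bar", "a0", "a1", "a2", "q", "r0", "v_bar", "b0", "b1", "s")


def params_from_sample(sample: dict, phospho_n: int = 0
                       ) -> tuple[UbParams, PhosphoParams | None]:
    """Build (UbParams, PhosphoParams) from one sampled dict.

    Keys from ``_UB_KEYS`` feed the ubiquitination block; for
    ``phospho_n >= 1`` keys ``y`` and ``k`` build a tied chain
    (k1 = ... = kn, the default simplification), with optional ``z`` and
    ``l``.
    """
    ub = UbParams(**{k: sample[k] for k in _UB_KEYS if k in sample})
    ph = None
    if phospho_n >= 1:
        ph = PhosphoParams.tied(phospho_n, y=sample["y"], k=sample["k"],
                                z=sample.get("z", 0.0), l=sample.get("l", 0.0))
    return ub, ph


def scan(x_profile: PeriodicProfile, samples: list[dict],
         rE: RateSeries | None = None, phospho_n: int = 0,
         **sim_kwargs) -> list[ScanRecord]:
    """Constrained-simulate every sampled parameter set.

    Infeasible sets (including integration failures) are retained with
    ``feasible=False`` and a reason; records depend only on their own
    sample, so the list is order-insensitive and trivially parallel.
    """
    if not samples:
        raise ValueError("no samples supplied")
    records = []
    for sample in samples:
        idx = sample.get("_index", len(records))
        ub, ph = params_from_sample(sample, phospho_n)
        try:
            sim = constrained_simulate(x_profile, ub, ph, **sim_kwargs)
        except RuntimeError as exc:
            records.append(ScanRecord(index=idx, sample=sample, feasible=False,
                                      reason=f"integration: {exc}",
                                      seed=sample.get("_seed")))
            continue
        if not sim.feasible.feasible:
            records.append(ScanRecord(index=idx, sample=sample, feasible=False,
                                      reason=sim.feasible.reason(),
                                      seed=sample.get("_seed")))
            continue
        S = similarity_S(sim.rate_series(), rE) if rE is not None else None
        records.append(ScanRecord(index=idx, sample=sample, feasible=True,
                                  S=S, cost=sim.cost, alpha_D=sim.alpha_D,
                                  seed=sample.get("_seed")))
    return records


def records_frame(records: list[ScanRecord]) -> pd.DataFrame:
    rows = []
    for rec in records:
        row = {"index": rec.index, "feasible": rec.feasible, "S": rec.S,
               "cost": rec.cost, "alpha_D": rec.alpha_D, "reason": rec.reason}
        row.update({k: v for k, v in rec.sample.items() if not k.startswith("_")})
        rows.append(row)
    return pd.DataFrame(rows)


def optimize_parameters(
    x_profile: PeriodicProfile,
    rE: RateSeries,
    objective: str,
    init: dict,
    ranges: dict,
    phospho_n: int = 0,
    maxiter: int = 200,
    **sim_kwargs,
) -> dict:
    """Nelder-Mead refinement of a feasible starting parameter set.

    The simplex runs in log10-parameter space over the keys of
    ``ranges``; coordinates outside a range are folded back by
    reflection, and infeasible evaluations are penalized with
    1e6 * (1 + violation magnitude).  Returns the best feasible sample,
    its objective value, S and cost, plus the objective trace.
    """
    if objective not in ("maximize_S", "minimize_cost"):
        raise ValueError(f"unknown objective {objective!r}")
    keys = list(ranges.keys())
    lo = np.array([math.log10(ranges[k]["low"]) for k in keys])
    hi = np.array([math.log10(ranges[k]["high"]) for k in keys])
    x0 = np.array([math.log10(init[k]) for k in keys])

    def fold(x):
        # reflect into [lo, hi]
        span = hi - lo
        y = np.mod(x - lo, 2 * span)
        y = np.where(y > span, 2 * span - y, y)
        return lo + y

    trace = []
    best = {"value": np.inf, "sample": None, "S": None, "cost": None}

    def objective_fn(x):
        xf = fold(x)
        sample = dict(init)
        sample.update({k: 10.0 ** v for k, v in zip(keys, xf)})
        ub, ph = params_from_sample(sample, phospho_n)
        try:
            sim = constrained_simulate(x_profile, ub, ph, **sim_kwargs)
        except RuntimeError:
            trace.append(1e6)
            return 1e6
        if not sim.feasible.feasible:
            worst = min(v["magnitude"] for v in sim.feasible.violations)
            val = 1e6 * (1.0 + abs(worst))
            trace.append(val)
            return val
        S = similarity_S(sim.rate_series(), rE)
        val = -S if objective == "maximize_S" else sim.cost
        trace.append(val)
        if val < best["value"]:
            best.update(value=val, sample=sample, S=S, cost=sim.cost)
        return val

    start = objective_fn(x0)
    if start >= 1e6:
        raise RuntimeError("initial point is infeasible; widen the search or "
                           "pick a feasible init")
    res = minimize(objective_fn, x0, method="Nelder-Mead",
                   options={"maxiter": maxiter, "xatol": 1e-3, "fatol": 1e-5})
    if best["sample"] is None:
        raise RuntimeError("no feasible point found during optimization")
    return {"best_sample": best["sample"], "objective": objective,
            "objective_value": best["value"], "S": best["S"],
            "cost": best["cost"], "n_eval": len(trace), "trace": trace,
            "converged": bool(res.success)}


def cost_similarity_association(records: list[ScanRecord]) -> dict:
    """Spearman rho between similarity S and proteosynthetic cost.

    Only feasible records enter; a constant S or cost column makes rho
    undefined and is flagged instead of silently returning a number.
    """
    feas = [r for r in records if r.feasible and r.S is not None]
    if len(feas) < 10:
        raise ValueError(f"need >= 10 feasible records, got {len(feas)}")
    S = np.array([r.S for r in feas])
    cost = np.array([r.cost for r in feas])
    table = pd.DataFrame({"index": [r.index for r in feas], "S": S, "cost": cost})
    if np.ptp(S) == 0 or np.ptp(cost) == 0:
        return {"spearman_rho": float("nan"), "flag": "constant-input",
                "table": table}
    rho = float(spearmanr(S, cost).statistic)
    return {"spearman_rho": rho, "flag": "ok", "table": table}
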