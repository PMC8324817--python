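"""Profile-constrained simulation: hold x(t) fixed, recover r(t) and g(t).

Changing a kinetic parameter normally changes both the degradation rate
r(t) and the abundance profile x(t), which confounds any analysis of how
proteolytic activity shapes degradation rhythmicity.  The constrained
technique removes the confound: the total protein profile x(t) is held
exactly at a prescribed periodic waveform, the free-substrate component
x0 is eliminated through x0 = x - (sum of the remaining components), and
only the remaining components are integrated to their periodic steady
state.  The synthesis profile that would sustain this solution is then
read off the balance equation, g(t) = x'(t) + r(t) x(t).

A parameter set is *biologically infeasible* for a profile whenever the
converged solution drives any of g(t), x0(t), or a free-enzyme
concentration to zero or below: the prescribed oscillation simply cannot
be maintained with that little enzyme.  This is the mechanism behind the
feasibility floor U >~ Rmax.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.integrate import solve_ivp

from rhythmdeg.models import SimResult, _dispatch_rhs, _r0_weights, _ub_mask, state_names
from rhythmdeg.params import MultiRouteParams, PER2Params, PhosphoParams, UbParams
from rhythmdeg.waveform import PeriodicProfile, RateSeries, alpha_D

__all__ = ["FeasibilityVerdict", "constrained_simulate", "alpha_and_cost"]

#: quantities dip this far below zero (relative to their scale) before
#: counting as violations; the screen itself is a strict "<= 0" rule
FEASIBILITY_MARGIN = 1e-9


@dataclass
class FeasibilityVerdict:
    """Outcome of the biological-feasibility screen."""

    feasible: bool
    violations: list = field(default_factory=list)

    def reason(self) -> str:
        if self.feasible:
            return "feasible"
        worst = min(self.violations, key=lambda v: v["magnitude"])
        return (f"{worst['quantity']} <= 0 at t={worst['time']:.2f} h "
                f"(magnitude {worst['magnitude']:.3g})")


def _constrained_rhs(x_profile: PeriodicProfile, params, phospho):
    """RHS over the reduced state (x0 eliminated by conservation)."""
    forward = _dispatch_rhs(params, phospho)
    zero_g = lambda t: 0.0

    def fun(t, reduced):
        x0 = x_profile(t) - reduced.sum()
        full = np.concatenate([[x0], reduced])
        d = forward(t, full, zero_g)
        return d[1:]

    return fun


def constrained_simulate(
    x_profile: PeriodicProfile,
    params,
    phospho: PhosphoParams | None = None,
    max_periods: int = 50,
    convergence_tol: float = 1e-4,
    rtol: float = 1e-5,
    atol: float = 1e-5,
    n_out: int = 241,
    method: str = "LSODA",
    raise_on_nonconvergence: bool = True,
    init_reduced=None,
) -> SimResult:
    """Integrate the reduced system to its periodic steady state.

    Starts from all complexes empty (so x0(0) = x(0)) and runs period by
    period until the relative sup-norm change of the reduced state across
    a period boundary drops below ``convergence_tol``.  The returned
    :class:`SimResult` covers the final period and carries a
    :class:`FeasibilityVerdict` for g(t), x0(t) and every free-enzyme
    pool.
    """
    names = state_names(params, phospho)
    period = x_profile.period
    fun = _constrained_rhs(x_profile, params, phospho)
    reduced = (np.zeros(len(names) - 1) if init_reduced is None
               else np.asarray(init_reduced, dtype=float))

    conv = np.inf
    k = 0
    xscale = float(np.max(x_profile(np.linspace(0, period, 241))))
    for k in range(1, max_periods + 1):
        sol = solve_ivp(fun, (0.0, period), reduced, method=method,
                        rtol=rtol, atol=atol)
        if not sol.success:
            raise RuntimeError(
                f"constrained integration failed in period {k}: {sol.message}")
        new = sol.y[:, -1]
        # residual relative to the profile scale: component changes far
        # below x(t) cannot move r(t) or the feasibility screen
        conv = float(np.max(np.abs(new - reduced)) / xscale)
        reduced = new
        if conv < convergence_tol and k >= 2:
            break
    else:
        if raise_on_nonconvergence:
            raise RuntimeError(
                f"no periodic steady state after {max_periods} periods "
                f"(residual {conv:.3g})")

    t_out = np.linspace(0.0, period, n_out)
    sol = solve_ivp(fun, (0.0, period), reduced, method=method,
                    rtol=rtol, atol=atol, t_eval=t_out)
    if not sol.success:
        raise RuntimeError(f"constrained output pass failed: {sol.message}")

    x = np.asarray(x_profile(t_out), dtype=float)
    x0 = x - sol.y.sum(axis=0)
    comp = np.vstack([x0, sol.y])
    w = _r0_weights(params, phospho)
    r = (w @ comp) / x
    D = comp[_ub_mask(names)].sum(axis=0) / x
    g = np.asarray(x_profile.derivative(t_out), dtype=float) + r * x
    verdict = _screen(t_out, comp, names, params, g, xscale, atol)
    cost = float(np.trapezoid(r * x, t_out) / period)
    try:
        aD = alpha_D(RateSeries(t_out[:-1], np.maximum(r[:-1], 0.0), period))
    except ValueError:
        aD = float("nan")
    return SimResult(times=t_out, components=comp, names=names, x=x, r=r, g=g,
                     D=D, feasible=verdict, alpha_D=aD, cost=cost,
                     periods_run=k, convergence=conv, period=period)


def _screen(t_out, comp, names, params, g, xscale, atol) -> FeasibilityVerdict:
    """Flag g, x0 and free-enzyme pools that hit zero or below."""
    checks: list[tuple[str, np.ndarray, float]] = []
    x0 = comp[names.index("x0")]
    r0max = _max_r0(params)
    checks.append(("g", g, r0max * xscale))
    checks.append(("x0", x0, xscale))

    def pool(label, total, bound_rows):
        if total > 0:
            free = total - comp[bound_rows].sum(axis=0)
            checks.append((label, free, total))

    if isinstance(params, UbParams):
        pool("u", params.u_bar, [names.index("xE0"), names.index("xEub")])
        pool("v", params.v_bar, [names.index("xHub")])
    elif isinstance(params, MultiRouteParams):
        for i, rt in enumerate(params.routes, start=1):
            pool(f"u{i}", rt.u_bar,
                 [names.index(f"x{i}E0"), names.index(f"x{i}Eub")])
            pool(f"v{i}", rt.v_bar, [names.index(f"x{i}Hub")])
    elif isinstance(params, PER2Params):
        rows_u = [names.index(f"x{i}{c}") for i in range(5) for c in ("E0", "Eub")]
        rows_v = [names.index(f"x{i}Hub") for i in range(5)]
        pool("u", params.u_bar, rows_u)
        pool("v", params.v_bar, rows_v)
        pool("u_beta", params.u_bar_beta,
             [names.index("xbE0"), names.index("xbEub")])
        pool("v_beta", params.v_bar_beta, [names.index("xbHub")])

    violations = []
    for label, series, scale in checks:
        tol = -FEASIBILITY_MARGIN * max(scale, atol)
        below = series <= tol
        if np.any(below):
            i = int(np.argmax(below))
            violations.append({"quantity": label, "time": float(t_out[i]),
                               "magnitude": float(series.min())})
    return FeasibilityVerdict(feasible=not violations, violations=violations)


def _max_r0(params) -> float:
    if isinstance(params, UbParams):
        return params.r0
    if isinstance(params, MultiRouteParams):
        return max(rt.r0 for rt in params.routes)
    if isinstance(params, PER2Params):
        return max([blk.r0 for blk in params.state_blocks] + [params.beta_block.r0])
    raise TypeError(type(params).__name__)


def alpha_and_cost(x_profile: PeriodicProfile, params,
                   phospho: PhosphoParams | None = None, **kwargs) -> dict:
    """Convenience scan statistic: {feasible, alpha_D, cost}.

    Infeasibility (including integration failure) is returned as a tagged
    result rather than raised, so parameter sweeps never abort.
    """
    try:
        sim = constrained_simulate(x_profile, params, phospho, **kwargs)
    except RuntimeError as exc:
        return {"feasible": False, "alpha_D": None, "cost": None,
                "reason": str(exc)}
    if not sim.feasible.feasible:
        return {"feasible": False, "alpha_D": None, "cost": None,
                "reason": sim.feasible.reason()}
    return {"feasible": True, "alpha_D": sim.alpha_D, "cost": sim.cost,
            "reason": "feasible"}
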