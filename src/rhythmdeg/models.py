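"""Mass-action ODE models of (phospho-dependent) ubiquitination.

Four variants share a common skeleton.  A substrate protein is produced
at rate g(t); the ubiquitination branch is

    x0 --(a0 u)--> xE,0 --(q)--> xE,ub --(a2)--> x0,ub
                                     \\                \\
                                      r0               r0, DUB cycle via xH,ub

with free-ligase concentration u(t) = u_bar - xE,0 - xE,ub and free
deubiquitinase v(t) = v_bar - xH,ub eliminated through the constant
enzyme totals.  The phospho-dependent variants prepend a kinase /
phosphatase chain x0 <-> xp1 <-> ... <-> xpn so that only the fully
phosphorylated form binds the ligase.  The multi-route variant gives
every phospho-form its own ligase block; the PER2 variant adds a
separate beta-TrCP phospho-site and ligase pool on top of the four-site
FASP chain.

The realized degradation rate is always
``r(t) = sum(r0_i * ubiquitinated components_i) / x(t) <= max_i r0_i``.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp

from rhythmdeg.params import UbParams, PhosphoParams, MultiRouteParams, PER2Params
from rhythmdeg.waveform import RateSeries, alpha_D

__all__ = [
    "SimResult",
    "rhs_phospho_independent",
    "rhs_phospho_dependent",
    "rhs_multiroute",
    "rhs_per2",
    "state_names",
    "ubiquitinated_total",
    "forward_simulate",
]


# ----------------------------------------------------------------------
# state layout


def state_names(params, phospho: PhosphoParams | None = None) -> list[str]:
    """Component names in canonical order for the given model variant."""
    if isinstance(params, UbParams):
        if phospho is None or phospho.n == 0:
            return ["x0", "xE0", "xEub", "x0ub", "xHub"]
        chain = [f"xp{i}" for i in range(1, phospho.n + 1)]
        return ["x0", *chain, "xE0", "xEub", "x0ub", "xHub"]
    if isinstance(params, MultiRouteParams):
        names = ["x0"] + [f"xp{i}" for i in range(1, 5)]
        for i in range(1, 5):
            names += [f"x{i}E0", f"x{i}Eub", f"x{i}0ub", f"x{i}Hub"]
        return names
    if isinstance(params, PER2Params):
        names = ["x0"] + [f"xp{i}" for i in range(1, 5)]
        for i in range(0, 5):
            names += [f"x{i}E0", f"x{i}Eub", f"x{i}0ub", f"x{i}Hub"]
        names += ["xpb", "xbE0", "xbEub", "xb0ub", "xbHub"]
        return names
    raise TypeError(f"unsupported parameter type {type(params).__name__}")


def _r0_weights(params, phospho: PhosphoParams | None = None) -> np.ndarray:
    """Per-component r0 weight so that r(t) x(t) = weights . state."""
    names = state_names(params, phospho)
    w = np.zeros(len(names))
    if isinstance(params, UbParams):
        for comp in ("xEub", "x0ub", "xHub"):
            w[names.index(comp)] = params.r0
    elif isinstance(params, MultiRouteParams):
        for i, rt in enumerate(params.routes, start=1):
            for comp in (f"x{i}Eub", f"x{i}0ub", f"x{i}Hub"):
                w[names.index(comp)] = rt.r0
    elif isinstance(params, PER2Params):
        for i, blk in enumerate(params.state_blocks):
            for comp in (f"x{i}Eub", f"x{i}0ub", f"x{i}Hub"):
                w[names.index(comp)] = blk.r0
        for comp in ("xbEub", "xb0ub", "xbHub"):
            w[names.index(comp)] = params.beta_block.r0
    return w


def ubiquitinated_total(state: np.ndarray, params, phospho=None) -> float:
    """r0-weighted ubiquitinated pool: equals r(t) * x(t)."""
    return float(_r0_weights(params, phospho) @ np.asarray(state))


# ----------------------------------------------------------------------
# right-hand sides (forward form: x0 is an explicit state, g supplied)


def rhs_phospho_independent(state, t, params: UbParams, g: Callable) -> np.ndarray:
    """Time derivative of (x0, xE0, xEub, x0ub, xHub)."""
    x0, xE0, xEub, x0ub, xHub = state
    p = params
    u = p.u_bar - xE0 - xEub
    v = p.v_bar - xHub
    bind = p.a0 * u * x0
    bind_ub = p.a0 * u * x0ub
    dxb = p.b0 * v * x0ub
    return np.array([
        g(t) - bind + p.a1 * xE0 + p.s * xHub,
        bind - (p.a1 + p.q) * xE0,
        p.q * xE0 + bind_ub - (p.a2 + p.r0) * xEub,
        p.a2 * xEub + p.b1 * xHub - dxb - bind_ub - p.r0 * x0ub,
        dxb - (p.b1 + p.s + p.r0) * xHub,
    ])


def rhs_phospho_dependent(state, t, params: UbParams, phospho: PhosphoParams,
                          g: Callable) -> np.ndarray:
    """Derivative of (x0, xp1..xpn, xE0, xEub, x0ub, xHub) for n >= 1."""
    n = phospho.n
    if n < 1:
        raise ValueError("phospho-dependent RHS requires n >= 1")
    if len(state) != n + 5:
        raise ValueError(f"state dimension {len(state)} does not match n={n}")
    p, ph = params, phospho
    x0 = state[0]
    xp = state[1:1 + n]
    xE0, xEub, x0ub, xHub = state[1 + n:]
    u = p.u_bar - xE0 - xEub
    v = p.v_bar - xHub
    y, z = ph.y, ph.z
    k, l = ph.k, ph.l

    d = np.zeros(n + 5)
    d[0] = g(t) - k[0] * y * x0 + l[0] * z * xp[0]
    # chain: xp[i-1] is the i-th phospho form
    for i in range(n):
        up = k[i] * y * (x0 if i == 0 else xp[i - 1])
        down = l[i] * z * xp[i]
        d[1 + i] += up - down
        if i + 1 < n:
            d[1 + i] += l[i + 1] * z * xp[i + 1] - k[i + 1] * y * xp[i]
    # ligase acts on the fully phosphorylated form xp[n-1]
    bind = p.a0 * u * xp[n - 1]
    d[n] += -bind + p.a1 * xE0 + p.s * xHub
    bind_ub = p.a0 * u * x0ub
    dxb = p.b0 * v * x0ub
    d[1 + n] = bind - (p.a1 + p.q) * xE0
    d[2 + n] = p.q * xE0 + bind_ub - (p.a2 + p.r0) * xEub
    d[3 + n] = p.a2 * xEub + p.b1 * xHub - dxb - bind_ub - p.r0 * x0ub
    d[4 + n] = dxb - (p.b1 + p.s + p.r0) * xHub
    return d


def rhs_multiroute(state, t, params: MultiRouteParams, g: Callable) -> np.ndarray:
    """Derivative for the four-route model (x0, xp1..4, four ligase blocks)."""
    ph = params.phospho
    y, z = ph.y, ph.z
    k, l = ph.k, ph.l
    x0 = state[0]
    xp = state[1:5]
    blocks = state[5:].reshape(4, 4)  # rows: route i; cols xE0, xEub, x0ub, xHub

    d = np.zeros_like(np.asarray(state, dtype=float))
    dxp = np.zeros(4)
    d[0] = g(t) - k[0] * y * x0 + l[0] * z * xp[0]
    for i in range(4):
        up = k[i] * y * (x0 if i == 0 else xp[i - 1])
        dxp[i] += up - l[i] * z * xp[i]
        if i + 1 < 4:
            dxp[i] += l[i + 1] * z * xp[i + 1] - k[i + 1] * y * xp[i]

    dblocks = np.zeros_like(blocks)
    for i, rt in enumerate(params.routes):
        xE0, xEub, x0ub, xHub = blocks[i]
        u = rt.u_bar - xE0 - xEub
        v = rt.v_bar - xHub
        bind = rt.a0 * u * xp[i]
        bind_ub = rt.a0 * u * x0ub
        dxb = rt.b0 * v * x0ub
        dxp[i] += -bind + rt.a1 * xE0 + rt.s * xHub
        dblocks[i, 0] = bind - (rt.a1 + rt.q) * xE0
        dblocks[i, 1] = rt.q * xE0 + bind_ub - (rt.a2 + rt.r0) * xEub
        dblocks[i, 2] = rt.a2 * xEub + rt.b1 * xHub - dxb - bind_ub - rt.r0 * x0ub
        dblocks[i, 3] = dxb - (rt.b1 + rt.s + rt.r0) * xHub

    d[1:5] = dxp
    d[5:] = dblocks.ravel()
    return d


def rhs_per2(state, t, params: PER2Params, g: Callable) -> np.ndarray:
    """Derivative for the realistic PER2 model (FASP chain + beta-TrCP site).

    State order: x0, xp1..xp4, five FASP-state blocks (i=0..4, each
    xE0/xEub/x0ub/xHub drawing on the shared ligase pool u_bar), then
    xp_beta and the beta block on its own pool u_bar_beta.
    """
    ph = params.phospho
    y, z = ph.y, ph.z
    k, l = ph.k, ph.l
    x0 = state[0]
    xp = state[1:5]
    blocks = state[5:25].reshape(5, 4)
    xpb = state[25]
    beta = state[26:30]

    u = params.u_bar - blocks[:, 0].sum() - blocks[:, 1].sum()
    v = params.v_bar - blocks[:, 3].sum()
    ub = params.u_bar_beta - beta[0] - beta[1]
    vb = params.v_bar_beta - beta[3]

    d = np.zeros(30)
    # FASP chain
    d[0] = g(t) - k[0] * y * x0 + l[0] * z * xp[0] - params.k_beta * y * x0 \
        + params.l_beta * z * xpb
    dxp = np.zeros(4)
    for i in range(4):
        up = k[i] * y * (x0 if i == 0 else xp[i - 1])
        dxp[i] += up - l[i] * z * xp[i]
        if i + 1 < 4:
            dxp[i] += l[i + 1] * z * xp[i + 1] - k[i + 1] * y * xp[i]
    # per-state ubiquitination blocks, substrate of block i is the i-th form
    forms = [x0, *xp]
    dblocks = np.zeros_like(blocks)
    for i, blk in enumerate(params.state_blocks):
        xE0, xEub, x0ub, xHub = blocks[i]
        bind = blk.a0 * u * forms[i]
        bind_ub = blk.a0 * u * x0ub
        dxb = blk.b0 * v * x0ub
        back = blk.a1 * xE0 + blk.s * xHub
        if i == 0:
            d[0] += -bind + back
        else:
            dxp[i - 1] += -bind + back
        dblocks[i, 0] = bind - (blk.a1 + blk.q) * xE0
        dblocks[i, 1] = blk.q * xE0 + bind_ub - (blk.a2 + blk.r0) * xEub
        dblocks[i, 2] = blk.a2 * xEub + blk.b1 * xHub - dxb - bind_ub - blk.r0 * x0ub
        dblocks[i, 3] = dxb - (blk.b1 + blk.s + blk.r0) * xHub
    d[1:5] = dxp
    d[5:25] = dblocks.ravel()
    # beta-TrCP site
    bb = params.beta_block
    bindb = bb.a0 * ub * xpb
    bindb_ub = bb.a0 * ub * beta[2]
    dxbb = bb.b0 * vb * beta[2]
    d[25] = params.k_beta * y * x0 - params.l_beta * z * xpb - bindb \
        + bb.a1 * beta[0] + bb.s * beta[3]
    d[26] = bindb - (bb.a1 + bb.q) * beta[0]
    d[27] = bb.q * beta[0] + bindb_ub - (bb.a2 + bb.r0) * beta[1]
    d[28] = bb.a2 * beta[1] + bb.b1 * beta[3] - dxbb - bindb_ub - bb.r0 * beta[2]
    d[29] = dxbb - (bb.b1 + bb.s + bb.r0) * beta[3]
    return d


def _dispatch_rhs(params, phospho):
    if isinstance(params, UbParams):
        if phospho is None or phospho.n == 0:
            return lambda t, s, g: rhs_phospho_independent(s, t, params, g)
        return lambda t, s, g: rhs_phospho_dependent(s, t, params, phospho, g)
    if isinstance(params, MultiRouteParams):
        return lambda t, s, g: rhs_multiroute(s, t, params, g)
    if isinstance(params, PER2Params):
        return lambda t, s, g: rhs_per2(s, t, params, g)
    raise TypeError(f"unsupported parameter type {type(params).__name__}")


# ----------------------------------------------------------------------
# results container


@dataclass
class SimResult:
    """Final-period trajectory of one model run.

    Attributes
    ----------
    times : sample times on [0, T]
    components : component trajectories, one row per state in
        :func:`state_names` order
    names : component names
    x : total protein concentration
    r : realized degradation rate r0-weighted over ubiquitinated pools
    g : synthesis rate (supplied in forward mode, reconstructed in
        constrained mode)
    D : ubiquitinated fraction of the total protein
    feasible : None for forward runs, else a FeasibilityVerdict
    alpha_D : rhythmicity of r over the final period
    cost : proteosynthetic cost <r x> over the final period
    periods_run : periods integrated before convergence/exhaustion
    convergence : relative sup-norm change between the last two periods
    """

    times: np.ndarray
    components: np.ndarray
    names: list[str]
    x: np.ndarray
    r: np.ndarray
    g: np.ndarray
    D: np.ndarray
    feasible: object | None
    alpha_D: float
    cost: float
    periods_run: int
    convergence: float
    period: float = 24.0

    def rate_series(self) -> RateSeries:
        return RateSeries(self.times[:-1], np.maximum(self.r[:-1], 0.0), self.period)

    def component(self, name: str) -> np.ndarray:
        return self.components[self.names.index(name)]

    def to_frame(self) -> pd.DataFrame:
        """Tidy (time, component, value) export including x, r, g, D."""
        rows = []
        for name, traj in zip(self.names, self.components):
            rows.append(pd.DataFrame({"time_h": self.times, "component": name,
                                      "value": traj}))
        for name, traj in (("x", self.x), ("r", self.r), ("g", self.g), ("D", self.D)):
            rows.append(pd.DataFrame({"time_h": self.times, "component": name,
                                      "value": traj}))
        return pd.concat(rows, ignore_index=True)

    def summary(self) -> dict:
        return {
            "alpha_D": self.alpha_D,
            "cost": self.cost,
            "feasible": (True if self.feasible is None else bool(self.feasible.feasible)),
            "periods_run": self.periods_run,
            "convergence": self.convergence,
        }


# ----------------------------------------------------------------------
# forward integration


def forward_simulate(
    g: Callable,
    params,
    phospho: PhosphoParams | None = None,
    period: float = 24.0,
    n_periods: int = 10,
    rtol: float = 1e-5,
    atol: float = 1e-5,
    init: Sequence[float] | None = None,
    n_out: int = 241,
    convergence_tol: float = 1e-4,
    method: str = "LSODA",
) -> SimResult:
    """Integrate a model variant forward under a given synthesis profile.

    Runs period by period (default up to ``n_periods``) and exits early
    once the relative sup-norm change of the state between consecutive
    period boundaries drops below ``convergence_tol``; the last period is
    then re-integrated on a dense output grid.
    """
    names = state_names(params, phospho)
    rhs = _dispatch_rhs(params, phospho)
    fun = lambda t, s: rhs(t, s, g)
    state = np.zeros(len(names)) if init is None else np.asarray(init, dtype=float)
    if len(state) != len(names):
        raise ValueError(f"initial state must have dimension {len(names)}")

    prev = state.copy()
    conv = np.inf
    k = 0
    for k in range(1, n_periods + 1):
        sol = solve_ivp(fun, (0.0, period), state, method=method,
                        rtol=rtol, atol=atol, dense_output=False)
        if not sol.success:
            raise RuntimeError(f"forward integration failed in period {k}: {sol.message}")
        state = sol.y[:, -1]
        scale = max(float(np.max(np.abs(state))), atol)
        conv = float(np.max(np.abs(state - prev)) / scale)
        prev = state.copy()
        if conv < convergence_tol and k >= 2:
            break

    t_out = np.linspace(0.0, period, n_out)
    sol = solve_ivp(fun, (0.0, period), state, method=method,
                    rtol=rtol, atol=atol, t_eval=t_out)
    if not sol.success:
        raise RuntimeError(f"forward output pass failed: {sol.message}")
    comp = sol.y
    x = comp.sum(axis=0)
    w = _r0_weights(params, phospho)
    rx = w @ comp
    with np.errstate(divide="ignore", invalid="ignore"):
        r = np.where(x > 0, rx / np.maximum(x, 1e-300), 0.0)
        D = np.where(x > 0, comp[_ub_mask(names)].sum(axis=0) / np.maximum(x, 1e-300), 0.0)
    gv = np.asarray([g(t) for t in t_out], dtype=float)
    cost = float(np.trapezoid(r * x, t_out) / period)
    try:
        aD = alpha_D(RateSeries(t_out[:-1], np.maximum(r[:-1], 0), period))
    except ValueError:
        aD = float("nan")
    return SimResult(times=t_out, components=comp, names=names, x=x, r=r, g=gv,
                     D=D, feasible=None, alpha_D=aD, cost=cost, periods_run=k,
                     convergence=conv, period=period)


def _ub_mask(names: list[str]) -> np.ndarray:
    return np.array([n.endswith(("Eub", "0ub", "Hub")) for n in names])
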