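"""Dimensionless reduction and closed-form degradation-rate approximations.

With tau = r0 t, the ubiquitinated fraction D(tau) = r(t)/r0 obeys a
relaxation equation whose quasi-static fixed point yields closed forms in
the dimensionless enzyme activities

    U = (a0/r0) (q/(a1+q)) u_bar        (ubiquitin ligase)
    V = (b0/r0) ((r0+s)/(b1+r0+s)) v_bar (deubiquitinase)
    Y = (k/r0) y,  Z = (l/r0) z          (kinase / phosphatase)

and the scaled log-decline profile R(tau) = -(1/r0) x'(t)/x(t).  The
simplest form (pseudo-steady state, V=0, conditions (i)-(iv)) is

    D(tau) = { 1 + (1/U) [1 - R(tau)] }^-1,

rhythmic purely because R(tau) oscillates.  A Michaelis-Menten variant
covers substrate-saturation of the ligase, a mono-phosphorylation form
adds the kinase factor, and a multisite form (eta_n) shows that the
smallest K_i Y across phosphosites limits the attainable rhythmicity.
Since g >= 0 forces R <= D <= 1, each form implies the feasibility floor
U (and Y) >~ Rmax.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from rhythmdeg.params import PhosphoParams, UbParams
from rhythmdeg.waveform import PeriodicProfile, log_decline_rate, min_constant_rate

__all__ = [
    "DimensionlessParams",
    "RProfile",
    "to_dimensionless",
    "D_eq_basic",
    "D_eq_mm",
    "D_eq_mono",
    "D_multisite",
    "alphaD_closed_form",
    "check_validity_conditions",
    "feasibility_lower_bounds",
]


@dataclass
class DimensionlessParams:
    """Derived dimensionless quantities of one parameter set."""

    U: float
    V: float = 0.0
    Y: float = float("inf")
    Z: float = 0.0
    A: float = float("nan")  # r0 (a1+q) / [q (a2+r0)]
    B: float = float("nan")  # r0 / (a2+r0)
    Q: float = float("nan")  # s / (r0+s)
    K: tuple = field(default_factory=tuple)  # k_i / k_1, K_1 = 1
    q_over_r0: float = float("nan")
    X_scale: float = float("nan")  # (a0/r0) q/(a1+q), nM^-1


@dataclass
class RProfile:
    """Scaled log-decline profile R(tau) = -(1/r0) x'/x over one period."""

    times: np.ndarray
    R: np.ndarray
    Rmax: float
    Rmin: float
    r0: float


def to_dimensionless(
    params: UbParams,
    profile: PeriodicProfile | None = None,
    phospho: PhosphoParams | None = None,
) -> tuple[DimensionlessParams, RProfile | None]:
    """Map kinetic constants (and optionally a profile) to (U, V, Y, Z, ...)."""
    p = params
    if p.a1 + p.q <= 0:
        raise ValueError("a1 + q must be positive for the dimensionless map")
    x_scale = (p.a0 / p.r0) * (p.q / (p.a1 + p.q))
    U = x_scale * p.u_bar
    denom_v = p.b1 + p.r0 + p.s
    V = (p.b0 / p.r0) * ((p.r0 + p.s) / denom_v) * p.v_bar if denom_v > 0 else 0.0
    dp = DimensionlessParams(
        U=U,
        V=V,
        A=p.r0 * (p.a1 + p.q) / (p.q * (p.a2 + p.r0)),
        B=p.r0 / (p.a2 + p.r0),
        Q=p.s / (p.r0 + p.s),
        q_over_r0=p.q / p.r0,
        X_scale=x_scale,
    )
    if phospho is not None and phospho.n >= 1:
        k1 = phospho.k[0]
        dp.Y = (k1 / p.r0) * phospho.y
        dp.Z = (phospho.l[0] / p.r0) * phospho.z if phospho.l else 0.0
        dp.K = tuple(ki / k1 for ki in phospho.k)
    rp = None
    if profile is not None:
        tt = profile.grid(0.01)
        R = np.asarray(log_decline_rate(profile, tt)) / p.r0
        rp = RProfile(times=tt, R=R,
                      Rmax=min_constant_rate(profile) / p.r0,
                      Rmin=float(np.min(R)), r0=p.r0)
    return dp, rp


# ----------------------------------------------------------------------
# closed forms for the ubiquitinated fraction D


def D_eq_basic(R, U: float):
    """Pseudo-steady-state D = {1 + (1/U)(1-R)}^-1 (V = 0, phospho-free)."""
    if U <= 0:
        raise ValueError("U must be positive")
    R = np.asarray(R, dtype=float)
    out = 1.0 / (1.0 + (1.0 - R) / U)
    return out if out.ndim else float(out)


def D_eq_mm(R, X, U: float, r0_over_q: float):
    """Michaelis-Menten variant D = {1 + (1/U)(1-R)[1 + (r0/q)U + (r0/q)X]}^-1.

    Reduces to :func:`D_eq_basic` when U and X are both << q/r0.
    """
    if r0_over_q <= 0:
        raise ValueError("r0/q must be positive")
    R = np.asarray(R, dtype=float)
    X = np.asarray(X, dtype=float)
    out = 1.0 / (1.0 + (1.0 - R) / U * (1.0 + r0_over_q * U + r0_over_q * X))
    return out if out.ndim else float(out)


def D_eq_mono(R, U: float, Y: float):
    """Mono-phosphorylation D = {(1 + (1-R)/U)(1 - R/Y) + 1/Y}^-1.

    Y -> inf recovers :func:`D_eq_basic`; a finite kinase pool amplifies
    the rhythmicity carried by R.
    """
    if U <= 0 or Y <= 0:
        raise ValueError("U and Y must be positive")
    R = np.asarray(R, dtype=float)
    out = 1.0 / ((1.0 + (1.0 - R) / U) * (1.0 - R / Y) + 1.0 / Y)
    return out if out.ndim else float(out)


def _eta_n_normalized(R: np.ndarray, U: float, Y: float,
                      K: np.ndarray) -> np.ndarray:
    """eta_n(R) / prod_i(K_i Y), summed term by term.

    Dividing every term of the printed eta_n sum by the full product
    prod(K_i Y) turns each into a bounded combination of 1/(K_i Y) and
    (1 - R/(K_i Y)) factors, so the evaluation neither overflows for
    very fast kinetics nor loses the small-K_i Y terms that carry the
    rhythmicity.  Pairwise accumulation over the term list.
    """
    n = len(K)
    KY = K * Y
    core = (1.0 - R) * (U - R)
    terms = [U * np.ones_like(R), (1.0 - R)]
    if n == 1:
        terms.append(core / KY[0])
    else:
        # middle terms m = 2..n-1: core / (K_{n-m+2} Y) * prod tail factors
        for m in range(2, n):
            tail = np.prod([1.0 - R / KY[i - 1] for i in range(n - m + 3, n + 1)],
                           axis=0) if m > 2 else 1.0
            terms.append(core / KY[n - m + 1] * tail)
        tail = (np.prod([1.0 - R / KY[i - 1] for i in range(3, n + 1)], axis=0)
                if n > 2 else 1.0)
        merged = 1.0 / KY[1] + 1.0 / KY[0] - R / (KY[0] * KY[1])
        terms.append(core * merged * tail)
    total = terms[0]
    for t in terms[1:]:
        total = total + t
    return total


def D_multisite(R, U: float, Y: float, K) -> np.ndarray:
    """Multisite-phosphorylation D = U (prod K_i) Y^n / eta_n(R).

    ``K`` are the relative kinase binding rates K_i = k_i/k_1 (K_1 = 1).
    For n = 1 this is algebraically identical to :func:`D_eq_mono`.  The
    repeated factor (1 - R/(K_i Y)) makes the site with the smallest
    K_i Y the dominant source of temporal variation.
    """
    K = np.asarray(K, dtype=float)
    if len(K) < 1:
        raise ValueError("at least one phosphosite required")
    if not np.isclose(K[0], 1.0):
        raise ValueError("K_1 must be 1 (rates are relative to site 1)")
    if U <= 0 or Y <= 0:
        raise ValueError("U and Y must be positive")
    R = np.asarray(R, dtype=float)
    scalar = R.ndim == 0
    R = np.atleast_1d(R)
    out = U / _eta_n_normalized(R, U, Y, K)
    return float(out[0]) if scalar else out


def alphaD_closed_form(Rmax: float, Rmin: float | None, U: float) -> float:
    """Closed-form rhythmicity alpha_D = (Rmax - Rmin) / (U + 1 - Rmin).

    Pass ``Rmin=None`` for the symmetric-profile shortcut Rmin = -Rmax,
    giving alpha_D = 2 Rmax / (U + 1 + Rmax).
    """
    if Rmin is None:
        Rmin = -Rmax
    denom = U + 1.0 - Rmin
    if denom <= 0:
        raise ValueError("U + 1 - Rmin must be positive")
    return (Rmax - Rmin) / denom


# ----------------------------------------------------------------------
# validity conditions and feasibility bounds


def check_validity_conditions(
    params: UbParams,
    profile: PeriodicProfile,
    margin: float = 0.1,
    sim=None,
) -> dict:
    """Evaluate the "much less than" conditions behind the closed forms.

    Conditions (i)-(iv) justify the pseudo-steady-state form
    :func:`D_eq_basic`; (v)-(vii) justify the Michaelis-Menten form
    :func:`D_eq_mm`.  Each condition is reported as a computed ratio that
    must not exceed ``margin`` ("<<" operationalized as ratio <= margin).
    Deubiquitinase-free models (v_bar = 0) skip the 1/s and DUB clauses.
    Condition (vi) compares the bound-ubiquitinated to bound-unmodified
    pools; it uses the trajectory maximum when a simulation result is
    supplied and the steady-state surrogate q/(a2+r0) otherwise.
    """
    p = params
    dp, rp = to_dimensionless(p, profile)
    T = profile.period
    tt = profile.grid(0.05)
    X = dp.X_scale * np.asarray(profile(tt), dtype=float)
    maxX = float(np.max(X))
    minX = float(np.min(X))
    has_dub = p.v_bar > 0

    conds = {}

    def record(name, ratio, note=""):
        conds[name] = {"ratio": float(ratio), "passes": bool(ratio <= margin),
                       "note": note}

    # (i) complex turnover fast on the period timescale
    taus = [1.0 / p.q, 1.0 / p.a2] + ([1.0 / p.s] if has_dub and p.s > 0 else [])
    record("i", max(taus) / T, "max(1/q, 1/a2, 1/s) << T")
    # (ii) ligase pool small against ubiquitination speed
    record("ii", dp.U / dp.q_over_r0, "U << q/r0")
    # (iii) deubiquitinase pool small
    record("iii", dp.V * p.r0 / (p.r0 + p.s), "V << (r0+s)/r0")
    # (iv) substrate does not saturate the enzymes
    bounds = [dp.q_over_r0, ((p.a2 + p.r0) / p.r0) * (p.q / (p.a1 + p.q))]
    if has_dub and p.b0 > 0:
        bounds.append((p.a0 / p.b0) * ((p.b1 + p.r0 + p.s) / p.r0)
                      * (p.q / (p.a1 + p.q)))
    record("iv", maxX / min(bounds), "max X << enzyme-saturation bounds")
    # (v) ubiquitination fast on the period timescale
    record("v", (1.0 / p.q) / T, "1/q << T")
    # (vi) ligase-bound pool dominated by the un-ubiquitinated complex
    if sim is not None:
        xE0 = sim.component("xE0")
        xEub = sim.component("xEub")
        ratio_vi = float(np.max(xEub / np.maximum(xE0, 1e-300)))
        note = "max xEub/xE0 << 1 (from simulation)"
    else:
        ratio_vi = p.q / (p.a2 + p.r0)
        note = "q/(a2+r0) << 1 (steady-state surrogate)"
    record("vi", ratio_vi, note)
    # (vii) either saturation regime
    r1 = maxX / (dp.U + dp.q_over_r0)
    r2 = dp.U / (minX + dp.q_over_r0)
    record("vii", min(r1, r2), "max X << U + q/r0  or  U << min X + q/r0")

    conds["eq_basic_ok"] = all(conds[c]["passes"] for c in ("i", "ii", "iii", "iv"))
    conds["eq_mm_ok"] = all(conds[c]["passes"] for c in ("v", "vi", "vii"))
    conds["margin"] = margin
    conds["U"] = dp.U
    conds["Rmax"] = rp.Rmax if rp is not None else float("nan")
    return conds


def feasibility_lower_bounds(profile: PeriodicProfile, r0: float) -> dict:
    """Common floor Rmax for the dimensionless ligase and kinase activities.

    Maintaining the prescribed waveform requires U >= ~Rmax (and, with
    phospho-dependent ubiquitination, Y >= ~Rmax): below it the screen in
    :func:`rhythmdeg.constrained.constrained_simulate` reports
    infeasibility.
    """
    if r0 <= 0:
        raise ValueError("r0 must be positive")
    rmax = min_constant_rate(profile) / r0
    return {"U_min": rmax, "Y_min": rmax}
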