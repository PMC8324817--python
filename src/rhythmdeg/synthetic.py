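"""Synthetic-data generators for every analysis stage.

The generators emulate the statistical structure the pipeline assumes
without mimicking any particular organism's waveforms: ~24-h strictly
positive periodic profiles with controllable mean, relative amplitude,
sharpness and asymmetry (hence controllable Rmax); noisy replicated
samplings of such profiles (multiplicative lognormal noise, as befits
ratio-scale abundance data); ground-truth degradation-rate observations
from the constrained simulation; and proteome tables whose abundance
distribution follows a truncated power law P(chi) ~ chi^-gamma with
tunable coupling between phospho labels, abundance and waveform
sharpness.  All generators are pure functions of (spec, seed).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from rhythmdeg.constrained import constrained_simulate
from rhythmdeg.fitting import EmpiricalSeries
from rhythmdeg.models import SimResult
from rhythmdeg.proteome import (CHI_MAX_DEFAULT, CHI_MIN_DEFAULT,
                                ProteomeRecord, protein_cg)
from rhythmdeg.waveform import PeriodicProfile, min_constant_rate

__all__ = [
    "WaveformSpec",
    "ProteomeSpec",
    "make_profile",
    "profile_with_target_Rmax",
    "make_noisy_timeseries",
    "make_degradation_truth",
    "make_synthetic_proteome",
]


@dataclass
class WaveformSpec:
    """Shape parameters of one synthetic circadian waveform."""

    mean: float = 1.0  # nM (or copies/cell for proteome series)
    rel_amplitude: float = 0.5  # b in (0, 1)
    sharpness: float = 1.0  # >= 1; sign-preserving power of the sinusoid
    asymmetry: float = 0.0  # in (-1, 1); smooth monotone time warp
    phase: float = 0.0  # hours
    period: float = 24.0

    def __post_init__(self):
        if not 0 < self.rel_amplitude < 1:
            raise ValueError("rel_amplitude must lie in (0, 1)")
        if self.sharpness < 1:
            raise ValueError("sharpness must be >= 1")
        if not -1 < self.asymmetry < 1:
            raise ValueError("asymmetry must lie in (-1, 1)")
        if self.mean <= 0 or self.period <= 0:
            raise ValueError("mean and period must be positive")


def make_profile(spec: WaveformSpec) -> PeriodicProfile:
    """Deterministic profile x(t) = mean * (1 + b * w(t)).

    w is a unit-amplitude sinusoid raised to ``sharpness`` with its sign
    preserved, on a time axis warped by the exactly periodic map
    t -> t + a * (T / 2 pi) * sin(2 pi t / T).
    """
    T = spec.period
    omega = 2.0 * np.pi / T
    a = spec.asymmetry

    def shape(t):
        tw = t + a * np.sin(omega * t) / omega
        s = np.sin(omega * (tw - spec.phase))
        return np.sign(s) * np.abs(s) ** spec.sharpness

    tt = np.linspace(0.0, T, 2401, endpoint=False)
    vals = spec.mean * (1.0 + spec.rel_amplitude * shape(tt))
    if np.any(vals <= 0):
        raise ValueError("waveform spec produces a non-positive profile")
    return PeriodicProfile.from_samples(tt, vals, period=T)


def profile_with_target_Rmax(
    target_Rmax: float,
    r0: float,
    mean: float = 1.0,
    period: float = 24.0,
    tol: float = 1e-3,
) -> PeriodicProfile:
    """Waveform whose scaled decline peak Rmax matches a target.

    Bisects the relative amplitude b of a sinusoid (then, if b alone
    cannot reach the target, the sharpness at b = 0.95) until
    |Rmax - target| < ``tol``.  Useful for boundary tests of the
    feasibility floor U >~ Rmax.
    """
    if not 0 < target_Rmax < 1:
        raise ValueError("target_Rmax must lie in (0, 1)")
    if r0 <= 0:
        raise ValueError("r0 must be positive")

    def rmax_of(b, sharp=1.0):
        prof = make_profile(WaveformSpec(mean=mean, rel_amplitude=b,
                                         sharpness=sharp, period=period))
        return min_constant_rate(prof) / r0, prof

    lo, hi = 1e-4, 0.95
    r_lo, _ = rmax_of(lo)
    r_hi, prof_hi = rmax_of(hi)
    if target_Rmax <= r_hi:
        if r_lo > target_Rmax:
            raise ValueError(
                f"target below attainable range [{r_lo:.3g}, {r_hi:.3g}]")
        for _ in range(60):
            mid = 0.5 * (lo + hi)
            r_mid, prof = rmax_of(mid)
            if abs(r_mid - target_Rmax) < tol:
                return prof
            if r_mid < target_Rmax:
                lo = mid
            else:
                hi = mid
        raise RuntimeError("amplitude bisection did not converge")
    # sharpen at b = 0.95
    s_lo, s_hi = 1.0, 8.0
    r_sh, _ = rmax_of(0.95, s_hi)
    if target_Rmax > r_sh:
        raise ValueError(
            f"target {target_Rmax:.3g} unreachable; attainable up to {r_sh:.3g} "
            f"at this r0 and period")
    for _ in range(60):
        mid = 0.5 * (s_lo + s_hi)
        r_mid, prof = rmax_of(0.95, mid)
        if abs(r_mid - target_Rmax) < tol:
            return prof
        if r_mid < target_Rmax:
            s_lo = mid
        else:
            s_hi = mid
    raise RuntimeError("sharpness bisection did not converge")


def make_noisy_timeseries(profile: PeriodicProfile, times, cv: float,
                          n_replicates: int, seed: int,
                          kind: str = "abundance") -> EmpiricalSeries:
    """Replicated samples with multiplicative lognormal noise of a given CV."""
    if cv < 0:
        raise ValueError("cv must be >= 0")
    times = np.asarray(times, dtype=float)
    rng = np.random.default_rng(seed)
    t_all, v_all, rep_all = [], [], []
    sigma = np.sqrt(np.log1p(cv ** 2))
    for k in range(1, n_replicates + 1):
        base = np.asarray(profile(times), dtype=float)
        if cv > 0:
            noise = rng.lognormal(mean=-0.5 * sigma ** 2, sigma=sigma,
                                  size=len(times))
        else:
            noise = np.ones(len(times))
        t_all.append(times)
        v_all.append(base * noise)
        rep_all.append(np.full(len(times), k))
    return EmpiricalSeries(np.concatenate(t_all), np.concatenate(v_all),
                           np.concatenate(rep_all), kind=kind,
                           period=profile.period, periodic=True)


def make_degradation_truth(x_profile: PeriodicProfile, params, phospho=None,
                           obs_times=None, noise_cv: float = 0.0,
                           seed: int = 0) -> tuple[SimResult, EmpiricalSeries]:
    """Ground-truth constrained simulation plus noisy rate observations."""
    sim = constrained_simulate(x_profile, params, phospho)
    if not sim.feasible.feasible:
        raise ValueError(f"parameters infeasible for this profile: "
                         f"{sim.feasible.reason()}")
    if obs_times is None:
        obs_times = np.arange(2.0, x_profile.period, 4.0)
    obs_times = np.asarray(obs_times, dtype=float)
    r_true = np.interp(obs_times, sim.times, sim.r)
    rng = np.random.default_rng(seed)
    if noise_cv > 0:
        sigma = np.sqrt(np.log1p(noise_cv ** 2))
        r_obs = r_true * rng.lognormal(-0.5 * sigma ** 2, sigma, len(obs_times))
    else:
        r_obs = r_true
    series = EmpiricalSeries(obs_times, r_obs,
                             np.ones(len(obs_times), dtype=int), kind="rate",
                             period=x_profile.period, periodic=True)
    return sim, series


@dataclass
class ProteomeSpec:
    """Stated world of one synthetic proteome table.

    Abundances follow the truncated power law with exponent ``gamma`` on
    [chi_min, chi_max]; a fraction of proteins oscillates and carries a
    generated waveform series; phospho labels are drawn from a logit
    model so that zero coupling coefficients give an exchangeable null.
    """

    n_proteins: int = 1000
    gamma: float = 1.0
    chi_min: float = CHI_MIN_DEFAULT
    chi_max: float = CHI_MAX_DEFAULT
    oscillating_fraction: float = 0.05
    phospho_base_rate: float = 0.434
    abundance_coeff: float = 0.0  # logit units per SD of log-abundance
    rmax_coeff: float = 0.0  # logit units per SD of decline-peak rank
    noise_cv: float = 0.1
    sample_times: tuple = tuple(np.arange(0.0, 24.0, 3.0))
    n_replicates: int = 2
    seed: int = 0

    def __post_init__(self):
        if not 0 < self.phospho_base_rate < 1:
            raise ValueError("phospho_base_rate must lie in (0, 1)")
        if not 0 <= self.oscillating_fraction <= 1:
            raise ValueError("oscillating_fraction must lie in [0, 1]")
        if self.chi_min >= self.chi_max or self.chi_min <= 0:
            raise ValueError("need 0 < chi_min < chi_max")


def sample_truncated_powerlaw(n: int, gamma: float, chi_min: float,
                              chi_max: float, rng) -> np.ndarray:
    """Inverse-CDF draws from P(chi) ~ chi^-gamma on [chi_min, chi_max]."""
    u = rng.uniform(size=n)
    if abs(gamma - 1.0) < 1e-12:
        return chi_min * (chi_max / chi_min) ** u
    e = 1.0 - gamma
    return (chi_min ** e + u * (chi_max ** e - chi_min ** e)) ** (1.0 / e)


def make_synthetic_proteome(spec: ProteomeSpec
                            ) -> tuple[list[ProteomeRecord], dict]:
    """Generate proteome records plus the ground-truth coupling record.

    Oscillating proteins receive a noisy replicated waveform series (and
    hence a computable cg); phospho labels follow
    logit p = logit(base) + abundance_coeff * z(log chi)
                          + rmax_coeff * z(decline peak),
    with both z-scores standardized within the table and the decline
    term zero for non-oscillating proteins.  With both coefficients zero
    the labels are independent of everything: the exchangeable null.
    """
    rng = np.random.default_rng(spec.seed)
    chi = sample_truncated_powerlaw(spec.n_proteins, spec.gamma,
                                    spec.chi_min, spec.chi_max, rng)
    n_osc = int(round(spec.oscillating_fraction * spec.n_proteins))
    osc_idx = rng.choice(spec.n_proteins, size=n_osc, replace=False)
    oscillating = np.zeros(spec.n_proteins, dtype=bool)
    oscillating[osc_idx] = True

    records: list[ProteomeRecord] = []
    decline_peak = np.zeros(spec.n_proteins)
    series_list: list[EmpiricalSeries | None] = [None] * spec.n_proteins
    for i in osc_idx:
        wf = WaveformSpec(
            mean=1.0,
            rel_amplitude=float(rng.uniform(0.2, 0.8)),
            sharpness=float(rng.uniform(1.0, 3.0)),
            asymmetry=float(rng.uniform(-0.5, 0.5)),
            phase=float(rng.uniform(0.0, 24.0)),
        )
        profile = make_profile(wf)
        decline_peak[i] = min_constant_rate(profile)
        series_list[i] = make_noisy_timeseries(
            profile, np.asarray(spec.sample_times), spec.noise_cv,
            spec.n_replicates, seed=int(rng.integers(0, 2 ** 31)))

    logit = np.log(spec.phospho_base_rate / (1 - spec.phospho_base_rate))
    zlog = (np.log(chi) - np.log(chi).mean())
    zlog = zlog / zlog.std() if zlog.std() > 0 else zlog
    # decline peaks are z-scored over the whole table (non-oscillating
    # proteins sit at 0), so a positive rmax_coeff both enriches
    # phosphoproteins among oscillators and tilts them toward sharp ones
    zdec = np.zeros(spec.n_proteins)
    if n_osc > 0 and decline_peak.std() > 0:
        zdec = (decline_peak - decline_peak.mean()) / decline_peak.std()
    eta = logit + spec.abundance_coeff * zlog + spec.rmax_coeff * zdec
    p = 1.0 / (1.0 + np.exp(-eta))
    phospho = rng.uniform(size=spec.n_proteins) < p

    for i in range(spec.n_proteins):
        rec = ProteomeRecord(id=f"P{i:05d}", mean_abundance=float(chi[i]),
                             oscillating=bool(oscillating[i]),
                             phospho=bool(phospho[i]),
                             series=series_list[i])
        rec.cg = protein_cg(rec)
        records.append(rec)

    truth = {"seed": spec.seed, "gamma": spec.gamma,
             "decline_peak": decline_peak, "phospho_prob": p,
             "oscillating_index": np.sort(osc_idx)}
    return records, truth
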