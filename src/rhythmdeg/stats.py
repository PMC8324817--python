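"""Randomization-based significance tests with a uniform p convention.

All tests report the add-one estimate p = (count + 1)/(N + 1), which can
never be literally zero; when the observed statistic beats every null
draw, the raw-fraction convention is reported alongside as a bound
string ("P<1e-4" for N = 1e4).  Ties between the observed and a null
statistic are resolved by a seeded uniform tie-break (lexicographic
comparison on (statistic, tie-break)), which makes the add-one p
*exactly* uniform under exchangeability even for coarse, discrete
statistics such as subset fractions; without it tied nulls would count
as exceedances and the tests would be conservative.  Every result
records its seed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.stats import spearmanr

__all__ = [
    "PermutationResult",
    "spearman_rho",
    "perm_test_spearman",
    "resample_test_enrichment",
    "perm_test_cg_monotonic",
    "test_cost_proximity",
]


@dataclass
class PermutationResult:
    observed: float
    n_null: int
    exceed_count: int
    p_value: float
    seed: int | None = None
    bound: str | None = None  # raw-fraction bound when count == 0

    def __post_init__(self):
        if self.exceed_count == 0 and self.bound is None:
            self.bound = f"P<{1.0 / self.n_null:g}"


def _finish(observed, count, n_null, seed) -> PermutationResult:
    return PermutationResult(observed=float(observed), n_null=int(n_null),
                             exceed_count=int(count),
                             p_value=(count + 1) / (n_null + 1), seed=seed)


def spearman_rho(xs, ys) -> float:
    """Rank correlation with average ranks for ties."""
    xs = np.asarray(xs, dtype=float)
    ys = np.asarray(ys, dtype=float)
    if len(xs) != len(ys) or len(xs) < 3:
        raise ValueError("need equal-length vectors with >= 3 entries")
    if np.ptp(xs) == 0 or np.ptp(ys) == 0:
        raise ValueError("spearman rho undefined for a constant vector")
    return float(spearmanr(xs, ys).statistic)


def perm_test_spearman(S_values, costs, n_perm: int = 10_000, seed: int = 0,
                       alternative: str = "less") -> PermutationResult:
    """One-tailed permutation test of the S-cost rank association.

    The null pairs the costs with randomly permuted S values.  The
    direction is fixed a priori: ``alternative='less'`` asks how often a
    null rho is at least as negative as the observed one (the direction
    of a cost-saving association), ``'greater'`` the reverse.
    """
    if n_perm < 100:
        raise ValueError("n_perm must be >= 100")
    if alternative not in ("less", "greater"):
        raise ValueError("alternative must be 'less' or 'greater'")
    S_values = np.asarray(S_values, dtype=float)
    costs = np.asarray(costs, dtype=float)
    obs = spearman_rho(S_values, costs)
    sign = 1.0 if alternative == "greater" else -1.0
    rng = np.random.default_rng(seed)
    u_obs = rng.uniform()
    count = 0
    for _ in range(n_perm):
        rho = sign * spearmanr(S_values, rng.permutation(costs)).statistic
        u = rng.uniform()
        if (rho, u) >= (sign * obs, u_obs):
            count += 1
    return _finish(obs, count, n_perm, seed)


def _phospho_flags(records) -> np.ndarray:
    return np.asarray([getattr(r, "phospho", r) for r in records], dtype=bool)


def resample_test_enrichment(all_records, oscillating_subset,
                             n_iter: int = 10_000, seed: int = 0
                             ) -> PermutationResult:
    """Phosphoprotein enrichment of the oscillating set by size-matched resampling.

    The null draws subsets of the same size uniformly (without
    replacement) from all detected proteins; a null fraction beating the
    observed one (ties broken by the seeded uniform) counts as
    exceedance.
    """
    if n_iter < 100:
        raise ValueError("n_iter must be >= 100")
    all_flags = _phospho_flags(all_records)
    sub_flags = _phospho_flags(oscillating_subset)
    if len(sub_flags) == 0:
        raise ValueError("empty oscillating subset")
    if len(sub_flags) > len(all_flags):
        raise ValueError("subset larger than the full set")
    obs = sub_flags.mean()
    rng = np.random.default_rng(seed)
    u_obs = rng.uniform()
    m = len(sub_flags)
    count = 0
    for _ in range(n_iter):
        f = rng.choice(all_flags, size=m, replace=False).mean()
        u = rng.uniform()
        if (f, u) >= (obs, u_obs):
            count += 1
    return _finish(obs, count, n_iter, seed)


def perm_test_cg_monotonic(records, bin_edges, n_iter: int = 10_000,
                           seed: int = 0, max_resample: int = 100
                           ) -> PermutationResult:
    """Positive cg-phospho association via cg-label permutation.

    cg values are permuted across proteins regardless of phospho label;
    for each permutation the phosphoprotein fraction is recomputed per
    ascending cg bin.  The counted event is that every adjacent-bin fold
    change of the permuted fractions is at least the corresponding
    observed fold change (all-adjacent dominance, the literal reading);
    an exactly tied fold-change vector is resolved by the seeded uniform
    tie-break, and undefined comparisons (0/0) void the event.  With two
    bins the event reduces to scalar exceedance and the p is exactly
    uniform under the null; with more bins the partial-order event makes
    the test conservative.  Permutations that empty a bin are redrawn
    (cg permutation preserves bin occupancy, so this only triggers for
    degenerate inputs).
    """
    if n_iter < 100:
        raise ValueError("n_iter must be >= 100")
    from rhythmdeg.proteome import ProteomeRecord  # cycle-free late import

    recs = [r for r in records if isinstance(r, ProteomeRecord)
            and r.cg is not None]
    if len(recs) < 2:
        raise ValueError("need >= 2 records with cg")
    cg = np.array([r.cg for r in recs])
    ph = np.array([r.phospho for r in recs], dtype=bool)
    edges = np.asarray(bin_edges, dtype=float)

    def fractions(cg_vec):
        idx = np.digitize(cg_vec, edges) - 1
        fr = np.full(len(edges) - 1, np.nan)
        for b in range(len(edges) - 1):
            sel = idx == b
            if sel.any():
                fr[b] = ph[sel].mean()
        return fr

    obs_fr = fractions(cg)
    if np.sum(~np.isnan(obs_fr)) < 2:
        raise ValueError("fewer than 2 non-empty cg bins")
    with np.errstate(divide="ignore", invalid="ignore"):
        obs_fold = obs_fr[1:] / obs_fr[:-1]
    obs_stat = (float(np.nanmin(obs_fold))
                if np.isfinite(obs_fold).any() else float("nan"))

    rng = np.random.default_rng(seed)
    u_obs = rng.uniform()
    count = 0
    for _ in range(n_iter):
        for _attempt in range(max_resample):
            fr = fractions(rng.permutation(cg))
            if np.isnan(fr).sum() <= np.isnan(obs_fr).sum():
                break
        else:
            warnings.warn("exhausted bin-resampling attempts")
        u = rng.uniform()
        with np.errstate(divide="ignore", invalid="ignore"):
            fold = fr[1:] / fr[:-1]
        ok = np.isfinite(fold) & np.isfinite(obs_fold)
        if not ok.any() or (np.isnan(fold) & np.isfinite(obs_fold)).any():
            continue
        if np.all(fold[ok] > obs_fold[ok]):
            count += 1
        elif np.all(fold[ok] >= obs_fold[ok]):
            # dominance with at least one exact tie: seeded tie-break
            if np.any(fold[ok] > obs_fold[ok]) or u >= u_obs:
                count += 1
    return _finish(obs_stat, count, n_iter, seed)


def test_cost_proximity(costs, focal_cost: float, reference_min_cost: float,
                        seed: int = 0) -> PermutationResult:
    """How unusually close the focal (largest-S) cost sits to the minimum cost.

    Empirical one-tailed probability that a scanned parameter set's cost
    is closer to the reference minimum than the focal cost is, add-one
    adjusted.  Not a permutation: the scan ensemble itself is the null.
    """
    costs = np.asarray(costs, dtype=float)
    if len(costs) == 0:
        raise ValueError("no costs supplied")
    if len(costs) < 100:
        warnings.warn(f"only {len(costs)} feasible records: low p resolution")
    rng = np.random.default_rng(seed)
    u_f = rng.uniform()
    u = rng.uniform(size=len(costs))
    d = np.abs(costs - reference_min_cost)
    d_f = abs(focal_cost - reference_min_cost)
    count = int(np.sum((d < d_f) | ((d == d_f) & (u < u_f))) )
    return _finish(focal_cost, count, len(costs), seed)
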