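"""Proteome-level biosynthetic cost accounting.

Every oscillating protein with a usable abundance time course gets a
constant-rate cost bound

    cg = max_t[-x'(t)/x(t)] * chi,

where chi is its typical absolute abundance (copies/cell).  Summing cg
over oscillating proteins and comparing against the steady turnover flux
r_i * chi of the non-oscillating rest yields Fcost, the lower-bound
share of total protein synthesis spent on maintaining the oscillations
when half-lives are constant.  Phosphoprotein fractions across cg bins
probe whether costly oscillators preferentially carry the extra PTM; an
abundance-controlled subset under the truncated power law
P(chi) ~ chi^-gamma (gamma ~ 1) removes the abundance confound.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import minimize_scalar

from rhythmdeg.fitting import EmpiricalSeries
from rhythmdeg.waveform import PeriodicProfile, min_constant_rate

__all__ = [
    "ProteomeRecord",
    "series_eligible",
    "protein_cg",
    "fcost_aggregate",
    "fcost_from_aggregates",
    "phospho_fraction",
    "bin_by_cg",
    "abundance_controlled_subset",
    "powerlaw_exponent",
    "read_proteome",
    "write_proteome",
]

#: abundance window (copies/cell) where phospho- and non-phospho-proteins
#: share the same power-law exponent, removing the abundance confound
CHI_MIN_DEFAULT = 3.0e4
CHI_MAX_DEFAULT = 5.4e5

#: average constant degradation rate of non-oscillating proteins, h^-1
RI_DEFAULT = 0.01


@dataclass
class ProteomeRecord:
    """One protein of a proteome table."""

    id: str
    mean_abundance: float  # chi, copies/cell
    oscillating: bool
    phospho: bool
    series: EmpiricalSeries | None = None
    cg: float | None = None

    def __post_init__(self):
        if self.mean_abundance <= 0:
            raise ValueError(f"{self.id}: abundance must be positive")


def series_eligible(series: EmpiricalSeries | None) -> bool:
    """Density filter for spline-able abundance time courses.

    Requires at least seven data points across replicates, and more than
    two (i.e. at least three) consecutive-time-point gaps shorter than
    6 hours.
    """
    if series is None:
        return False
    if series.n_points < 7:
        return False
    ut = np.unique(series.times)
    gaps = np.diff(ut)
    return int(np.sum(gaps < 6.0)) > 2


def protein_cg(record: ProteomeRecord) -> float | None:
    """cg = max_t[-x'/x] * chi for an oscillating, eligible protein.

    The relative series is splined with the same periodic-cubic
    conventions as the waveform layer; the absolute abundance chi enters
    only in the final multiplication.  Returns None (tagged absent) when
    the record is non-oscillating or its series fails the density
    filter.
    """
    if not record.oscillating or not series_eligible(record.series):
        return None
    ut, mv = record.series.replicate_means()
    profile = PeriodicProfile.from_samples(
        np.mod(ut, record.series.period), mv, period=record.series.period)
    return min_constant_rate(profile) * record.mean_abundance


def attach_cg(records: list[ProteomeRecord]) -> list[ProteomeRecord]:
    """Compute and store cg on every record (in place); returns records."""
    for rec in records:
        rec.cg = protein_cg(rec)
    return records


def fcost_from_aggregates(sum_cg_oscillating: float,
                          flux_non_oscillating: float) -> float:
    """Fcost from pre-summed aggregates.

    ``sum_cg_oscillating`` is the total constant-rate cost bound of the
    oscillating set (copies/cell/h); ``flux_non_oscillating`` is
    r_i * (total abundance of the non-oscillating rest).
    """
    denom = sum_cg_oscillating + flux_non_oscillating
    if denom <= 0:
        raise ValueError("empty Fcost denominator")
    return sum_cg_oscillating / denom


def fcost_aggregate(records: list[ProteomeRecord],
                    constant_rate: float = RI_DEFAULT) -> dict:
    """Proteome-wide cost share of the oscillating proteins.

    The oscillating set C comprises records with a computed cg.  Returns
    the abundance fraction sum_C chi / sum_A chi and
    Fcost = sum_C cg / (sum_C cg + r_i * sum_{A-C} chi).
    """
    with_cg = [r for r in records if r.cg is not None]
    rest = [r for r in records if r.cg is None]
    sum_cg = sum(r.cg for r in with_cg)
    sum_chi_all = sum(r.mean_abundance for r in records)
    if sum_chi_all <= 0 or (sum_cg + constant_rate * sum(
            r.mean_abundance for r in rest)) <= 0:
        raise ValueError("empty denominator in Fcost aggregation")
    return {
        "abundance_fraction": sum(r.mean_abundance for r in with_cg) / sum_chi_all,
        "Fcost": fcost_from_aggregates(
            sum_cg, constant_rate * sum(r.mean_abundance for r in rest)),
        "n_oscillating": len(with_cg),
        "n_total": len(records),
    }


def phospho_fraction(records: list[ProteomeRecord], subset_filter=None) -> float:
    """Fraction of phosphoproteins in a (filtered) record subset."""
    subset = [r for r in records if subset_filter is None or subset_filter(r)]
    if not subset:
        raise ValueError("empty subset for phosphoprotein fraction")
    return sum(r.phospho for r in subset) / len(subset)


def bin_by_cg(records: list[ProteomeRecord], edges) -> dict:
    """Phosphoprotein fraction per half-open cg bin [e_i, e_{i+1}).

    Also fits the visual-guide least-squares line of fraction against
    bin index (empty bins are excluded from the regression with a
    warning) and reports its R^2.
    """
    edges = np.asarray(edges, dtype=float)
    if np.any(np.diff(edges) <= 0):
        raise ValueError("bin edges must be strictly increasing")
    with_cg = [r for r in records if r.cg is not None]
    cgv = np.array([r.cg for r in with_cg])
    ph = np.array([r.phospho for r in with_cg], dtype=bool)
    idx = np.digitize(cgv, edges) - 1
    nbins = len(edges) - 1
    fractions, counts = [], []
    for b in range(nbins):
        sel = idx == b
        counts.append(int(sel.sum()))
        fractions.append(float(ph[sel].mean()) if sel.any() else float("nan"))
    fr = np.asarray(fractions)
    ok = ~np.isnan(fr)
    if (~ok).any():
        warnings.warn(f"{int((~ok).sum())} empty cg bin(s) excluded from trend")
    slope = r2 = float("nan")
    if ok.sum() >= 2:
        xs = np.arange(nbins)[ok].astype(float)
        coef = np.polyfit(xs, fr[ok], 1)
        slope = float(coef[0])
        pred = np.polyval(coef, xs)
        ss_res = float(np.sum((fr[ok] - pred) ** 2))
        ss_tot = float(np.sum((fr[ok] - fr[ok].mean()) ** 2))
        r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else float("nan")
    return {"edges": edges, "fractions": fr, "counts": np.asarray(counts),
            "slope": slope, "r_squared": r2}


def abundance_controlled_subset(records: list[ProteomeRecord],
                                chi_min: float = CHI_MIN_DEFAULT,
                                chi_max: float = CHI_MAX_DEFAULT
                                ) -> list[ProteomeRecord]:
    """Inclusive abundance filter chi_min <= chi <= chi_max."""
    if chi_min >= chi_max:
        raise ValueError("chi_min must be below chi_max")
    out = [r for r in records if chi_min <= r.mean_abundance <= chi_max]
    if not out:
        warnings.warn("abundance-controlled subset is empty")
    return out


def powerlaw_exponent(abundances, chi_min: float = CHI_MIN_DEFAULT,
                      chi_max: float = CHI_MAX_DEFAULT) -> float:
    """Maximum-likelihood exponent of a truncated power law on [chi_min, chi_max].

    P(chi) proportional to chi^-gamma on the window; values outside the
    window are discarded.  The likelihood is maximized numerically (the
    gamma = 1 normalization log(chi_max/chi_min) is handled as the limit
    of the general form).
    """
    chi = np.asarray(abundances, dtype=float)
    chi = chi[(chi >= chi_min) & (chi <= chi_max)]
    n = len(chi)
    if n < 50:
        raise ValueError(f"need >= 50 abundances inside the window, got {n}")
    log_sum = float(np.sum(np.log(chi)))

    def neg_loglik(gamma):
        if abs(gamma - 1.0) < 1e-9:
            logZ = np.log(np.log(chi_max / chi_min))
        else:
            z = (chi_max ** (1 - gamma) - chi_min ** (1 - gamma)) / (1 - gamma)
            if z <= 0:
                return np.inf
            logZ = np.log(z)
        return gamma * log_sum + n * logZ

    res = minimize_scalar(neg_loglik, bounds=(0.01, 6.0), method="bounded",
                          options={"xatol": 1e-6})
    return float(res.x)


# ----------------------------------------------------------------------
# TSV round-trip

_TIME_COL = re.compile(r"^t(?P<h>[0-9.]+)_rep(?P<k>\d+)$")


def read_proteome(path, period: float = 24.0) -> list[ProteomeRecord]:
    """Read the documented proteome TSV.

    Columns: id, abundance, oscillating, phospho, then optional wide
    time columns ``t<h>_rep<k>`` holding relative abundances.
    """
    df = pd.read_csv(path, sep="\t", comment="#")
    required = {"id", "abundance", "oscillating", "phospho"}
    if not required.issubset(df.columns):
        raise ValueError(f"{path}: expected columns {sorted(required)}")
    time_cols = [(c, *m.groups()) for c in df.columns
                 if (m := _TIME_COL.match(c))]
    records = []
    for _, row in df.iterrows():
        series = None
        if time_cols:
            t, v, rep = [], [], []
            for col, h, k in time_cols:
                if pd.notna(row[col]):
                    t.append(float(h))
                    v.append(float(row[col]))
                    rep.append(int(k))
            if len(set(t)) >= 2:
                series = EmpiricalSeries(np.array(t), np.array(v),
                                         np.array(rep), period=period,
                                         periodic=True)
        records.append(ProteomeRecord(
            id=str(row["id"]), mean_abundance=float(row["abundance"]),
            oscillating=bool(row["oscillating"]), phospho=bool(row["phospho"]),
            series=series))
    return records


def write_proteome(records: list[ProteomeRecord], path) -> None:
    time_cols: dict[str, dict[str, float]] = {}
    base = []
    for rec in records:
        base.append({"id": rec.id, "abundance": rec.mean_abundance,
                     "oscillating": int(rec.oscillating),
                     "phospho": int(rec.phospho)})
        if rec.series is not None:
            cols = {}
            for t, v, k in zip(rec.series.times, rec.series.values,
                               rec.series.replicates):
                h = f"{t:g}"
                cols[f"t{h}_rep{int(k)}"] = v
            time_cols[rec.id] = cols
    df = pd.DataFrame(base)
    if time_cols:
        wide = pd.DataFrame.from_dict(time_cols, orient="index")
        df = df.merge(wide, left_on="id", right_index=True, how="left")
    df.to_csv(path, sep="\t", index=False)
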