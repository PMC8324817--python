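#!/usr/bin/env python
"""Steady phosphorylation amplifies degradation rhythmicity and cuts cost.

With the waveform and ubiquitination constants fixed, requiring n prior
phosphorylation events (n = 0..4, steady kinase pool) before
ubiquitination makes the degradation rate more rhythmic and the
proteosynthetic cost lower at every additional site, and a spot check
shows the ATP bill of the extra phosphates is negligible against the
synthesis saving.

Writes results/02_phospho_n.csv and results/02_summary.json.
"""

import json
from pathlib import Path

import pandas as pd

from rhythmdeg.constrained import constrained_simulate
from rhythmdeg.params import PhosphoParams, UbParams
from rhythmdeg.synthetic import WaveformSpec, make_profile
from rhythmdeg.waveform import atp_payoff_fraction

OUT = Path(__file__).resolve().parent.parent / "results"
REF = dict(a0=234.9, a1=17880.6, a2=15347.2, q=262.2, r0=1.3)


def main():
    OUT.mkdir(exist_ok=True)
    profile = make_profile(WaveformSpec(rel_amplitude=0.5))
    p = UbParams(u_bar=0.22, **REF)

    rows = []
    for n in range(5):
        ph = None if n == 0 else PhosphoParams.tied(n, y=152.7, k=0.013)
        sim = constrained_simulate(profile, p, ph)
        rows.append({"n": n, "alpha_D": sim.alpha_D, "cost": sim.cost,
                     "peak_to_trough_ratio": sim.r.max() / sim.r.min()})
    df = pd.DataFrame(rows)
    df.to_csv(OUT / "02_phospho_n.csv", index=False)

    base_cost = df.loc[0, "cost"]
    df["saving_vs_n0_percent"] = 100 * (1 - df["cost"] / base_cost)
    payoff = 100 * atp_payoff_fraction(4, 100)
    summary = {
        "alpha_D_by_n": df["alpha_D"].tolist(),
        "cost_by_n": df["cost"].tolist(),
        "saving_vs_n0_percent": df["saving_vs_n0_percent"].tolist(),
        "atp_payoff_percent_n4_N100": payoff,
    }
    (OUT / "02_summary.json").write_text(json.dumps(summary, indent=2))

    for _, r in df.iterrows():
        print(f"n={int(r['n'])}: alpha_D={r['alpha_D']:.3f} "
              f"cost={r['cost']:.4f} nM/h "
              f"({r['saving_vs_n0_percent']:.1f}% saved vs n=0)")
    print(f"ATP payoff threshold (n=4, N=100): {payoff:.2f}% of synthesis -- "
          f"far below the realized savings")


if __name__ == "__main__":
    main()
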