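# rhythmdeg

Rhythmic degradation of circadian proteins from steady proteolytic
machinery: mass-action ubiquitination models, profile-constrained
simulation, and proteosynthetic cost analysis.

## The problem

A protein whose concentration x(t) oscillates with the day obeys

    dx/dt = g(t) − r(t)·x(t),    x(t) = x(t + 24 h),

so everything synthesized in a day is also degraded in that day: the
period average ⟨g⟩ = ⟨r·x⟩ is a *proteosynthetic cost* paid every day for
the lifetime of the organism. Because g ≥ 0, any degradation rate obeys
r(t) ≥ max(−x′/x, 0); a **constant** rate (constant half-life) must sit at
the peak of that floor, which pins the cost at least at

    cg = maxₜ[−x′(t)/x(t)] · ⟨x⟩ₜ .

A **rhythmic** degradation rate that peaks only during the falling phase
can undercut cg. The question this package addresses quantitatively: where
would such a rhythmic rate come from, if the proteolytic machinery itself
— ubiquitin ligases, kinases — is constant over the day?

The answer it implements and tests: rhythmicity of r(t) emerges
spontaneously from mass-action kinetics. With a steady ligase pool ū,
in dimensionless form (U ∝ ū, R(τ) = −(1/r0)·x′/x, r0 the degradation
rate of ubiquitinated protein), the ubiquitinated fraction settles to

    D(τ) ≈ { 1 + (1 − R(τ))/U }⁻¹,    r(t) = r0·D,

which oscillates because R does, with rhythmicity
α_D = (max r − min r)/max r ≈ (Rmax − Rmin)/(U + 1 − Rmin) and the
feasibility floor U ≳ Rmax. Extra *steady* phosphorylation steps ahead of
ubiquitination amplify α_D and cut the cost further, at an ATP price
bounded by n/(4N) of synthesis (n phosphosites, N residues) — about 1%
for n = 4, N = 100.

## What is in the package

| module | contents |
|---|---|
| `rhythmdeg.waveform` | `PeriodicProfile`, `RateSeries`, cost functionals (cg, α_D, similarity S, half-life, ATP payoff) |
| `rhythmdeg.params` / `models` | kinetic parameter sets and ODE right-hand sides for the phospho-independent, mono/multisite, multi-route and PER2 variants; forward integration |
| `rhythmdeg.constrained` | the profile-constrained simulation (x(t) held fixed, r(t) and g(t) recovered, biological feasibility screened) |
| `rhythmdeg.approx` | dimensionless reduction, closed forms for D(τ), validity-condition checker, feasibility bounds |
| `rhythmdeg.fitting` | time-series ingestion, smoothing splines, empirical rate profiles rE(t), uniform scans, Nelder–Mead refinement |
| `rhythmdeg.proteome` | per-protein cg, the Fcost aggregate, phosphoprotein fractions across cg bins, truncated-power-law MLE |
| `rhythmdeg.stats` | four randomization tests with an add-one, seeded, exactly calibrated p convention |
| `rhythmdeg.synthetic` | generators: waveforms with controllable Rmax, noisy replicated series, ground-truth degradation observations, power-law proteomes |
| `rhythmdeg.cli` | `rhythmdeg` console script (constrained, approx, tim, empirical-rate, scan, optimize, proteome, stats, synth) |

Numbered drivers under `analysis/` narrate the main results and write
tables to `results/`; `docs/methods.md` documents the model, conventions
and limitations.

## Worked example

```python
import numpy as np
from rhythmdeg import UbParams, constrained_simulate, cg
from rhythmdeg.synthetic import WaveformSpec, make_profile

profile = make_profile(WaveformSpec(rel_amplitude=0.5))   # 24 h sinusoid, mean 1 nM
params = UbParams(u_bar=0.22, a0=234.9, a1=17880.6, a2=15347.2,
                  q=262.2, r0=1.3)                         # steady ligase pool
sim = constrained_simulate(profile, params)
print(f"feasible={sim.feasible.feasible} alpha_D={sim.alpha_D:.3f} "
      f"cost={sim.cost:.4f} nM/h  (constant-rate bound cg={cg(profile):.4f})")
```

prints

```
feasible=True alpha_D=0.137 cost=0.4688 nM/h  (constant-rate bound cg=0.1511)
```

— the degradation rate is rhythmic (13.7% peak-to-trough) although
nothing in the machinery oscillates. Sweeping the ligase down
(`analysis/01_spontaneous_rhythmicity.py`) raises α_D monotonically to
0.184 until the feasibility floor U ≈ Rmax = 0.116, where the cost drops
to 0.1428 nM/h — 5.5% below cg. Requiring phosphorylation first
(`analysis/02_phospho_amplification.py`, kinase pool 152.7 nM,
k = 0.013 nM⁻¹h⁻¹):

```
n=0: alpha_D=0.137 cost=0.4688 nM/h (0.0% saved vs n=0)
n=1: alpha_D=0.214 cost=0.3798 nM/h (19.0% saved vs n=0)
n=2: alpha_D=0.280 cost=0.3191 nM/h (31.9% saved vs n=0)
n=3: alpha_D=0.339 cost=0.2751 nM/h (41.3% saved vs n=0)
n=4: alpha_D=0.393 cost=0.2417 nM/h (48.5% saved vs n=0)
```

each extra steady phosphorylation site makes degradation more rhythmic
and cheaper, against an ATP payoff threshold of only 1% of synthesis.
`analysis/03_parameter_recovery.py` recovers known kinetics from a
synthetic degradation-rate profile (scan + simplex reach overlap
similarity S = 1.000, cost within 0.1% of truth; Spearman ρ = −0.93
between S and cost across the scan), and `analysis/04_proteome_cost.py`
runs the proteome chain on a generated power-law table (γ̂ = 0.99;
oscillators hold 10% of abundance but ≥ 70% of synthesis; phosphoprotein
fraction rises across cg bins, permutation p = 2×10⁻⁴).

## Acceptance script

```sh
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

recomputes, from package code at run time, the worked-example quantities:
the proteome-wide cost share Fcost and the oscillating abundance fraction
implied by the published mouse-liver aggregate fluxes, and the ATP-payoff
bound 100·n/(4N) for a 100-residue protein with four phosphorylation
events. The JSON maps each target id to `{"value": ..., "n": ...}`.
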