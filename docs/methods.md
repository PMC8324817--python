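# Methods

## The model

A protein with circadian production obeys the balance

    dx/dt = g(t) − r(t)·x(t),        x(t) = x(t+T),  T = 24 h,

with synthesis rate g(t) ≥ 0 and degradation rate r(t) ≥ 0. Periodicity
forces ⟨g⟩ = ⟨r·x⟩ over one period; this average is the *proteosynthetic
cost* — the protein mass that must be resynthesized every day just to keep
the oscillation going. Because g ≥ 0, every feasible degradation rate obeys
the pointwise floor r(t) ≥ max(−x′/x, 0); a constant rate must sit at the
floor's peak, so the constant-rate cost is bounded below by
cg = maxₜ[−x′/x]·⟨x⟩. A rate that peaks only during the falling phase can
undercut cg — that is the cost logic the whole package revolves around.

Degradation is modeled mechanistically as mass-action ubiquitination with
*steady* enzyme pools: a ubiquitin ligase pool ū binds free substrate
(a0, releases at a1), ubiquitinates bound substrate (q), releases
ubiquitinated protein (a2); ubiquitinated species degrade at r0, the hard
ceiling of any realized r(t) = r0·(ubiquitinated fraction). An optional
deubiquitinase pool v̄ (b0, b1, s) reverses the tag. Variants prepend a
kinase/phosphatase chain (pools y, z; lumped rates kᵢ, lᵢ) so that only the
n-fold phosphorylated form is a ligase substrate; a multi-route variant
gives each phospho-form its own ligase block; the PER2 variant combines a
four-site chain with an independent phospho-site feeding a second ligase
pool (30 state components). Nothing in the machinery oscillates: any
rhythmicity of r(t) is emergent.

## The constrained simulation

Changing a kinetic constant normally changes x(t) and r(t) together. The
profile-constrained technique removes the confound: x(t) is prescribed, the
free-substrate component is eliminated via x0 = x − Σ(other components),
and the remaining components are integrated (LSODA, rtol = atol = 1e−5)
period by period until the state change across a period boundary falls
below 1e−4 relative to max x(t) (max 50 periods; the residual is
normalized by the profile scale because component changes far below x(t)
cannot move r(t)). The synthesis profile that would sustain the solution is
read off the balance, g = x′ + r·x, with x′ from the profile's spline. A
parameter set is *biologically infeasible* for a profile when the converged
solution drives any of g(t), x0(t), or a free-enzyme concentration to ≤ 0
(tolerance −1e−9 × the quantity's scale on a 0.1 h output grid): the
prescribed oscillation cannot be maintained with that little enzyme.

## Closed forms and their regime

With τ = r0·t, U = (a0/r0)(q/(a1+q))·ū, Y = (k/r0)·y and
R(τ) = −(1/r0)·x′/x, the pseudo-steady-state fixed point gives
D = {1 + (1−R)/U}⁻¹ (deubiquitinase-free, conditions (i)–(iv): fast complex
turnover, small U against q/r0, small V, unsaturated enzymes — "≪"
operationalized as ratio ≤ margin, default 0.1, configurable). A
Michaelis–Menten variant adds substrate saturation; the mono-phosphorylation
form multiplies in the kinase factor; the multisite form D = U·ΠKᵢYⁿ/ηₙ(R)
is evaluated with every ηₙ term divided by Π(KᵢY), which keeps all factors
bounded for arbitrarily fast or slow kinetics (verified identical to the
printed sum to 1e−12). Condition (vi) (bound-ubiquitinated ≪
bound-unmodified) needs a trajectory; without one the checker reports the
steady-state surrogate q/(a2+r0).

Since g ≥ 0 implies R ≤ D ≤ 1, each closed form yields the feasibility
floor U (and Y) ≳ Rmax: enzyme activities cannot fall below the scaled peak
decline rate of the waveform. The bound, the monotone rise of α_D =
(max r − min r)/max r toward the floor, and the <10% closed-form/ODE
agreement under the conditions are all asserted in the acceptance suite.

## Empirical stages

Abundance time courses are normalized by a reference-time replicate
average, smoothed with a periodic smoothing spline (degree 3, smoothing
condition s = 5 by default), and floored at 1e−3 × mean (with a warning) to
stay strictly positive. Sparse degradation-rate measurements become an
empirical profile rE(t) as: linear interpolation with terminal-segment
continuation beyond the sampled span, pointwise-maxed with the balance
floor max(−x′/x, 0) (optionally pre-smoothed with a centered 1 h window:
the order is smooth → floor → clamp), and clamped from below by the
smallest measured rate. Moving averages are centered, endpoint-inclusive,
over replicate means, wrapping only for periodic-flagged series; a window
strictly wider than the span is an error (the spec's own window-2-on-span-2
example forces the strict reading).

Parameter scans draw uniformly (linear or log10 per parameter) with a
recorded seed, push every set through the constrained simulation, and
retain infeasible sets tagged with a reason; the overlap similarity
S = ∫min(r, rE)/∫max(r, rE) is computed on a 0.05 h grid (insensitive to
halving). Refinement is Nelder–Mead in log10-parameter space with
reflection at the range bounds and a 1e6·(1+violation) penalty on
infeasible evaluations; kinase rates are tied (k₁ = … = kₙ) by default,
with an untied override. Sampling ranges default to about a decade around
the published worked-example constants (a0 234.9 nM⁻¹h⁻¹, a1 17 880.6 h⁻¹,
a2 15 347.2 h⁻¹, q 262.2 h⁻¹, r0 1.3 h⁻¹, ū 0.22 nM, y 152.7 nM, k 0.013
nM⁻¹h⁻¹), the only physiological anchors printed with the figures.

## Proteome stage

A protein's cg is maxₜ[−x′/x] of the periodic cubic spline of its relative
series, times its absolute abundance χ (copies/cell). Series are eligible
when they carry ≥ 7 points across replicates and ≥ 3 consecutive
unique-time gaps shorter than 6 h. Fcost sums cg over the oscillating
eligible set C and compares it with the steady flux rᵢ·Σχ of the rest
(rᵢ = 0.01 h⁻¹ default): Fcost = Σ_C cg / (Σ_C cg + rᵢ·Σ_{A−C} χ), the
lower-bound share of total synthesis spent on the oscillators under
constant half-lives. Phosphoprotein fractions are computed per half-open cg
bin with a least-squares visual-guide slope; the abundance-controlled
subset (3.0e4 ≤ χ ≤ 5.4e5 copies/cell, inclusive) removes the abundance
confound because both label classes follow the same truncated power law
P(χ) ∝ χ^−γ, γ ≈ 1, there; γ is estimated by numerical maximum likelihood
on the truncated family.

## Randomization tests

All tests report the add-one p = (count+1)/(N+1) with the seed, and a
raw-fraction bound string ("P<1e-4") when the observed beats every null
draw. Two conventions differ deliberately from plain counting. First, the
one-tailed direction is fixed a priori (default: negative S–cost
association) rather than taken from the observed sign — a sign-adaptive
tail is uniform only on (0, 0.5) under the null and would fail calibration.
Second, ties between the observed and a null statistic are resolved by a
seeded uniform tie-break (lexicographic on (statistic, uniform)), which
makes the add-one p *exactly* uniform under exchangeability even for
coarse statistics such as subset fractions; plain counting of ties is
conservative enough to fail a KS check at desk scale. The cg-monotonic test
counts the literal all-adjacent-fold-dominance event: with two bins this is
a scalar exceedance and exactly calibrated; with more bins it is a
partial-order event that is *not* uniform under the null (it behaves like a
product of tail probabilities, anti-conservative for some draws), so
multi-bin p-values should be read as descriptive. The cost-proximity test
is an empirical quantile within the scan ensemble, not a permutation.

## Synthetic data

Waveforms are x(t) = mean·(1 + b·w(t)) with w a sign-preserving power of a
sinusoid (sharpness ≥ 1) on a time axis warped by the exactly periodic map
t → t + a·(T/2π)·sin(2πt/T) (asymmetry |a| < 1); b < 1 guarantees strict
positivity, and Rmax is controllable — by bisection on b, then on sharpness
— to 1e−3. Measurement noise is multiplicative lognormal with a specified
CV (abundance data are ratio-scale; the sources publish no error model).
Synthetic proteomes draw abundances from the truncated power law by inverse
CDF; oscillating proteins (default 5% of the table, a desk-scale stand-in
for the few-percent circadian fraction) receive noisy replicated waveform
series and hence a computable cg; phospho labels follow
logit p = logit(base) + β_χ·z(log χ) + β_R·z(decline peak), with the
decline peak z-scored over the whole table (non-oscillators at 0) so a
positive β_R both enriches phosphoproteins among oscillators and tilts them
toward sharp waveforms; β_χ = β_R = 0 is an exchangeable null. Defaults:
γ = 1, χ window 3.0e4–5.4e5, base rate 0.434 (the published all-protein
phosphoprotein fraction), CV 0.1. What a green test establishes is that the
pipeline detects structure the generator injected and stays calibrated on
the generator's null; it says nothing about organism-specific waveform
shapes, measurement error correlations, or annotation biases in real
phosphoproteome tables.

## Numerical choices and degenerate inputs

Period integrals use trapezoidal quadrature; extremum searches use a 0.01 h
grid with bounded golden-section refinement. Profiles built from samples
are periodic cubic splines (value- and derivative-continuous at the wrap).
All-zero rate series make α_D and S undefined (hard errors); constant
vectors make Spearman ρ undefined (flagged). Initial conditions are empty
complexes (constrained mode: x0(0) = x(0)); transients are discarded by the
convergence criterion. CT and ZT hour labels are treated identically.

## Known limitations

The paper's supplementary parameter ranges and its digitized third-party
datasets (TIM, PRR7, PER2, mouse-liver and Arabidopsis tables) are not
available here; the empirical stages run on user-supplied CSV/TSV or on the
generators, and the published headline fits (S = 0.76/0.75, ρ < −0.99, the
65.1%/51.3% fractions) are therefore not reproduced, only their
property-level counterparts. The realistic PER2 parameterization is not in
the text; its model is exercised through structural reductions. Stochastic
kinetics, nucleocytoplasmic partitioning, and phosphorylation-*inhibited*
degradation are out of scope.
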