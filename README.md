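# domeq

Two-domain conformational equilibria from magnetic resonance: simulate
and invert DEER (PELDOR) dipolar traces into two-state distance
distributions with populations, convert paramagnetic relaxation
enhancements (PRE) into distance restraints, assemble ensemble-averaged
NOE/PRE/DEER restraints, and test whether one rigid-body state or two
are needed to satisfy them.

## The problem

Many regulatory proteins consist of two domains connected by a flexible
linker — Pin1, with its WW binding domain (residues 1–39) and catalytic
PPIase domain (residues 50–163), is the archetype. Such proteins
exchange between a *compact* state with a specific interdomain
interface and an *extended* state in which the domains tumble
quasi-independently; ligands shift this equilibrium and thereby tune
activity allosterically. The equilibrium is measurable: DEER on doubly
spin-labeled constructs yields the interspin distance distribution
P(r), whose modes are the state geometries and whose weights are the
state populations; PREs report population-averaged interdomain
distances up to ~25 Å; interdomain NOEs exist only in the compact
state. `domeq` implements that inference chain end to end, with a
synthetic ground-truth generator so every stage is testable against
known truth.

## The models

**DEER.** A trace is `V(t) = [1 − λ + λ ∫P(r)K(t,r)dr] · e^{−κ|t|^d}`
with the powder-averaged dipolar kernel
`K(t,r) = ∫₀¹ cos[(1−3x²) ω_dd t] dx`, `ω_dd = 2π·52.04 MHz·(r/nm)⁻³`
(evaluated via its Fresnel closed form). P(r) is inferred either as a
bi-Gaussian — compact center r₁, extended center r₂ > r₁, widths σ₁,
σ₂, compact population p₁ — by joint least squares with the modulation
depth λ and background (κ, d), or parameter-free by non-negative
Tikhonov regularization with GCV-selected α. Residual-resampling
bootstrap (200 samples) gives 95% confidence intervals.

**PRE.** `r = [(K/R₂sp)(4τc + 3τc/(1+ω_H²τc²))]^{1/6}` with
R₂sp = R₂(para) − R₂(dia), K = 1.23×10⁻³² cm⁶s⁻², and τc from the
¹⁵N R₂/R₁ ratio.

**Two-state evaluation.** Restraints are scored against a rigid-body
ensemble by `TF = Σ w·violation²` (flat-bottom bounds; NOE/PRE average
as ⟨r⁻⁶⟩⁻¹ᐟ⁶ across states, DEER effective distances linearly; weights
NOE/DEER/PRE = 1/1/0.01). A seeded multi-start optimizer places the
mobile domain per state and the state populations.

## Worked example

```python
import numpy as np
from domeq import (BiGaussianModel, BackgroundModel, PathwayModel,
                   DistanceGrid, simulate_trace, fit_bigaussian,
                   extract_populations)

grid = DistanceGrid()                      # 15-80 A, 0.5 A step
truth = BiGaussianModel(22, 1.5, 0.68, 45, 8)   # 68% compact
trace = simulate_trace(truth, PathwayModel.four_pulse(0.4),
                       BackgroundModel(0.1, 1.0), np.linspace(0, 2.5, 251))
fit = fit_bigaussian(trace, grid, n_starts=8, seed=1)
print(f"compact {fit.model.p1:.3f} at {fit.model.r1:.2f} A, "
      f"extended {fit.model.p2:.3f} at {fit.model.r2:.2f} A")
```

prints

```
compact 0.680 at 22.00 A, extended 0.320 at 45.00 A
```

i.e. the fit recovers the planted equilibrium — 68% of molecules in the
compact state with a 22 Å label separation, 32% extended at 45 Å —
from the time trace alone. The full pipeline on synthetic data, from
the shell:

```
domeq pipeline --seed 0 --out run0
```

```
TF one-state 312.79 A^2, two-state 0.0000 A^2 (two-state required: True)
```

meaning no single domain placement satisfies the compact-contact NOEs,
the PRE distances and the extended DEER distance simultaneously (target
function ~313 Å²), while a two-state ensemble satisfies everything —
the restraint-space signature of a genuine conformational equilibrium.
`run0/report.json` carries the fitted populations, the recovered state
geometries, and the per-stage timings; the other subcommands
(`simulate`, `fitdeer`, `pre2dist`, `restraints`, `optimize`,
`analyze`) expose the individual stages.

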