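# Methods

`domeq` analyzes the interdomain conformational equilibrium of a
two-domain protein — the canonical example being Pin1, whose WW binding
domain (residues 1–39) and catalytic PPIase domain (residues 50–163)
sample a compact, contact-forming state and an extended, quasi-
independent state — by combining pulsed-EPR distance distributions
(DEER), paramagnetic relaxation enhancements (PRE), interdomain NOEs
and scalar couplings into a single testable pipeline. This note
documents the models, the defaults, and the deliberate simplifications.

## DEER forward model

The echo amplitude of a doubly spin-labeled molecule is modeled as

    V(t) = [ Λ₀ + Σₖ λₖ D(t − T0ₖ) ] · B(t)

where `D(t) = ∫ P(r) K(t, r) dr` is the intramolecular dipolar form
factor of the interspin distance distribution `P(r)` and `K` the
powder-averaged dipolar kernel

    K(t, r) = ∫₀¹ cos[(1 − 3x²) ω_dd(r) t] dx,
    ω_dd(r) = 2π · 52.04 MHz · (r/nm)⁻³ .

The kernel is evaluated by its exact Fresnel-integral closed form
(`scipy.special.fresnel`), which agrees with brute-force orientation
quadrature to better than 1e-6. Four-pulse DEER is a single modulated
pathway of amplitude λ (the modulation depth) refocusing at t = 0;
five-pulse DEER adds a secondary four-pulse-type artefact pathway of
amplitude λ₂ refocusing at a configurable T0 (default: trace midpoint).
The intermolecular background is a stretched exponential
`B(t) = exp(−κ|t|^d)`. With a single pathway the background multiplies
the whole signal; with several pathways a product of per-pathway
backgrounds with κ scaled by the pathway amplitude is used. This is a
convention choice (the convention of the standard analysis software for
phenomenological backgrounds differs in detail); it only matters for
primary five-pulse data, and an artefact-subtraction path back to the
single-pathway form is provided.

Units: time in µs, distances in Å (converted to nm only inside ω_dd),
κ in µs⁻¹.

**Distance grid and sampling.** The default grid spans 15–80 Å — the
practical detection window of Q-band DEER on such constructs — with
131 points (0.5 Å step). Simulation and fitting use the same trapezoid
quadrature on the same grid, so inference is self-consistent by
construction. The absolute quadrature accuracy of a grid depends on
whether its step resolves the kernel oscillation in `r`: a 0.5 Å step
resolves a 22 Å component up to roughly 1.5 µs; a 0.25 Å step (261
points) covers the full 2.5 µs window to better than 1e-4. Tests pin
both regimes.

## Inference

**Bi-Gaussian model.** `P(r)` is a two-Gaussian mixture with centers
r₁ < r₂ (compact and extended; the ordering is enforced by sorting, so
component 1 is always the compact state), widths σ₁, σ₂ and compact
population p₁. The fit is a joint trust-region least squares
(`scipy.optimize.least_squares`) over (r₁, σ₁, p₁, r₂, σ₂, λ, κ, d)
with the background bounded to κ ∈ [0.02, 1] µs⁻¹ and d ∈ [0.9, 1.2],
started from 8 seeded initializations (one moment-based, the rest
random within bounds); the lowest-cost solution wins. Noiseless
round trips over p₁ ∈ [0.3, 0.9], r₁ ∈ [20, 30] Å, r₂ ∈ [38, 55] Å
recover populations within 0.01 and compact centers within 0.2 Å.

**Tikhonov regularization.** The parameter-free inversion minimizes
`‖D − K P‖² + α²‖L₂ P‖²` subject to `P ≥ 0`, with `L₂` the
second-difference operator, solved by non-negative least squares on the
stacked system. The form factor `D` is obtained two-pass: background
and modulation depth come from the parametric fit (or from metadata a
synthetic trace carries) and are divided out. α is selected by
generalized cross-validation, `GCV(α) = n‖D − K P_α‖² / tr(I − H_α)²`,
using the influence matrix of the *unconstrained* solve (the
constrained solve has no closed-form trace — a documented
approximation) and the constrained residual. A minimum on the α-grid
boundary is flagged; on noiseless data the boundary flag at the small-α
end is expected and harmless. GCV is the rotation-invariant
approximation to exact leave-one-out cross-validation; the test suite
verifies the exact linear-smoother LOO identity against brute-force
refits and the GCV ≈ LOO agreement (within 5% in the mean over noise
realizations) on a toy inversion whose leverage is near-uniform.
Leverage is structurally concentrated at early times (the t = 0 kernel
row is constant), so pointwise agreement on full traces is not expected.

**Bootstrap.** Uncertainties are residual-resampling bootstrap
percentile intervals, 200 resamples by default (which converges the
95% CIs at these noise levels), each refit warm-started from the point
estimate. Percentile intervals were chosen over reverse-percentile
("basic") intervals: the sampling distributions of the populations are
skewed and bounded, and reverse-percentile intervals undercover badly
there. Measured coverage of the 95% intervals over 50 independent
replicates at noise σ = 0.005 is ~95% (the acceptance suite re-measures
this). CI width shrinks with SNR as expected.

**Populations.** For a bi-Gaussian fit the compact population is p₁
directly. For a gridded distribution the density is integrated below
and above a split distance; `split="auto"` places the split at the
density minimum between the two highest modes and refuses unimodal
input. The two fractions are renormalized to sum to 1 exactly.

## PRE distances

The transverse enhancement R₂sp = R₂(para) − R₂(dia) (negative
differences are measurement noise: flagged and clipped to zero) is
converted by the Solomon–Bloembergen dipolar relation

    r = [ (K / R₂sp) · (4 τc + 3 τc / (1 + ω_H² τc²)) ]^(1/6)

with K = 1.23e-32 cm⁶ s⁻² (the standard nitroxide–¹H dipolar constant)
and the proton Larmor frequency of the spectrometer (default 600 MHz).
τc comes from the ¹⁵N R₂/R₁ ratio, τc = √(6R₂/R₁ − 7)/(4π ν_N), the
isotropic-tumbling estimator, summarized as a trimmed mean over rigid
residues — a single global τc is used for the conversion because the
restraints are interdomain and tumbling is reported at domain level.
Distances above 25 Å are *excluded*, not capped: beyond that range the
enhancement is within noise and the distance unreliable. Distances are
referenced to the label-site Cβ, the same convention as the DEER
restraints. The synthetic rates are generated from the reduced
spectral-density model (R₁ ∝ 3J(ω_N), R₂ ∝ 2J(0) + 1.5J(ω_N)) under
which the τc estimator is exact, so the round trip isolates
implementation errors.

## Restraints and two-state evaluation

Ensemble-averaged probes must be satisfied by the population-weighted
average over states, not by each state alone: NOE and PRE distances
average as `(Σ pop_s r_s⁻⁶)^(−1/6)`, DEER effective distances — which
are linear population averages by construction — average linearly (the
averaging mode per restraint kind is a documented modeling choice).
Default weights are NOE 1, DEER 1, PRE 0.01. The DEER effective
distance is `⟨r⟩ = ∫ r P(r) dr` between the label Cβs, turned into an
upper/lower limit pair with a ±5 Å tolerance. The target function is
`TF = Σ wᵢ · violationᵢ²` (Å²) with flat-bottom violations: zero inside
[lower, upper], linear outside, squared in the sum.

**Rigid-body surrogate.** The full torsion-angle simulated-annealing
engine is deliberately replaced by rigid-body placement: domain A is
fixed, domain B is placed with 6 degrees of freedom per state, and the
state-1 population is optimized within [0.05, 0.95] (starting at
0.5/0.5) or fixed from the upstream DEER fit. The central scientific
claim this machinery supports — that compact-only contacts and
extended-state distances are jointly unsatisfiable by any single
placement but satisfiable by two — lives entirely in interdomain
restraint space, which rigid bodies expose at desk scale. Absolute TF
values are therefore *not* comparable to a full structure-calculation
target function; only the one-state/two-state contrast (here ≥ 20×) is
meaningful. Intradomain coordinates are untouched by construction
(tested).

**State-resolved DEER restraints.** With only flat-bottom
population-averaged restraints, the extended placement is
underdetermined: population and extended distance trade off freely
inside the ±5 Å window. The pipeline therefore supplements the
conventional ensemble-averaged effective-distance restraint with one
restraint per bi-Gaussian component pinning the corresponding state's
label distance to the fitted center within ±1.5 Å (a conservative
multiple of the typical fitted-center confidence interval). This is a
design choice of the surrogate, exposed as
`PipelineConfig.use_state_restraints` / `state_restraint_tolerance`.

Scalar couplings are back-calculated with standard Karplus
parameterizations (³J_HNHα: A, B, C = 7.09, −1.42, 1.55 Hz with the
−60° phase; ³J_HαHβ and ³J_NCγ registered analogously); they validate
dihedral handling and are not used to drive the rigid-body placement.

## Ensemble analysis

Conformers are sorted compact/extended by presence of any interdomain
heavy-atom pair below a 5 Å cutoff (no published number exists for
this; a 4–6 Å sensitivity table is emitted alongside). RMSD profiles
between two conformer sets are computed between *mean* structures after
least-squares superposition of every conformer onto a canonical
reference core — the iterated mean core over the union of both sets,
which makes the profile exactly symmetric under swapping the sets. The
core defaults to the larger domain's Cα trace and is recorded in the
output metadata, because interdomain RMSD values depend on this choice.
Per-residue uncertainty is `√(var_a + var_b)`, the upper limit for the
uncertainty of the difference of means. Restraint-set overlap is
reported per kind as `|A∩B|/|A|` and `|A∩B|/|B|` on order-normalized
atom-pair identities.

## Synthetic ground truth

Domains are Cα+Cβ bead chains (3.8 Å Cα spacing, 1.53 Å Cβ offset)
generated as confined random walks — no real coordinates are required
anywhere, though multi-model PDBs are read and written. The compact
placement is solved (nested bracketing root finds) so the label-site
Cβ–Cβ distance hits its target (default 22 Å, within 0.1 Å) while the
domains touch (minimum interdomain distance ≈ 4 Å); the extended
placement translates domain B outward along the label axis to the
extended target (default 45 Å), leaving no pair within 8 Å. Defaults:
70:30 compact:extended, label widths σ = 1.5 / 8 Å, label sites 15/90,
modulation depth 0.4, κ = 0.1 µs⁻¹, d = 1, trace 0–2.5 µs at 251
points, noise ladder σ ∈ {0, 0.002, 0.005, 0.02} (default 0.005).
Synthetic NOE upper limits exist only for pairs in contact in the
compact state (the extended state contributes none), set to the
ensemble r⁻⁶-averaged distance plus 0.5 Å so the planted truth is
feasible. All generators are deterministic given their seed.

What the generator does *not* emulate — and what passing tests
therefore cannot show about real data: spin-label rotamer
distributions (label broadening is a per-state Gaussian), orientation
selection and pulse-shape effects, nuclear modulation, anisotropic
tumbling, solvent PREs, side-chain packing and real NOE spectral
overlap. The generator's statistical structure matches the analysis
assumptions exactly, so failures isolate implementation bugs, while
agreement says nothing about model adequacy for experimental spectra.

## Numerical choices and limitations

* Non-negative Tikhonov solves use `scipy.optimize.nnls` (active-set,
  machine-precision tolerance) on the stacked regularized system.
* Optimizer ties are broken by cost; the rigid-body search stops early
  at cost < 1e-12.
* Bi-Gaussian model adequacy is not decided by the package: constructs
  whose distributions are not two-Gaussian (e.g. a label pair whose
  components overlap) are reported with their residual RMS and left to
  the user; the Tikhonov route is the model-free cross-check.
* Flat-bottom restraints make every point inside the bounds equally
  acceptable: recovered state distances are meaningful to the restraint
  tolerance, not beyond it.
* Problem sizes throughout (251-point traces, 131-point grids, 200
  bootstrap resamples, 50-replicate coverage simulations, ~10-restraint
  optimizations) are desk-scale choices that keep every check in
  seconds to a few minutes.
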