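# Methods

This note documents the models implemented in `cosolv`, the choices made
where the design was genuinely open, and the limits of what the test suite
demonstrates.

## Data model and units

Solubilities are stored as molar concentrations (mol/L). The measured
solubility table for acetylsalicylic acid is headed "molar fraction" in its
source but its cells are molar concentrations (the neat-water cell 0.0246
matches the text's "0.0246 mol·L⁻¹"); all cosolvency fits therefore run on
the molar scale, and hand recomputation of the published MRD% values
succeeds only on that scale. Temperatures are Kelvin internally
(25 °C → 298.15 K, 37 °C → 310.15 K); CSV files carry Celsius for
readability.

Mole-fraction conversions need solution densities that were measured but not
published (and are acknowledged to be biased by dissolved salicylic acid).
The package therefore uses standard pure-liquid densities — water
0.99705/0.99333 g·cm⁻³ and ethanol 0.78522/0.77641 g·cm⁻³ at
298.15/310.15 K — purely for volume-to-mole bookkeeping, and user-supplied
densities override them. Exact reproduction of the source's molar→mole
fraction conversions is impossible without the unpublished density table;
nothing acceptance-critical depends on them.

## Cosolvency models

All four models are anchored at the neat solvents: at f₁ ∈ {0, 1} they
return C₂ and C₁ exactly, by construction.

**Log-linear.** σ = ln(C₁/C₂) when measured; σ = M·log P + N with the
ethanol constants M = 2.14, N = 0.92 when predicted (log P = 1.18 for ASA).
The predictive variant needs only the aqueous solubility.

**Jouyban–Acree.** The response ln C<sub>m,T</sub> − f₁ ln C₁,T − f₂ ln C₂,T
is regressed without intercept on f₁f₂/T, f₁f₂(f₁−f₂)/T and f₁f₂(f₁−f₂)²/T.
Anchor rows contribute zero rows and are retained; a dataset with only
anchors is rank deficient and rejected. Fitting both temperatures jointly on
the packaged dataset gives J = (1426.4, 515.3, −1084.3) K and a pooled
back-calculated MRD% of 9.9.

Published pre-trained coefficient sets are shipped as data: a two-term set
trained on a minimal ASA subset (anchors at both temperatures plus
f₁ ∈ {0.3, 0.5, 0.7} at 25 °C — reproducible with
`ja_fit(dataset.subset(...), n_terms=2)`), a solute-independent
ethanol–water set, and the Abraham-extended set in which each mixing
coefficient is the dot product of a published vector with
(1, E, S, A, B, V). For ASA (E, S, A, B, V = 0.84, 1.42, 0.57, 0.77, 1.29)
the zeroth-power coefficient evaluates to 937.2 K.

**Modified Wilson.** −ln C<sub>m</sub> = 1 − f₁(1 + ln C₁)/(f₁ + f₂λ₁₂)
− f₂(1 + ln C₂)/(f₁λ₂₁ + f₂), with both solubility symbols resolved to the
same (molar) scale as C<sub>m</sub> — verified by the published λ pairs
reproducing the published per-temperature MRD% (25.2 at 25 °C, 25.7 at
37 °C) only under this reading. The fit minimizes squared ln-residuals from
a 3 × 3 grid of starts over [0.1, 5]², bounded below at λ > 0; ties within
1e-12 in the objective resolve to the smaller λ₁₂. Noiseless synthetic data
are recovered to 1e-6, and the packaged 37 °C data reproduce the published
λ = (0.294, 3.405).

## PC-SAFT

The residual Helmholtz energy a<sup>res</sup> = a<sup>hc</sup> +
a<sup>disp</sup> + a<sup>assoc</sup> follows the standard perturbed-chain
formulation with its universal dispersion constants taken verbatim (not
re-derived). Implementation choices:

* Temperature-dependent segment diameter d = σ[1 − 0.12 exp(−3ε/kT)].
* Lorentz–Berthelot combining rules with k<sub>ij</sub> = 0 throughout (the
  purely predictive setting); Wolbach–Danner rules for cross-association
  between all associating pairs.
* 2B association (one donor + one acceptor per molecule): by symmetry the
  two site fractions per component coincide, so one unbonded fraction per
  component is solved by damped successive substitution (damping 0.5,
  tolerance 1e-12, ≤ 500 sweeps) with a bounded least-squares root solve as
  fallback.
* The association cell of the solute parameter table is read as
  κ<sup>AB</sup> = 0.01 and ε<sup>AB</sup>/k = 2453.80 K (matching the
  κ-then-ε pattern of the solvent rows and physically plausible hydrogen-bond
  energies); association energies are Kelvin-valued ε/k for all components.
* Compressibility is analytic (the association part via the stationarity of
  the site-fraction functional); the suite checks it against central
  differences of a<sup>res</sup> to 1e-8.
* Composition derivatives in ln φ<sub>k</sub> are central differences of
  a<sup>res</sup> at constant T and total density with the mole fractions
  treated as free variables (step 1e-5); Gibbs–Duhem holds to ~1e-5 on
  random ternary states.
* Density solving scans the pressure isotherm over packing fractions up to
  0.74, refines every bracketed root by Brent's method, discards mechanically
  unstable roots (dP/dρ < 0 — the EOS admits spurious high-packing
  crossings), and returns the densest stable root for the liquid branch, the
  most dilute for the vapor branch. A packing-fraction hint enables a fast
  local bracket when iterating.
* Pressure is not stated in the source; 1.013 bar is assumed everywhere.

Validation is indirect because no intermediate quantities are published for
this system: the implementation reproduces experimental pure-liquid
densities within 1–3 % for non-associating chains (methane, propane, butane,
hexane, toluene, decane with their standard parameters, checked during
development) and vapor pressures at the sub-percent level for hexane and
ethanol. The constant-diameter 2B water set is a known compromise fit: it
reproduces the ambient vapor pressure within ~4 % but underpredicts ambient
liquid density by ~7 % (≈ 0.92 g·cm⁻³); the test suite asserts this
published model behavior, not the experimental density.

## Solid–liquid equilibrium

x = x<sub>ideal</sub>/γ(x) with x<sub>ideal</sub> = exp[(ΔH<sub>m</sub>/R)(1/T<sub>m</sub> − 1/T)]
is iterated with damping 0.5 from x<sub>ideal</sub>, relative tolerance
1e-8, at most 200 iterations; the solute-free solvent ratio is held fixed
while renormalizing with the solute. The solute's reference fugacity is the
hypothetical pure subcooled liquid at the same T, P (liquid branch), and is
computed once per problem. Iterates escaping (0, 1) are clipped and flagged.
The converged root is independent of damping ∈ {0.3, 0.5, 0.8} to ~1e-8.

Fusion properties default to the untreated-drug DSC values
(T<sub>m</sub> = 145.3 °C, ΔH = 165.6 J/g × 180.16 g/mol = 29.83 kJ/mol);
the source never states which DSC row fed its calculation, so this is
configurable. No ΔC<sub>p</sub> correction is applied (the working equation
omits it).

With these inputs the neat-ethanol prediction at 25 °C is x = 0.0445,
+13 % from the published 0.0395. Water-rich compositions are predicted far
lower than the published values (the model's γ for ASA in nearly pure water
is ~10⁶ here versus ~10² implied by the published table); since the
published per-point comparisons also depend on unpublished solution
densities, they are treated as indicative only. The solubility profile is
monotone and smooth on the log scale; because x spans several decades from
water to ethanol, smoothness is asserted as a bound on |Δ ln x| per 0.1 f₁
step rather than on the linear scale (where even the published predictions
jump by > 50 % between adjacent points).

## Evaluation

MRD% is computed on the linear concentration scale. When temperatures have
unequal point counts the pooled MRD% differs from the mean of
per-temperature values, so reports carry both. For the log-linear model on
the packaged data the per-temperature values are 37.6 (25 °C) and 44.5
(37 °C) and the pooled value is 41.0; the published table assigns 41.0 to
37 °C and 44.5 to "overall", which is inconsistent with its own definition —
the package reports the recomputed assignment.

Percent crystallinity integrates designated reflections (defaults 7.8° and
15.6° 2θ, half-width 0.5°) by the trapezoidal rule after subtracting a
straight baseline through the window edges, relative to the full trace
area. On synthetic diffractograms with a known 40/60 crystalline/amorphous
split the estimate is within 1 percentage point.

## Synthetic data

Noise on solubilities is multiplicative (Gaussian on ln C, default SD 0.05):
solubility is strictly positive and the evaluation metric is a relative
deviation. The recorded value is a single draw; the SD column is the sample
SD of three further replicate draws, mimicking a triplicate assay. The
default design mirrors the real one (11 fractions × 2 temperatures). Two
statistical contracts are tested over seeded replicates: the mean refitted
J₀ lies within 2 % of truth (200 replicates), and the true model's self-MRD%
matches the folded-normal mean 100·(e^{σ√(2/π)} − 1) ≈ 4.07 % at σ = 0.05
(500 replicates, tolerance 0.35 covering Monte-Carlo error plus the
small-σ approximation).

Because the anchor solubilities enter every Jouyban–Acree regression row,
anchor noise is correlated across rows; interval coverage for J₀ is
therefore checked with a parametric bootstrap (simulating mixture and anchor
noise at the estimated residual scale), which attains ~91 % coverage of
truth by nominal-95 % intervals — a case-resampling bootstrap is
inconsistent for this design and undercovers (~80 %).

What the generators do **not** emulate: drift or autocorrelation in the
assay, hydrolysis kinetics over time (the degradation product is recorded,
not modelled), heteroscedasticity beyond the constant ln-scale SD, and
diffractogram artifacts (preferred orientation, instrument broadening).
Passing tests demonstrate correct statistical behavior under the stated
noise model, not robustness to real-world assay pathologies.

## Problem sizes

The test suite runs the full 22-point dataset everywhere it matters, 200–500
replicate synthetic studies for the statistical contracts, and a handful of
PC-SAFT/SLE states (the 11-point SLE profile once); the whole suite
completes in well under a minute on one CPU.

## Known limitations

* PC-SAFT pure-component parameters are inputs; no regression of them.
* No vapor–liquid flash, no polar/ionic terms, no eutectic or
  co-precipitation modelling; the degradation product is excluded from the
  SLE composition.
* Abraham descriptors are user-supplied numbers (no structure handling).
* The ΔC<sub>p</sub> term in the SLE working equation is not implemented.
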