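# Methods

## The measurement model

The package analyses ternary solutions: a solute A (amino acid or peptide)
dissolved at molality m_A in a mixed solvent of water plus a co-solvent B
(here an ionic liquid) at molality m_B.  The *solvent* for all molality and
baseline purposes is the water + co-solvent mixture: the baseline density
ρ₀ and sound speed u₀ at each (m_B, T) are taken from a measured m_A = 0
row of that group, never interpolated and never replaced by a water
correlation.  This matters because the transfer functions are defined
against exactly that mixed reference solvent.

All internal quantities are strict SI (kg m⁻³, mol kg⁻¹, m³ mol⁻¹, Pa⁻¹).
Published tables in this field mix scale factors (10⁻⁶ m³ mol⁻¹ for
volumes, 10⁻⁶ m³ mol⁻¹ GPa⁻¹ for compressions); conversion happens only at
the output boundary (`solvatherm.units`), which avoids the scale ambiguities
that plague cross-table comparisons.

## Derived quantities

**Apparent molar volume.**  V_φ = M/ρ − (ρ − ρ₀)/(m_A ρ ρ₀), algebraically
identical to the total-volume definition ((1 + m_A M)/ρ − 1/ρ₀)/m_A.  The
identity is enforced by property tests (≤10⁻¹² relative on random inputs)
and pins the implemented form: any correct variant must satisfy it.

**Compressibility.**  K_s = 1/(u²ρ) (Newton–Laplace; isentropic because the
acoustic perturbation is fast and small), and
K_φ,s = M K_s/ρ + (K_s ρ₀ − K_s0 ρ)/(m_A ρ ρ₀), equivalent to
((1 + m_A M) K_s/ρ − K_s0/ρ₀)/m_A.  Negative K_φ,s is expected for
zwitterionic solutes: the electrostricted hydration shell is stiffer than
bulk solvent.

**Molality basis.**  The molality-based (not molarity-based) forms are used
throughout; all concentration columns of the reference tables are
mol kg⁻¹.

## Limiting fits

Both apparent properties are extrapolated to infinite dilution with
Y(m_A) = Y⁰ + S·m_A by unweighted OLS.  The linear-in-m form (not the √m
Masson form for electrolytes) reflects the near-ideal behaviour of
zwitterionic non-electrolytes over the working range (≈0.05–0.40 mol kg⁻¹),
and matches the single-experimental-slope convention of published tables.
Inverse-variance weighting is available (`weighted=True`) but is not the
default, since per-point instrument uncertainties are nominally uniform.

Two standard errors are reported per coefficient:

* `se_intercept` / `se_slope` — classical residual-based OLS errors with
  n − 2 degrees of freedom.  This is the convention behind parenthetical
  errors in published tables and is kept for comparability.
* `se_intercept_meas` / `se_slope_meas` — measurement-propagated
  (delta-method) errors.  The OLS estimator is a fixed linear map H of the
  apparent values, so its covariance follows exactly from the known
  measurement-noise structure: per-point independent contributions (solution
  ρ and u, which enter as ≈1/m_A and therefore blow up toward the dilute
  end) plus *common-mode* contributions from the single shared baseline
  (ρ₀, u₀) of the dilution series.  var = Σ H²σ²_indep + Σ_shared (H·g)²
  with g the baseline jacobian times its sigma.

The distinction is not cosmetic.  Monte Carlo at instrument-scale noise
shows the residual-based interval covers the true limiting volume in only
~40% of replicates (the shared-baseline error is invisible to residuals and
the heteroscedasticity violates the OLS assumptions), while the propagated
interval is calibrated (~95% two-sigma coverage, empirical-sd/se ratio
≈1.0).  Uncertainty statements about limiting values should therefore use
the `_meas` errors; the classical ones exist to mirror the printed-table
convention.

## Temperature model, expansibility, Hepler classification

V⁰_φ(T) = a + b(T − T_ref) + c(T − T_ref)² with T_ref = 298.15 K.  The
reference temperature is pinned by the observation that, in the study
system's published tables, the 298.15 K expansibility column equals b
exactly for every row.  E⁰_φ = b + 2c(T − T_ref); its temperature
derivative is the constant 2c, which carries Hepler's criterion:
(∂²V⁰_φ/∂T²)_p > 0 → structure-maker, < 0 → structure-breaker.  The default
classification tolerance is zero; passing the propagated se of 2c as `tol`
avoids over-claiming from noise, and with only four temperatures the
curvature is genuinely noise-sensitive (noisy synthetic campaigns can flip
the sign of 2c even when limiting volumes are recovered well).

Coefficients are kept signed internally.  Published coefficient tables for
the study system print |c|; the bundled copy adds the sign inferred from the
expansibility trend (E⁰_φ decreasing with T forces c < 0, as for the
dipeptide at low m_B).  Classification is invariant to the choice of T_ref
(a translation of the quadratic's argument), which is property-tested.

Two fit-quality metrics are computed because the field's σ column is
ambiguously defined: residual_sd = √(RSS/(n − 3)) (units of V⁰_φ; NaN at
n = 3 where there are no residual degrees of freedom) and the dimensionless
mean absolute relative deviation.  Neither is used as a validation target.

## Transfer functions and interaction coefficients

Transfers are differences of limiting fits at equal (solute, T, property):
ΔY⁰ = Y⁰(m_B) − Y⁰(m_B = 0), with quadrature-combined standard errors.
They are never computed from raw apparent values, because the definition
lives at infinite dilution.

The McMillan–Mayer expansion ΔY⁰(m_B) = 2 Y_AB m_B + 3 Y_ABB m_B² is fitted
with zero intercept (Δ(0) = 0 by construction) and both coefficients
jointly.  The implementation is pinned against the 2×2 normal-equations
closed form.

A documented inconsistency in the study system's published coefficient
table: refitting the published transfer compressions reproduces the
published pair/triplet compression coefficients divided by exactly 10 and
100 respectively, for all eight (solute, T) cells — the signature of a fit
performed with m_B rescaled by 0.1.  The bundled copy of that table is
therefore kept verbatim for documentation but is not used as a validation
reference; the volume coefficients (fitted to supplementary data not in the
main tables) are likewise not validation targets.

## Synthetic generator

The generator emulates the study design: four temperatures (288.15, 298.15,
308.15, 318.15 K), five co-solvent molalities (0.00–0.40 mol kg⁻¹), an
8-point solute-molality grid on [0.05, 0.40] mol kg⁻¹, and Gaussian
instrument noise with σ_ρ = 0.05 kg m⁻³ and σ_u = 0.4 m s⁻¹ — half the
instrument's expanded uncertainties, reading those as 2σ (coverage factor
2).  Target apparent properties V⁰_φ(T) + S_v m_A and K⁰_φ,s(T) + S_k m_A
are inverted *exactly* to noiseless (ρ, u) — the inversions are closed-form
and property-tested to ≤10⁻¹² — and noise is then added to solution and
baseline rows alike.  The default ground truth takes its temperature-model
coefficients and limiting compressions/slopes from the bundled reference
tables, with a volume slope of 0.5×10⁻⁶ m³ mol⁻¹/(mol kg⁻¹), a typical
positive experimental slope for these solutes.  Default baselines are
water-like constants (997.047 kg m⁻³, 1496.7 m s⁻¹ at 298.15 K) with mild
linear m_B and T trends; no water equation of state is embedded.

Randomness is confined to the generator: each row draws from a
counter-based substream keyed by (seed, canonical row position), so output
is byte-reproducible and independent of iteration order, and every
downstream stage is deterministic.

What the generator does *not* emulate: instrument drift and hysteresis,
temperature-dependent noise, ρ–u error correlation, and deviations from
linear concentration dependence.  Passing recovery tests therefore
demonstrates correctness of the analysis chain under its own statistical
assumptions, not robustness to real-instrument systematics.

## Numerical choices and degenerate inputs

- OLS via numpy least squares; standard errors from the closed-form
  covariance.  Oracles in the test suite (normal equations, Vandermonde
  solve, finite-difference jacobians) are implemented independently of the
  code paths they check.
- Limiting fits require ≥2 distinct m_A > 0 (≥3 for standard errors);
  temperature fits require ≥3 distinct temperatures; interaction fits
  require ≥2 distinct m_B > 0.  Groups failing preconditions are collected
  into skip reports, never silently dropped.
- Duplicate measurement keys, missing baselines (named by group), and
  non-numeric cells (named by row) are hard errors at read time; validation
  is order-independent.
- Result CSVs are written with fixed formatting and stable column order;
  rewriting the same table is byte-identical, and a JSON manifest (seed,
  config hash, content hash) accompanies each result table.

## Problem sizes

The test suite and the reproduction script run on desk-scale inputs: the
full synthetic campaign is 340 rows, Monte-Carlo calibration checks use 200
replicates of a single-condition 8-point series, and oracle comparisons use
500–1000 random small instances.  These sizes give comfortably
stable statistics for the properties asserted (binomial 2σ on a 95%
coverage estimate over 200 replicates is ±3 percentage points).

## Known limitations

- The uncertainty model treats ρ and u as independent; the instrument
  reports both from one cell, and any common temperature-control error is
  not represented.
- The quadratic temperature model is the highest order supported; with four
  temperatures a cubic would be saturated.
- Transfer standard errors combine the two limiting-fit errors in
  quadrature, ignoring the (small) correlation induced by shared water
  references across m_B values at fixed T.
- No excess-property (V^E) or enthalpic interaction coefficients.
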