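# Methods

This note records the model equations, numerical choices and known limits
of the implementation.

## 1. SVD of spectral series

The raw (uncentered) wavelength × condition matrix X (m × n) is factorized
by a thin SVD, X = UΣVᵀ, keeping r = min(m, n) components. Columns of U
are unit-norm basis spectra, columns of V unit-norm amplitude vectors.

**Sign convention.** SVD signs are arbitrary; for reproducible output the
largest-magnitude element of each U column is made positive (first index on
ties) and the matching V column flipped to compensate. Repeated runs on the
same input agree bit for bit.

**Diagnostics.** Explained variance of component i is σᵢ²/Σσⱼ². The lag-1
autocorrelation C(v) = Σᵢ vᵢvᵢ₊₁ / Σᵢ vᵢ² is near 1 for smooth vectors
(a constant vector of length n scores (n−1)/n), near 0 for white noise.
A component is flagged significant when *both* C(uᵢ) > 0.8 and
C(vᵢ) > 0.8; the threshold is a conventional choice exposed as a
parameter. A cumulative-explained-variance selector (default 98%) is
provided as an alternative.

**Reference-spectrum constraint.** Given a measured spectrum of a known
state (interpolated onto the data grid, no extrapolation), the first basis
vector is pinned to u₁ = ref/‖ref‖, its amplitude row is the least-squares
projection a = u₁ᵀX, and the remaining components are the thin SVD of the
deflated residual X − u₁a. Because the residual lives in the
(m−1)-dimensional subspace orthogonal to u₁, up to min(m−1, n) residual
components are kept; when the reference points partly outside the data
column space the total component count can be min(m, n) + 1. This keeps
the all-component reconstruction exact in every case. A reference
(numerically) orthogonal to the data produces a warning, not an error.

## 2. Unfolding models

Temperatures are converted to kelvin internally; user-facing values are in
°C. R = 8.314 J mol⁻¹ K⁻¹.

**Equilibrium steps** use the Gibbs–Helmholtz form (ΔH in kJ/mol, ΔCp in
kJ mol⁻¹ K⁻¹, both referenced to the midpoint Tm):

ΔG(T) = ΔH (1 − T/Tm) + ΔCp (T − Tm − T ln(T/Tm)),
K(T) = exp(−ΔG·1000 / (R T)) (exponent clipped at ±700).

**Irreversible steps** use a rate constant parameterized by the activation
energy Eₐ (kJ/mol) and the temperature T_f where k = 1 min⁻¹:

k(T) = exp(−(Eₐ·1000/R)(1/T − 1/T_f)).

Schemes:

* `two_state_rev` (N ⇌ D): f_N = 1/(1+K).
* `three_state_rev` (N ⇌ I ⇌ D): f_N = 1/(1+K₁+K₁K₂), f_I = K₁ f_N,
  f_D = K₁K₂ f_N. A soft penalty keeps Tm₁ ≤ Tm₂ during fitting.
* `two_state_irrev` (N → D): during a scan at rate v (°C/min),
  df_D/dT = k(T)(1 − f_D)/v, integrated by classical RK4 with the
  temperature step subdivided to ≤ 0.1 °C. Halving the substep changes the
  fractions by < 1e-6 over the tested parameter ranges, and the Eₐ = 0
  (constant-rate) case matches the closed-form exponential to the same
  level.
* `three_state_partial` (N ⇌ I → D, rapid pre-equilibrium):
  df_D/dT = k(T) f_I / v with f_I = K₁(1 − f_D)/(1 + K₁), same integrator.

**Isothermal kinetics** (time grids in seconds, rates per minute):
`two_state_irrev` decays exponentially at k(T); `two_state_rev` relaxes
toward equilibrium at k_u + k_f with k_f = k_u/K (so fitting kinetic data
with this scheme requires Eₐ and T_f for the unfolding rate);
`three_state_partial` decays at k·K₁/(1+K₁). For `three_state_rev` the
relaxation rule above is defined only for a single transition, so
isothermal fractions are returned at instantaneous equilibrium — a
deliberate simplification; do not use this scheme for kinetic traces whose
relaxation time matters.

**DSC.** Cp(T) = (a_N + b_N T) f_N + (a_D + b_D T)(1 − f_N) + d⟨H⟩/dT,
where ⟨H⟩ is the population-weighted enthalpy (H_I = ΔH₁(T),
H_D = ΔH₁ + ΔH₂ for the sequential scheme). For equilibrium schemes the
excess term is evaluated analytically via the van't Hoff derivative
d ln K/dT = ΔH(T)·1000/(R T²); for kinetic schemes numerically via
`np.gradient`. Closed-form checks: the two-state peak height equals
ΔH²·1000/(4 R Tm²) within 0.02% on a 0.01 °C grid (the true maximum sits
slightly below Tm because of the 1/T² factor), and the excess-heat area
conserves the total enthalpy to < 0.01%.

## 3. Global fitting

One shared thermodynamic/kinetic parameter set is fitted simultaneously to
any mixture of DSC, scalar melt, isothermal kinetic and SVD-amplitude
datasets. Each dataset adds its own linear observable parameters: per-state
baselines a_s + b_s T for scalar signals (DSC fits only native and
denatured baselines; intermediate baseline slopes are fixed at zero unless
requested), or a k × n_states coefficient matrix for SVD amplitude blocks.

**Weighting.** Each dataset is weighted by w = 1/(n_points · span²), span
being its peak-to-peak signal range, so every dataset contributes an O(1),
unit-free share of the penalty regardless of length or units. SVD
amplitude blocks are weighted *per component* with the same rule:
a hidden intermediate lives in a component whose span is two orders of
magnitude below the first, and a single per-dataset weight would let the
optimizer ignore it.

**Optimizer.** Bounded trust-region-reflective least squares
(`scipy.optimize.least_squares`, `x_scale='jac'`), with optional seeded
Latin-hypercube multi-start over the finite-bounded free parameters. A
model-evaluation failure at absurd trial parameters yields a
large-residual sentinel instead of an exception so the optimizer can back
away. If no start improves on the initial point, the initial point is
reported with `converged = False`.

**Uncertainties.** Standard errors come from s²(JᵀJ)⁻¹ with
s² = wssr/(N − p) at the solution — the usual linearized approximation;
they are indicative, not confidence intervals. Nested models are compared
with the F-ratio ((wssr₁ − wssr₂)/Δp) / (wssr₂/(N − p₂)).

**Spectra from fits.** Fitted spectra are X_fit = U[:, :k] · curvesᵀ and
per-state fingerprints F = U[:, :k] · C; the fraction-weighted sum of
fingerprints reproduces X_fit exactly.

## 4. Synthetic data generator

Each macrostate contributes a smooth unimodal emission band (Gaussian or
log-normal) with an optional linear per-state baseline drift;
X(λ, T) = Σ_s spectrum_s(λ)(1 + drift_s(T − T₀)) f_s(T) + ε, with ε i.i.d.
Gaussian from a seeded PCG64 generator. The same machinery produces DSC
thermograms, scalar melt curves and isothermal traces from one ground
truth.

Shipped presets:

* `two_state_fluor` — clean two-state melt (Tm 50 °C, ΔH 400 kJ/mol,
  150 temperatures, 1% noise); the parameter-recovery workhorse. Over 20
  seeds the fitted Tm has an RMSE of ~0.05 °C and ΔH a relative RMSE of
  ~2%.
* `three_state_hidden_intermediate` — a scarcely populated intermediate:
  the intermediate band (341 nm) was chosen close to the span of the
  native (330 nm) and denatured (352 nm) bands, so the third SVD component
  carries only ~0.2% of the variance and every conventional scalar signal
  shows a single apparent transition near 50 °C, while the third amplitude
  curve shows two. These spectra were fixed up front from the target
  scenario, not adjusted afterwards.
* `irreversible_scanrate_series` — kinetically controlled melt
  (Eₐ 300 kJ/mol, T_f 60 °C) whose apparent midpoint rises by several °C
  per decade of scan rate.
* `dsc_two_peaks` — sequential three-state thermogram with two resolved
  excess-heat peaks at 45 and 55 °C.

Realism limits: noise is additive, homoscedastic and uncorrelated (real
detectors are closer to shot-noise-limited, with wavelength-dependent
variance); bands are unimodal and drift linearly; no stray-light, buffer
mismatch or aggregation artifacts. Recovery statistics from this generator
are therefore best-case.

## 5. File I/O precision

CSV output is written at 17 significant digits and parsed with
correctly-rounded float conversion, so a CSV round trip is bit-for-bit
exact. xlsx cells are serialized at 16 significant digits (a limit of the
workbook format's text representation), so an xlsx round trip is exact to
one unit in the last place; a second write/read cycle is then stable.

## 6. Known limitations

* Four schemes only; parallel, multi-domain and oligomeric mechanisms are
  out of scope.
* `three_state_rev` isothermal traces are equilibrium snapshots (see §2).
* Baselines are linear in temperature; curvature must be handled by
  restricting the fit range (`normalize` with a temperature window).
* Standard errors ignore parameter correlations beyond the linearized
  covariance, and the Tm-ordering penalty can bias errors when the two
  transitions nearly coincide.
* The significance rule assumes noise is uncorrelated along both axes;
  smooth systematic artifacts (lamp drift) will be flagged as signal.
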