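# Methods

This note documents the models implemented in `tscocryst`, the
parameters that matter, the numerical choices, and what the synthetic
generators do and do not emulate.

## Spectral model and normalization

A Raman spectrum is a strictly increasing wavenumber grid (cm⁻¹) with
one intensity per point. Every analysis step operates on min–max
normalized intensities, `x̄ = (x − min)/(max − min)`, which is
idempotent and invariant under positive affine rescaling — so arbitrary
instrument intensity units never matter. Normalizing a constant
spectrum is an error (`DegenerateSpectrum`), not a silent zero.

The default grid is 1,000 uniformly spaced points over 400–3750 cm⁻¹
(spacing ≈ 3.35 cm⁻¹). The window excludes the low-wavenumber phonon
region and reaches high enough to capture solvent-affected bands. Grid
spacing is configurable through `SpectralGrid`. Resampling is linear
interpolation and refuses to extrapolate (`CoverageError`): intensity
is never fabricated outside the measured span. Band restriction (e.g.
the 700–1200 cm⁻¹ window conventionally used to monitor one cocrystal
marker band) keeps exactly the in-window grid points; restricted
spectra are re-normalized before fitting.

## Polynomial unmixing kernel

The mixture spectrum R is modelled as a pointwise polynomial in the
P = N + 2 normalized basis spectra (N fingerprints plus the isolated
molecules A and B), truncated at third order. Since elementwise
products commute, the symmetric duplicates of the full double/triple
sums are collapsed to unique multiset columns: the design matrix has
1 + P + P(P+1)/2 + P(P+1)(P+2)/6 columns. Duplicated columns would add
nothing to the model space and only worsen conditioning.

The system R = ρA is solved by the Moore–Penrose pseudoinverse
(minimum-norm least squares), which tolerates singular ρ. Two
singular-value cutoffs are exposed:

* `DEFAULT_RCOND = 1e-10` — tight; preserves exact algebraic recovery
  on noiseless consistent systems (noiseless linear-only mixtures are
  recovered to ~1e-13).
* `MEASUREMENT_RCOND = 1e-3` — coarse; used by the controller-facing
  `estimate_fractions` and the plant-survey pipeline. The polynomial
  design matrix is severely ill-conditioned (condition numbers ~1e9
  for a 6-fingerprint library at order 3), so with percent-level
  spectral noise the small singular directions only inject noise into
  the linear coefficients. Truncating them is ordinary truncated-SVD
  regularization: at 1 % additive noise it reduces worst-case weight
  errors from ~0.8 to ~0.03 while biasing noiseless recovery by < 0.005.

Weights are `a′ᵢ = aᵢ / Σ_fingerprints aⱼ`; the isolated-molecule
coefficients are removed and reported separately as the noise share.
Because mixture normalization is an affine map absorbed by the constant
column and a common linear rescaling, the weights are invariant to it
(the raw coefficients are not). Negative weights are reported as-is by
default; a clip-and-renormalize flag (on in the controller path)
produces proper fractions. A denominator below 1e-12 raises
`ZeroDenominator` — the all-noise case; `is_noise_dominated` offers a
softer flag when tiny residual fingerprint coefficients survive.

Identifiability: with the full 21-fingerprint library at order 3 the
design matrix has 2,600 columns against 1,000 grid points; the
minimum-norm solution is still returned and the effective rank
reported, but quantitative weights then depend on spectral
distinctness. The quantitative pipelines use 6–7-fingerprint libraries,
which are full column rank at order 3.

The reconstruction error is reported as ‖R − R̄‖/‖R‖ in percent
(norm-relative; a per-wavelength maximum would be an alternative
reading). Order-3 fits of mixtures contaminated with fourth-order
cross terms at 1 % of the linear amplitude reconstruct to mean errors
far below 0.5 % — most of the fourth-order component lies inside the
order-3 column span.

## Synthetic fingerprint generator

A stand-in for quantum-chemistry-computed fingerprint spectra. Each
basis spectrum is a sum of Lorentzian lines (the natural Raman line
shape): one dominant marker line of amplitude 1 plus 3–6 minor lines
(amplitude ≤ 0.35, HWHM 8–30 cm⁻¹, positions seeded), then normalized.
Marker positions are spread evenly over 600–3600 cm⁻¹ so every
component has a distinguishing band and the unmixing problem is
identifiable; CO-5's marker is pinned at 2250 cm⁻¹ (the 2000–2500 cm⁻¹
band where that cocrystal pair emerges) and CO-2's at 950 cm⁻¹ (inside
the 700–1200 cm⁻¹ monitoring window). Generation is bit-reproducible
for a given (config, seed).

What this does **not** emulate: realistic relative cross-sections,
band congestion of real condensed-phase spectra, baselines, cosmic-ray
spikes, or instrument response. Passing tests demonstrate the algebra
and the pipeline logic, not performance on laboratory spectra.

Mixtures are synthesized with the same polynomial forward model
(optionally with fourth-order contamination to probe truncation), plus
additive Gaussian noise on intensities, then normalized.

## Design space and the gauge parameter M

`M = ψ·t·τ·f/L` is adopted as the reading of the gauge parameter — the
only grouping of those symbols that is dimensionless when τ carries
inverse time. ψ defaults to 1 and is exposed as configuration only; no
calibration procedure is implemented. M is linear and strictly
increasing in t, τ and f, decreasing in L.

Design-space axes default to T ∈ [298, 400] K in 5 bins — matching the
five simulated operating temperatures (room temperature up to just
above the coformer melting point) — and M ∈ [0, 1] in 20 bins. Cell
aggregation is the arithmetic mean of contributing weight sets, which
conserves the sum-to-one property. Cells without estimates are NaN
("not computed") and are never imputed; stored values below 1e-5 are
flagged blank ("nearly zero") — two distinct states.

`find_optimum` returns the single cell maximizing the summed target
fraction, with exact ties broken toward the lowest temperature and
then the lowest M; the window is reported in axis units. `lookup`
interpolates bilinearly over occupied neighbor cell centers, excluding
missing neighbors (renormalizing the weights) and flagging the
exclusion. `screw_speed_for_M` inverts M algebraically for the shear
rate and converts to rotation speed through a user-supplied
proportionality `tau_per_speed` — whether the gauge's τ is the
molecular shear rate or the screw speed itself is deliberately left to
the user's machine calibration.

The `FractionField` fixture encodes ground-truth fraction surfaces
(Gaussian bumps, exponential decays, flats, normalized to sum to one)
over (T, M). The default field places the combined CO-5 + CO-2 optimum
near 345 K and M ≈ 0.48, with one cocrystal decaying in M, two
near-zero cocrystals and a mild dimer background — the qualitative
shape of a system where one cocrystal pair dominates in a band of
conditions. Its `encoded_optimum` is computed from the field itself
with the same argmax rule the design space uses, so end-to-end tests
compare pipeline output against the field's own truth rather than
hard-coded cells.

## Coexistence screening

Both standard routes to the Flory–Huggins χ are provided, because
published fraction maps imply some negative values while solubility
parameters can only give χ ≥ 0:

* solubility route: χ = V_ref (δᵢ − δⱼ)² / (R T), δ in MPa^0.5,
  V_ref default 1e-4 m³/mol (typical small-molecule molar volume);
* exchange-energy route (default in the CLI): χ = z (wᵢⱼ − (wᵢᵢ +
  wⱼⱼ)/2) / (R T), energies in kJ/mol, coordination number z default 6.

Pairs are classified miscible when χ ≤ ½(1/√mᵢ + 1/√mⱼ)² (the binary
critical value; 2 for unit segment counts). No binodal/spinodal
construction is attempted.

## Rheology

Carreau: μ = μ∞ + (μ₀ − μ∞)[1 + (λγ̇)^α]^((n−1)/α), α fixed at 2.
Fitting is nonlinear least squares on ln μ (the data span many decades
of shear; log residuals weight them evenly) with a single (λ, n)
shared across all temperatures and one μ₀ per temperature — the
temperature dependence enters only through the plateau. μ∞ is fixed at
0 by default: it is not identifiable unless the data reach the
high-shear plateau, and the power-law reduction drops it anyway.
Initialization is a deterministic multi-start over candidate λ values
taken from the reciprocal shear rates of the data; the lowest final
cost wins. The log-domain shape term uses `logaddexp` for overflow
safety. R² is reported on the fitted (log) scale.

Arrhenius: ln μ regressed on 1/T; A = exp(intercept), E/R = slope. The
refined relative form μ/μ₀ = exp[E/R (1/T − 1/T₀)] is provided for the
temperature-sensitive regime (the switch threshold, conventionally
around 35 °C, is configuration, not hard-coded). Note the generator's
default constants (A = 610.75 cP, E/R = −736.64 K) make viscosity
*increase* with temperature under μ = A·exp(E/R·T⁻¹); the fitting is
sign-agnostic and recovers whatever constants generated the data. The
synthetic viscosity table applies multiplicative lognormal noise so
positivity is preserved.

## Controller

The design space acts as the decision surface. The state-to-M mapping
uses a fixed configured residence time t and τ = tau_per_speed · speed,
so M is linear in speed and speed is an effective actuator. (The
superficially natural proxy t = L/(f·speed) makes M independent of
speed when τ is itself proportional to speed — the two dependencies
cancel — so it cannot serve a speed-steering controller; the mapping
is config-replaceable for real installations.)

Policy: inside the optimum window, hold. Outside, step T toward the
window's temperature band only while T is outside it (default 5 K per
move) and step speed toward the M band (default 10 % per move), both
clamped to actuator bounds — speed is the preferred handle because
barrel temperature is slow and lossy to manipulate on an uninsulated
machine. This is a deliberately minimal, step-limited policy (no
gains, no model-predictive element); a hold is a fixed point.

## Problem sizes and determinism

The pipeline tests survey 5 × 20 (T, M) cells with one synthesized
1,000-point mixture each (6–7 fingerprint libraries, order 3, ≈ 220
design columns) and run 50-step closed loops over 5 seeds; the whole
suite runs in well under a minute on one core. All randomness flows
through `numpy.random.default_rng` seeds passed explicitly; identical
seeds give bit-identical libraries, mixtures, tables and trajectories.

## Known limitations

* Synthetic spectra are idealized (see above); no baseline correction,
  cosmic-ray removal or instrument-response deconvolution is provided —
  inputs are assumed preprocessed.
* Weight identifiability degrades with overlapping fingerprints and in
  the underdetermined 21-fingerprint/order-3 regime; rank and
  conditioning are reported so callers can detect it.
* The optimum search returns a single best cell (plus tie-break), not a
  connected plateau region.
* χ matrices from real interaction energies, and real fraction maps,
  depend on electronic-structure/molecular-dynamics inputs that are out
  of scope; the package consumes such descriptors, it does not compute
  them.
* No spectrometer drivers or plant integration; the controller is a
  simulation-grade sketch of the decision loop.
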