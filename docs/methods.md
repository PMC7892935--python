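# Methods

This note documents the model implemented in `injeradry`, the closures it
uses, the meaning and defaults of the tunable parameters, the numerical
scheme, what the synthetic data generator does and does not emulate, and
the known limitations.

## The physical problem

A fresh injera slab (3 cm thick, 30 cm diameter, ~61 % moisture wet basis,
porosity 0.74) sits on a mesh tray in a tunnel dryer. Hot dry air (323.15
or 333.15 K, 0.25 or 0.5 m/s, relative humidity 15.7 or 11 %) flows over
it. The quantity of interest is the dimensionless moisture ratio

    MR(t) = (X(t) - Me) / (X0 - Me)

where X is the volume-averaged dry-basis moisture, X0 its initial value
and Me the equilibrium moisture obtained by inverting the sorption
isotherm at the air state. Drying is considered complete at MR = 0.03.

## Governing equations

On the sample grid (1-D through-thickness by default; 2-D axisymmetric
optionally) the solver integrates a single total-moisture concentration
c (mol/m³) and the temperature T (K):

    dc/dt = div(D grad c) - u_d·grad c - Sm
    (ρcp)_eff dT/dt = div(k_eff grad T) - ρ_f cp_f u_d·grad T + Sh

with the non-equilibrium evaporation source

    Sm = K_vap (a_w(X) c_v,sat(T) - c_v),     Sh = -H_evap M_v Sm.

`a_w(X)` is the sorption isotherm
`exp(-0.0267 X^-1.656 + 0.0107 e^(-1.287X) X^1.51)` (the sign reading with
the correct limits a_w(0)=0, a_w(∞)=1), and `c_v,sat = p_v,sat/(RT)` with
the six-term saturation-pressure correlation. Evaporation consumes latent
heat (H_evap = 2.454 MJ/kg), so the source term cools the matrix; the sign
convention is chosen so that the early drying stage shows the evaporative
cooling plateau before the sample relaxes to the air temperature.

Boundary faces exchange heat and vapour with the air through film
coefficients (below); the tray side is insulated by default (`bottom =
"convective"` switches it). Darcy advection `u_d = (k_ii k_r/μ) grad p`
is available behind the `darcy` flag with a user-supplied constant
pressure gradient, and is off by default: no internal pressure equation
is posed, so transport is diffusion plus distributed evaporation.

## Closures

Three closure ingredients connect the printed equations into a solvable
model. They are physical modelling choices of this package, each exposed
as an ordinary configuration entry:

1. **Pore-vapour split (ventilation).** The pore vapour c_v entering the
   evaporation source is taken from a quasi-steady balance between the
   K_vap relaxation toward local equilibrium and an exchange with the
   drying air at the pore-ventilation rate N (`vent_rate`, default
   0.2 1/s):

       c_v = (K_vap a_w c_v,sat + N C_a) / (K_vap + N)

   which collapses the source to Sm = G (a_w c_v,sat - C_a) with
   G = K_vap N/(K_vap+N) and C_a = (RH/100) c_v,sat(T_air). For
   K_vap ≫ N the result is independent of K_vap — the strong-evaporation
   regime; the sweep over K_vap ∈ {10², 10³, 10⁴} 1/s moves the drying
   time by under 0.1 %. The vapour removed this way is swept into the
   air stream: it leaves the moisture balance through the source
   bookkeeping, which the run report closes against storage change and
   boundary flux.

2. **Exchange-area factor.** The film coefficients h_T and h_m from the
   flat-plate correlations describe a smooth impermeable surface, while
   injera exposes a strongly enlarged open-pore surface ("eyes") to the
   flow. A single multiplier `area_factor` (default 20.5) scales both
   films identically, preserving the heat/mass-transfer analogy.

3. **Capillary diffusivity.** Internal liquid transport uses a constant
   effective capillary diffusivity `capillary_diffusivity` (default
   1.61e-7 m²/s). The gas-phase effective diffusivity
   D_g = D_va ε^(3/4) S_g^(10/3) transports only the vapour share of the
   moisture: it enters multiplied by the local equilibrium-vapour slope
   ∂c_v/∂c = c_v,sat (da_w/dX)(dX/dc), so it matters only where the
   isotherm is steep (nearly dry material). Applying D_g to the total
   moisture instead would short-circuit the wet core through the dried
   surface layer and make the internal resistance vanish.

The three constants were fixed once, together, against the reference
tunnel observations (drying time 125 min at 333.15 K/0.5 m/s/RH 11 %, and
150 min at 323.15 K/0.5 m/s/RH 15.7 %), and then frozen as the package
defaults. The two observations constrain two effective resistances — the
external/exchange-limited early phase and the internal diffusion-limited
falling-rate phase — whose different temperature sensitivities fix the
split between them; N then sits in the insensitive strong-evaporation
plateau. No per-condition tuning exists: the 323.15 K prediction, the
0.25 m/s predictions and every derived quantity (kinetic constants,
effective diffusivity, temperature histories) follow from the same three
constants.

## Why a closure at all

A strict film model with the correlation coefficients cannot dry this
sample in the observed time: with h_m ≈ 4.2e-3 m/s and a surface vapour
concentration bounded by c_v,sat ≈ 7.3 mol/m³, the film-limited time for
the 1,492 mol/m² inventory is of order 900 min, and the latent-heat
budget through h_T ≈ 100 W/(m²K) gives a similar bound. The observed
125 min therefore requires an exchange several times the flat-plate
value, which the open-pore area factor and ventilation exchange encode.
The model makes that enhancement explicit and calibrated rather than
implicit.

## Properties

Solid-matrix properties come from the mass-fraction mixture rules over
the shipped component polynomial correlations (Choi–Okos family, t in
°C, valid 273–473 K, enforced with explicit range errors):

* density ρ = 1/Σ(x_i/ρ_i(T)) — reproduces the measured 1136.49 kg/m³
  at 323.15 K within 1.4 %;
* specific heat cp = Σ cp_i x_i — gives ≈3190 J/(kg·K), which does
  **not** reproduce the measured 3676 J/(kg·K); no standard component
  correlation does, so this value is soft-logged, never asserted;
* conductivity k = Σ k_i E_i with volume fractions E_i — gives ≈0.53
  W/(m·K) against the measured 0.34–0.37; also soft-logged only.

Effective thermal properties of the porous mixture use the source-form
rules by default (`mixture_rule = "as_printed"`): (ρcp)_eff =
ρ_p cp_p − (1−ε) ρ_f cp_f and k_eff = ε k_p + (1−ε) k_f, with the pore
fluid a water/air blend by the vapour mass fraction X_v. The physically
conventional volume-fraction weighting is available as `"corrected"`.
Within the study's temperature window the two differ mainly through the
thermal inertia; the defaults were calibrated with `as_printed`.

The irreducible saturation uses S_ir = 2.88 (1/T0) (ln 1/ε)^0.48
(≈ 0.0054 at ε = 0.74), and the relative permeabilities are the cubic
water law above S_ir and k_gr = 1 − 1.1 S_w below S_w = 1/1.1, clamped to
[0, 1]; both feed the property bundle and the optional Darcy closure.

Moisture bookkeeping convention: wet basis M_wb = c M_w/ρ_p; dry basis
X_db = c M_w/((1−ε) ρ_p), i.e. the dry-matrix mass is referred to the
solid volume fraction. The printed initial concentration 49,750 mol/m³
is used as the default initial condition even though applying the
wet-basis relation to M_wb = 0.608 would give ≈38,400; the two are
mutually inconsistent in the source material, and the initial condition
wins because every MR value is normalised by X0 anyway.

Solid-matrix properties are evaluated once per run at the air
temperature; their variation over 298–333 K is below half a percent and
does not warrant per-node re-evaluation.

## Transfer coefficients

Re = ρ_a u L/μ_a, Pr = cp_a μ_a/k_a, Sc = μ_a/(ρ_a D_a) with dry-air
constants (ρ_a 1.25, μ_a 1.81e-5, cp_a 1000, k_a 0.0285, D_a 2.6e-5) and
the flow-aligned characteristic length L = 0.30 m (sample diameter).
The laminar branch (Re < 5e5, the standard assignment)

    h_T = (2 k_eff/L) · 0.3387 Re^1/2 Pr^1/3 / (1 + (0.0468/Pr)^2/3)^1/3

applies at all study conditions (Re ≈ 5.2e3–1.04e4); the turbulent
branch (0.037 Re^4/5 − 871) Pr^1/3 is implemented for completeness. The
mass coefficient is h_m = (D_a/L)(2 + 0.552 Re^1/2 Sc^1/3). Air humidity
affects only the far-field vapour concentration, not the transport
properties.

## Numerics

Node-centred finite volumes (default n_z = 61 over 0.03 m; the 2-D
axisymmetric mode adds n_r = 31 rings with the rim as an additional film
face), harmonic averaging of D and k_eff at faces, backward-Euler time
stepping (default Δt = 60 s, safely below the 5-min step-independence
threshold), and Picard iteration over the nonlinear coefficients with
the evaporation source Newton-linearized in the solved variable
(∂Sm/∂c through the isotherm slope in the moisture solve, ∂Sm/∂T through
the saturation-curve slope in the energy solve). Convergence requires a
relative moisture change below 1e-8 and a temperature change below
1e-6 K per sweep (max 50; typically ≤ 8). Non-convergence raises a step
error with diagnostics; concentrations more negative than 1e-9 of the
initial value are an error, smaller undershoots are floored with a
logged warning.

Verification: against the Fourier-series slab solution (constant D,
fixed surface concentration, insulated base) the solver is within 0.05 %
at n_z = 41, with observed spatial order ≈ 1.9 when Δt is refined with
Δz² to isolate the spatial error. Time discretisation is first order;
at the default step the MR curve carries about 1e-3 absolute truncation
(halving Δt moves MR(t) by < 0.005 everywhere), and the moisture balance
closes to round-off. The drying time is reported with linear
interpolation between output samples.

Degenerate inputs: zero exchange (area factor 0, K_vap 0) leaves MR ≡ 1;
air in equilibrium with the sample is a fixed point to 1e-10; fully
dried cells stop evaporating through the isotherm limit a_w → 0 rather
than through ad-hoc switches.

## Kinetics and statistics

Thin-layer models (time in minutes): Henderson–Pabis a·e^(−kt), two-term
b₁e^(−k₁t) + b₂e^(−k₂t), Page e^(−k t^n), fitted by bounded
least squares from fixed starting values (1, 0.02), (0.7, 0.02, 0.3,
0.005) and (0.02, 1). R² is the squared Pearson correlation between
observed and fitted series; RMSE is the root mean squared residual.
Ranking is by descending R², then ascending RMSE — both compared at the
4-decimal precision at which such constants are conventionally reported
— then by fewer parameters, which settles the nested Henderson–Pabis /
two-term comparison when the extra term buys nothing.

The effective moisture diffusivity uses the first-term Fickian slab
approximation: the least-squares slope k of ln MR against time (s) over
the falling-rate window MR ∈ [0.7, 0.05] gives D_eff = k L²/π² with
L = 0.015 m (half-thickness, two-sided exchange convention). Window and
L are arguments, not constants.

The factorial analysis is a balanced two-factor fixed-effects ANOVA with
interaction, computed from cell/marginal/grand means; p-values from the
F distribution. The response variable for the temperature × velocity
design is the mean |dMR/dt| over the first 60 min. Its type-I error is
calibrated: 5.95 % rejections over 2000 null simulations at α = 0.05.

## Synthetic data generator

`synthetic.generate_experiment` emulates the measurement structure of
the tunnel experiment: ~100 g sample (dry matter from the 60.8 %
moisture), a balance record every 1 min (Gaussian noise, SD 0.1 g,
floored at the dry-matter mass), and a centre thermocouple every 15 min
(SD 1.0 K, matching the ±1 °C instrument). Truth curves come from the
PDE simulator or a closed-form kinetics model; noise can alternatively
be applied directly in MR space (SD 0.01). Everything is seeded through
`numpy.random.default_rng`; zero-noise output is bit-identical to the
truth.

What it deliberately does not emulate: sensor drift, ambient humidity
fluctuations, psychrometer behaviour, sample-to-sample composition
variability, or shrinkage-induced mass-geometry coupling. Passing the
recovery and calibration tests therefore demonstrates the correctness of
the fitting and testing machinery under the stated noise model, not
robustness to every artefact of real dryer data.

`generate_factorial` draws replicate drying rates from an additive
cell-means model with configurable true effects, used for ANOVA power
and type-I calibration.

## Known limitations and open reproduction gaps

* The measured cp (3676 J/(kg·K)) and k (0.34–0.37 W/(m·K)) of injera
  are not recoverable from the printed mixture rules with any standard
  component correlations; they are reported as soft checks only.
* The reported Henderson–Pabis pair (rate 0.0189 1/min with α = 1) is
  mathematically incompatible with drying to MR = 0.03 in 125 min
  (e^(−0.0189·125) = 0.094): no simulated curve can reproduce both. This
  package follows the drying times; its fitted rate on the reference
  curve is ≈ 0.0244 1/min with R² = 0.9947.
* Similarly, the reported effective diffusivities imply a
  between-condition ratio of 1.68 between the 333.15 K/0.5 m/s and
  323.15 K/0.5 m/s rows, while the reported drying times imply 1.2; the
  slope method on the simulated curves gives ≈ 1.09e-8 m²/s at the
  reference condition against the reported 1.29e-8.
* On the smooth simulated curve the Page model (R² ≈ 0.9999) outranks
  Henderson–Pabis: the stretched exponential absorbs both the
  sensible-heating onset and the diffusive tail. The reported ranking
  (Henderson–Pabis first, Page last) was obtained on noisy experimental
  data.
* Shrinkage, case hardening, sorption hysteresis and radiative heating
  are out of scope; the 2-D axisymmetric mode resolves radial structure
  only through the uniform rim film, not a spatially varying external
  flow field.
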