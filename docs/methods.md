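# Methods

## Scope and model chain

`leafgm` analyses simultaneous leaf gas-exchange and chlorophyll
fluorescence records from C3 leaves.  The computational chain is:

fluorescence → Φ_PSII, J_f → variable-J inversion → (C_c, g_m) →
conductance chain (g_sc, g_t, WUE_i) → Grassi–Magnani limitation partition
(l_s, l_m, l_b) → pooled statistics against water-status covariates
(Ψ_soil, Ψ_leaf, ABA).

All fluxes are in µmol CO2 m⁻² s⁻¹, conductances in mol m⁻² s⁻¹ (g_s on an
H2O basis, g_sc = g_s/1.6 and g_m on a CO2 basis), CO2 mole fractions in
µmol mol⁻¹, O2 in mmol mol⁻¹, temperatures in Kelvin internally (ingest
converts °C → K), water potentials in MPa (≤ 0), ABA in ng ml⁻¹.

## Kinetic temperature scaling

Γ*, K_c and K_o follow exp(c − H_a/(R·T_k)) with H_a in kJ mol⁻¹
(multiplied by 1000 internally against R = 8.314 J K⁻¹ mol⁻¹).  Defaults:

| parameter | c | H_a (kJ/mol) | value at 25 °C |
|---|---|---|---|
| Γ* (tomato) | 12.7 | 23.2 | 28.24 µmol mol⁻¹ |
| K_c | 38.2668 | 80.99 | 268.9 µmol mol⁻¹ |
| K_o | 14.6666 | 23.72 | 163.7 mmol mol⁻¹ |

The K_c/K_o constants are the standard in-vivo Rubisco parameterisation,
converted from the commonly tabulated partial-pressure basis to a
mole-fraction basis at 101.325 kPa (c shifts by ln(10⁶/101325) = 2.2894;
H_a is unchanged).  The Γ* constants evaluate to 28.24 µmol mol⁻¹ at 25 °C;
the unit basis of the upstream source is not fully documented, so the value
is treated as a mole fraction and every constant is config data
(`PhotoConfig`), overridable per run.  α = 0.84, β = 0.5 and O = 210
mmol mol⁻¹ live in the same config.

## Variable-J inversion

R_d is taken as half the measured dark respiration.  The inversion is only
defined when J_f > 4(A_n + R_d); below that the fluorescence-implied C_c
diverges.  Records violating it, or yielding C_c ≥ C_i (negative drawdown),
are flagged with machine-readable reason codes and retained.  This is
deliberate: the ±10/20 % sensitivity analysis shows that a 20 %
underestimate of J_f can flip well-watered records into the unstable
regime, and that instability is part of the method's diagnostic output.
The sensitivity table perturbs exactly one of {R_d, Γ*, J_f, C_i}
multiplicatively per cell, reports mean ± sd of the perturbed g_m, the
count of newly invalidated records, and a paired two-sided t-test flag
(ns / P<0.05 / P<0.01) against the unperturbed estimates.  The t-test is a
pragmatic choice — the flag convention predates any stated test — and the
replication unit (records as provided) is recorded in output metadata
rather than guessed.

## FvCB model and A/Ci fitting

A_n = min(A_c, A_j) − R_d structure with A_c the Rubisco-limited and A_j
the RuBP-regeneration-limited branch.  Curve simulation solves the
supply/demand balance A_n = g_sc(C_a − C_i) = g_m(C_i − C_c) = FvCB(C_c)
by Brent's method per setpoint; the solution is unique because supply is
strictly decreasing and demand non-decreasing in C_c, and every solved
point is re-checked to a 1e−8 flux residual.

`fit_vcmax` fits the Rubisco-limited branch to points with C_i below a
configurable cutoff (default 300 µmol mol⁻¹ — which limitation-state
assignment the classic protocol used is not documented, so the cutoff is
reported with every fit).  The fit is on a C_i basis with the conventional
infinite-g_m assumption; with kinetics fixed and R_d known the model is
linear in V_cmax, and the bounded least-squares solver (V_cmax₀ =
4·max(A_n), bounds (0, 1000], deterministic, no restarts) converges to
that linear solution.  On finite-g_m leaves this yields the usual
*apparent* V_cmax underestimate; passing `x_col="Cc"` fits on a
chloroplastic-CO2 basis (C_c = C_i − A_n/g_m from the record's g_m
estimate), which the zero-noise closure tests use to recover the
generating V_cmax exactly.  The repeated 400 µmol mol⁻¹ setpoints in the
protocol are retained and used as a stability check (warning if the two
A_n readings differ by more than 10 %).

## Limitation partition

∂A/∂C_c is evaluated at each record's estimated C_c with the V_cmax fitted
for that plant/day (configurable fallback when no curve is available); the
evaluation point is recorded in the output metadata, since the partition
equations require a C_c but do not prescribe which one.  The three
fractions sum to one algebraically; the pipeline asserts the identity to
1e−12 on every row.  Drought-stage binning for stage summaries uses
Ψ_soil breakpoints (−0.71, −1.15 MPa by default, configurable).

## Synthetic drydown generator

The generator emulates a 7-day progressive pot drydown (days 27–33 after
transplanting) with a well-watered control, at the replication of the
emulated protocol: 2 control and 6 drought plants per day.

* **Soil.** Drought RSWC declines linearly 82.90 → 37.27 % of field
  capacity.  The water-retention mapping RSWC → Ψ_soil is log-linear
  between the anchors (82.90 %, −0.40 MPa) and (37.27 %, −1.44 MPa) — the
  emulated experiment reports endpoints, not a retention curve.  Control:
  RSWC 75.13 %, Ψ_soil −0.43 MPa, stationary.
* **Leaf water potential.** Flat at −0.72 MPa until Ψ_soil crosses
  −0.71 MPa, then linear in Ψ_soil with slope 1.25, reaching ≈ −1.63 MPa
  at the final day.
* **ABA.** Flat at 0.3262 ng ml⁻¹ until Ψ_soil < −1.01 MPa, then
  exponential in −Ψ_soil at rate ln(300)/0.43 MPa⁻¹, calibrated once so
  the final drought mean is 97.86 ng ml⁻¹ ≈ 300× the control baseline.
* **Conductances.**  g_s = g_s,ww · f_hyd(Ψ_leaf) · f_ABA(ABA) with
  g_s,ww = 0.32; f_hyd is 1 until Ψ_leaf < −0.90 MPa then declines
  linearly (1.1 MPa⁻¹); f_ABA = (1 + ABA₀/k)/(1 + ABA/k) with half-point
  k = 50 ng ml⁻¹ (a Hill-type solute-signal attenuation, normalised to 1
  at baseline).  g_m holds a 0.20 mol m⁻² s⁻¹ plateau until Ψ_leaf <
  −1.28 MPa, then declines at 0.53 mol m⁻² s⁻¹ MPa⁻¹; both floored at
  0.01.  By construction g_s leaves its plateau at milder stress than g_m.
  No functional forms for these responses are established for the emulated
  system; these are the package's modelling choices, stated here, not
  empirical claims.
* **Biochemistry.** V_cmax = 100, J (light-saturated at PPFD 1500) = 160,
  R_dark = 2 µmol m⁻² s⁻¹, constant across the drydown — the generator
  models purely diffusional drought limitation.  Consequently the
  synthetic WUE_i rises monotonically under drought (C_a − C_i widens),
  whereas real leaves often show a rise-then-fall as biochemical
  impairment raises C_i again under severe stress; passing tests on this
  generator therefore say nothing about non-stomatal V_cmax responses.
* **Observables.** For each plant×day the coupled system is solved at
  C_a = 400 with the true conductances; J_f is back-filled from the
  consistency identity J_f = (A_n+R_d)(4C_c+8Γ*)/(C_c−Γ*) so the
  variable-J inversion is exact on noiseless data, and Fs is derived from
  Φ_PSII against a fixed instrument-scale Fm′ = 2000 (only Φ_PSII matters
  downstream).  Noise is multiplicative log-normal per observable
  (default CV 2 % for gas-exchange observables, 3 % for water potentials,
  10 % for ABA), reflecting errors that scale with signal.  Seeding uses
  `numpy` SeedSequence streams; identical seed ⇒ bit-identical tables,
  and the observation table is invariant to whether A/Ci curves are also
  generated.

## Departure-day detection

"When does a drought variable leave the control envelope?" is answered
against the *pooled* control (the control arm is stationary by design and
per-day control replication is only n = 2): the departure day is the first
day from which every subsequent day has the drought mean below 90 % of the
pooled control mean *and* a Welch test against the pooled control
significant at 0.05.  The persistence and significance requirements keep
single-day noise dips in a 6-replicate day mean from registering as
departures.

## Statistics

* Pearson correlations (two-sided P, flags at 0.05/0.01) over the pooled
  drought + control × all-days table by default; pairs with < 3 complete
  rows or a constant column are flagged undefined.  Pooling is
  configurable via the variable list.
* Regression family selection fits linear, exponential and logarithmic
  candidates and keeps the highest r².  Exponential fits are log-linear
  least squares (documented, deterministic) rather than iterative; r² for
  the nonlinear families is computed on the original y scale so the
  comparison across families is fair.  Fits are marked non-significant
  (not displayed) when the slope P ≥ 0.05.
* Treatment-vs-control: per-day Welch two-sample t-tests with Holm
  adjustment across days — a pragmatic stand-in for many-to-one
  (Dunnett-style) per-day annotation; the method string is written into
  every comparison artifact.

## Problem sizes and numerical choices

The test suite exercises the default scenario (56 records/run; five seeded
runs = 210 drought records for the noisy g_m recovery check), 100-seed
V_cmax recovery on the 14-point protocol, and 10-seed qualitative drydown
reproduction — desk-scale sizes chosen so the whole suite runs in seconds
while keeping Monte-Carlo medians stable.  Root finding uses Brent's
method at xtol 1e−12; the variable-J inversion and partition are closed
form.  Degenerate statistical inputs (zero-variance arms, single-record
cells) return explicit flags ("insufficient replication", "undefined")
rather than NaN-propagating silently.

## Known limitations

* No TPU limitation, no temperature response of V_cmax/J_max, no
  g_m-explicit A/Ci fitting; the C_i-basis V_cmax is an apparent value.
* The generator has no mechanistic soil–plant hydraulics, no ABA
  biosynthesis kinetics and no within-day time courses; its response
  forms are plausible calibrated shapes, not mechanistic claims.
* The sensitivity-table significance flags assume paired records; the
  appropriate replication unit (leaf vs plant) is metadata the caller
  must supply for real datasets.
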